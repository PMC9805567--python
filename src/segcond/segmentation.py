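"""Changepoint segmentation of the reduced (PC1) signal.

Chromosomal coordinates are treated as a pseudo-time axis and segment
boundaries are structural breaks in a piecewise-constant mean model.
For a fixed number of breaks m the break positions minimize the residual
sum of squares, found exactly by dynamic programming (the classic
multiple-structural-breaks recursion); m itself is chosen by BIC.
Because the exact search is quadratic in window length, chromosomes are
scanned in overlapping sliding windows and window-level boundaries are
merged.

Break index convention: a break at index b splits the signal between
positions b and b+1 (segments ``[0..b]`` and ``[b+1..]``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GenomeGrid

__all__ = [
    "SegmentationConfig",
    "Segment",
    "detect_breakpoints",
    "chow_f_statistics",
    "segment_chromosome",
    "segment_genome",
    "segmentation_diagnostics",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Sliding-window segmentation parameters.

    window_bins=1000 at 5-kb bins corresponds to 5 Mb of DNA; windows
    advance by step_bins so consecutive windows overlap by half.
    min_seg_frac is the minimum segment size as a fraction of the window
    (0.05 -> 50 bins -> 250 kb), which also caps the number of breaks a
    window can report at floor(1/min_seg_frac) - 1.
    """

    window_bins: int = 1000
    step_bins: int = 500
    min_seg_frac: float = 0.05
    merge_tol_bins: int | None = None  # default: one minimal segment

    def __post_init__(self) -> None:
        if not (0 < self.min_seg_frac <= 0.5):
            raise ValueError("min_seg_frac must be in (0, 0.5]")
        if self.step_bins > self.window_bins:
            raise ValueError("step_bins must not exceed window_bins")
        if self.window_bins < 2 * self.min_seg_bins:
            raise ValueError("window must hold at least two minimal segments")

    @property
    def min_seg_bins(self) -> int:
        return math.ceil(self.min_seg_frac * self.window_bins)

    @property
    def max_breaks_per_window(self) -> int:
        return int(1 / self.min_seg_frac) - 1

    @property
    def merge_tolerance(self) -> int:
        return self.merge_tol_bins if self.merge_tol_bins is not None else self.min_seg_bins


@dataclass(frozen=True)
class Segment:
    """A contiguous genomic interval between two changepoints."""

    id: str
    chrom: str
    start: int          # bp, 0-based half-open
    end: int
    mean_pc1: float
    sd_pc1: float
    n_bins: int
    start_bin: int = 0  # bin offsets within the chromosome
    end_bin: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def _segment_cost_matrix(x: np.ndarray, min_seg: int) -> np.ndarray:
    """cost[i, j] = RSS of fitting a constant to x[i..j] inclusive.

    Entries for segments shorter than min_seg (or with j < i) are +inf.
    """
    n = x.size
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = (s2[j + 1] - s2[i]) - (s1[j + 1] - s1[i]) ** 2 / length
    cost = np.maximum(cost, 0.0)  # guard tiny negative round-off
    cost[length < max(min_seg, 1)] = np.inf
    return cost


def detect_breakpoints(signal: np.ndarray, min_seg_bins: int,
                       max_breaks: int,
                       return_details: bool = False):
    """Optimal piecewise-constant breakpoints with BIC model selection.

    For each break count m <= max_breaks the globally RSS-minimizing
    break positions are found by dynamic programming, subject to every
    segment holding >= min_seg_bins points.  The returned m* minimizes
    BIC(m) = n * ln(RSS_m / n) + (2m + 2) * ln(n); ties go to the
    smallest m.

    A signal too short to hold two minimal segments yields no breaks
    (with a warning) rather than an error, since chromosome tails are
    legitimately short.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if min_seg_bins < 1:
        raise ValueError("min_seg_bins must be >= 1")
    if max_breaks < 0:
        raise ValueError("max_breaks must be >= 0")
    if n < 2 * min_seg_bins:
        warnings.warn(
            f"signal of length {n} cannot hold two segments of {min_seg_bins} bins; "
            "returning no breakpoints", stacklevel=2)
        return ([], {}) if return_details else []

    m_cap = min(max_breaks, n // min_seg_bins - 1)
    cost = _segment_cost_matrix(x, min_seg_bins)

    # F[m][j]: minimal RSS of x[0..j] split into m+1 segments.
    F = cost[0, :].copy()
    rss = np.full(m_cap + 1, np.inf)
    rss[0] = F[n - 1]
    argmins: list[np.ndarray] = []
    for m in range(1, m_cap + 1):
        # candidate last break t: previous part is x[0..t], new segment x[t+1..j]
        cand = F[:-1, None] + cost[1:, :]
        arg = np.argmin(cand, axis=0)
        F = cand[arg, np.arange(n)]
        argmins.append(arg)
        rss[m] = F[n - 1]

    with np.errstate(divide="ignore"):
        log_term = np.where(rss > 0, np.log(rss / n), -np.inf)
    k = 2 * np.arange(m_cap + 1) + 2
    bic = np.where(np.isfinite(rss), n * log_term + k * np.log(n), np.inf)
    m_star = int(np.argmin(bic))  # first occurrence == smallest m on ties

    breaks: list[int] = []
    j = n - 1
    for m in range(m_star, 0, -1):
        t = int(argmins[m - 1][j])
        breaks.append(t)
        j = t
    breaks.reverse()

    if return_details:
        details = {"rss": rss, "bic": bic, "m": m_star,
                   "f_stats": chow_f_statistics(x, breaks)}
        return breaks, details
    return breaks


def chow_f_statistics(signal: np.ndarray, breaks: list[int]) -> list[float]:
    """Per-break F statistic (structural-break test) for reporting.

    For each break, the two adjacent segments are compared against their
    pooled fit: F = ((RSS_pooled - RSS_split) / 1) / (RSS_split / (n - 2))
    for the constant-mean model with one parameter per regime.
    """
    x = np.asarray(signal, dtype=float)
    edges = [0] + [b + 1 for b in breaks] + [x.size]
    out = []
    for bi in range(len(breaks)):
        left = x[edges[bi]: edges[bi + 1]]
        right = x[edges[bi + 1]: edges[bi + 2]]
        pooled = np.concatenate([left, right])
        rss_split = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        rss_pool = ((pooled - pooled.mean()) ** 2).sum()
        dof = pooled.size - 2
        if rss_split <= 0 or dof <= 0:
            out.append(np.inf)
        else:
            out.append(float((rss_pool - rss_split) / (rss_split / dof)))
    return out


def _window_starts(n: int, window: int, step: int) -> list[int]:
    if n <= window:
        return [0]
    starts = list(range(0, n - window + 1, step))
    if starts[-1] + window < n:
        starts.append(n - window)  # right-anchored tail window
    return starts


def _merge_boundaries(breaks: list[int], tol: int) -> list[int]:
    """Single-linkage clustering of break indices; each cluster -> its median."""
    if not breaks:
        return []
    b = sorted(breaks)
    merged = []
    cluster = [b[0]]
    for v in b[1:]:
        if v - cluster[-1] <= tol:
            cluster.append(v)
        else:
            merged.append(cluster[len(cluster) // 2 - (1 - len(cluster) % 2)])
            cluster = [v]
    merged.append(cluster[len(cluster) // 2 - (1 - len(cluster) % 2)])
    return merged


def segment_chromosome(pc1: np.ndarray, chrom: str, chrom_size: int,
                       bin_size: int,
                       cfg: SegmentationConfig = SegmentationConfig()) -> list[Segment]:
    """Segment one chromosome by sliding-window breakpoint detection.

    Windows of ``cfg.window_bins`` advance by ``cfg.step_bins``; the last
    window is right-anchored at the chromosome end so every bin is
    scanned with full context.  Window-level breaks are pooled, merged by
    single-linkage clustering (gap <= merge tolerance, cluster replaced
    by its median) and converted to segments.
    """
    x = np.asarray(pc1, dtype=float)
    n = x.size
    expected = -(-chrom_size // bin_size)
    if n != expected:
        raise ValueError(f"pc1 length {n} != bin count {expected} for {chrom}")

    all_breaks: list[int] = []
    for w0 in _window_starts(n, cfg.window_bins, cfg.step_bins):
        wlen = min(cfg.window_bins, n)
        wx = x[w0: w0 + wlen]
        h = math.ceil(cfg.min_seg_frac * wlen)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            br = detect_breakpoints(wx, h, cfg.max_breaks_per_window)
        # A break pinned to the admissibility margin (exactly min_seg from a
        # window edge) usually marks a changepoint lying beyond the margin,
        # pushed inward by the constraint; drop it unless the window edge is
        # a chromosome end, where the margin is genuine.  The overlapping
        # neighbour window sees the true position unconstrained.
        left_end = w0 == 0
        right_end = w0 + wlen == n
        for b in br:
            if b == h - 1 and not left_end:
                continue
            if b == wlen - h - 1 and not right_end:
                continue
            all_breaks.append(w0 + b)

    boundaries = _merge_boundaries(all_breaks, cfg.merge_tolerance)
    edges = [0] + [b + 1 for b in boundaries if 0 <= b < n - 1] + [n]
    edges = sorted(set(edges))

    segments = []
    for i, (b0, b1) in enumerate(zip(edges[:-1], edges[1:])):
        seg = x[b0:b1]
        segments.append(Segment(
            id=f"{chrom}_seg{i:04d}",
            chrom=chrom,
            start=b0 * bin_size,
            end=min(b1 * bin_size, chrom_size),
            mean_pc1=float(seg.mean()),
            sd_pc1=float(seg.std()),
            n_bins=b1 - b0,
            start_bin=b0,
            end_bin=b1,
        ))
    return segments


def segment_genome(pc1: np.ndarray, grid: GenomeGrid,
                   cfg: SegmentationConfig = SegmentationConfig()) -> list[Segment]:
    """Apply :func:`segment_chromosome` to every chromosome of the grid."""
    segments: list[Segment] = []
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        segments.extend(segment_chromosome(
            pc1[sl], chrom, grid.chrom_sizes[chrom], grid.bin_size, cfg))
    return segments


def segmentation_diagnostics(segments: list[Segment],
                             pc1: np.ndarray | None = None) -> pd.DataFrame:
    """Per-segment size / neighbour-contrast / within-SD diagnostics.

    These are the quantities used to choose the minimum-segment-size
    cutoff: segment length, the absolute difference between a segment's
    mean signal and each neighbour's, and the within-segment SD.
    Neighbour columns are NaN where a segment has no neighbour on that
    side.  Segments must come from a single chromosome, in order.
    """
    rows = []
    for i, seg in enumerate(segments):
        prev_d = abs(seg.mean_pc1 - segments[i - 1].mean_pc1) if i > 0 else np.nan
        next_d = (abs(seg.mean_pc1 - segments[i + 1].mean_pc1)
                  if i < len(segments) - 1 else np.nan)
        rows.append({
            "segment_id": seg.id,
            "chrom": seg.chrom,
            "size_bp": seg.length,
            "n_bins": seg.n_bins,
            "mean_pc1": seg.mean_pc1,
            "sd_pc1": seg.sd_pc1,
            "diff_prev": prev_d,
            "diff_next": next_d,
        })
    return pd.DataFrame(rows)
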