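"""Chromatin-contact integration and condensate calling.

Normalized per-contact scores (an externally produced SHAMAN-style
track, or the built-in distance-decay fallback) are pooled per segment
pair by taking the median of all contributing contact scores.  Only
intra-chromosomal contacts are scored and only segment pairs within a
distance cap (default 2 Mb) enter the table, matching the rapid decay
of informative normalized contacts with distance.  A score cutoff is
estimated by permutation, the table is binarized, and putative
transcriptional condensates (PTCs) are the connected components of the
resulting graph over enhancer-enriched segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .grid import GenomeGrid
from .segmentation import Segment

__all__ = [
    "ContactScoreSet",
    "PTC",
    "load_contact_scores",
    "fallback_score_contacts",
    "score_segment_pairs",
    "estimate_cutoff",
    "call_ptcs",
    "overlap_ptcs",
]

logger = logging.getLogger(__name__)

DEFAULT_DMAX = 2_000_000
DEFAULT_EXTERNAL_CUTOFF = 17.0  # only meaningful on the external score scale


@dataclass
class ContactScoreSet:
    """Point list of normalized contact scores.

    Records are canonicalized so pos1 <= pos2 on the same chromosome.
    Inter-chromosomal records are kept but flagged: condensate scoring
    is intra-chromosomal only.
    """

    records: pd.DataFrame  # chrom1, pos1, chrom2, pos2, score
    source_tag: str = "external_normalized"
    _by_chrom: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = self.records
        required = ["chrom1", "pos1", "chrom2", "pos2", "score"]
        if list(df.columns[:5]) != required:
            df = df.copy()
            df.columns = required + list(df.columns[5:])
        if len(df) and not np.all(np.isfinite(df["score"].to_numpy(dtype=float))):
            raise ValueError("contact scores must be finite")
        same = df["chrom1"] == df["chrom2"]
        flip = same & (df["pos1"] > df["pos2"])
        if flip.any():
            df = df.copy()
            p1 = df.loc[flip, "pos1"].copy()
            df.loc[flip, "pos1"] = df.loc[flip, "pos2"]
            df.loc[flip, "pos2"] = p1
        self.records = df

    @property
    def n_intra(self) -> int:
        return int((self.records["chrom1"] == self.records["chrom2"]).sum())

    def intra(self) -> pd.DataFrame:
        df = self.records
        return df[df["chrom1"] == df["chrom2"]]

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (pos1, pos2, score) arrays sorted by pos1 (cached)."""
        if not self._by_chrom:
            for chrom, sub in self.intra().groupby("chrom1", sort=False):
                p1 = sub["pos1"].to_numpy(dtype=np.int64)
                p2 = sub["pos2"].to_numpy(dtype=np.int64)
                sc = sub["score"].to_numpy(dtype=float)
                order = np.argsort(p1, kind="stable")
                self._by_chrom[chrom] = (p1[order], p2[order], sc[order])
        return self._by_chrom


def load_contact_scores(path, source_tag: str = "external_normalized") -> ContactScoreSet:
    """Read a 5-column tab-delimited score track (header optional)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        logger.warning("contact score file %s is empty", path)
        return ContactScoreSet(pd.DataFrame(
            columns=["chrom1", "pos1", "chrom2", "pos2", "score"]), source_tag)
    if df.shape[1] != 5:
        raise ValueError(f"{path}: expected 5 tab-delimited columns, got {df.shape[1]}")
    first = df.iloc[0]
    start = 0
    try:
        float(first[1]), float(first[3]), float(first[4])
    except (TypeError, ValueError):
        start = 1  # header row
    body = df.iloc[start:].reset_index(drop=True)
    out = pd.DataFrame({"chrom1": body[0], "chrom2": body[2]})
    for col, j in (("pos1", 1), ("pos2", 3), ("score", 4)):
        vals = pd.to_numeric(body[j], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + start + 1
            raise ValueError(f"{path}: malformed value in column {j + 1}, line {line}")
        out[col] = vals
    out = out[["chrom1", "pos1", "chrom2", "pos2", "score"]]
    out["pos1"] = out["pos1"].astype(np.int64)
    out["pos2"] = out["pos2"].astype(np.int64)
    n_inter = int((out["chrom1"] != out["chrom2"]).sum())
    if n_inter:
        logger.warning("%d inter-chromosomal records loaded; they are not scored",
                       n_inter)
    return ContactScoreSet(out, source_tag)


def fallback_score_contacts(raw_pairs: pd.DataFrame, grid: GenomeGrid,
                            alpha: float = 1.0) -> ContactScoreSet:
    """Distance-decay observed/expected scores from raw contact pairs.

    For every populated bin pair at bin distance d the score is
    log2((observed + alpha) / (expected_d + alpha)), where expected_d is
    the genome-wide mean count over all possible intra-chromosomal bin
    pairs at distance d.  Scores are NOT on the external normalizer's
    scale: the condensate cutoff must be re-estimated by permutation.
    """
    cols = list(raw_pairs.columns[:3])
    if len(raw_pairs) == 0:
        return ContactScoreSet(pd.DataFrame(
            columns=["chrom1", "pos1", "chrom2", "pos2", "score"]), "fallback")
    df = raw_pairs.rename(columns=dict(zip(cols, ["chrom", "pos1", "pos2"])))
    bs = grid.bin_size
    b1 = df["pos1"] // bs
    b2 = df["pos2"] // bs
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    pairs = pd.DataFrame({"chrom": df["chrom"], "b1": lo, "b2": hi})
    counts = pairs.groupby(["chrom", "b1", "b2"]).size().reset_index(name="n")
    counts["d"] = counts["b2"] - counts["b1"]
    # possible bin pairs at each distance, summed over chromosomes
    nb = np.array([grid.n_bins_chrom(c) for c in grid.chroms])
    max_d = int(counts["d"].max())
    d = np.arange(max_d + 1)
    possible = np.maximum(nb[:, None] - d[None, :], 0).sum(axis=0).astype(float)
    observed_by_d = counts.groupby("d")["n"].sum().reindex(d, fill_value=0).to_numpy()
    expected = observed_by_d / np.maximum(possible, 1.0)
    score = np.log2((counts["n"].to_numpy() + alpha)
                    / (expected[counts["d"].to_numpy()] + alpha))
    mid = bs // 2
    out = pd.DataFrame({
        "chrom1": counts["chrom"],
        "pos1": (counts["b1"] * bs + mid).astype(np.int64),
        "chrom2": counts["chrom"],
        "pos2": (counts["b2"] * bs + mid).astype(np.int64),
        "score": score,
    })
    return ContactScoreSet(out, "fallback")


# ---------------------------------------------------------------------------
# segment-pair pooling
# ---------------------------------------------------------------------------

def _segment_distance(a: Segment, b: Segment, mode: str = "end_gap") -> int:
    if a.chrom != b.chrom:
        raise ValueError("distance undefined across chromosomes")
    if mode == "end_gap":
        return max(0, max(a.start, b.start) - min(a.end, b.end))
    if mode == "midpoint":
        return abs((a.start + a.end) // 2 - (b.start + b.end) // 2)
    raise ValueError(f"unknown distance mode {mode!r}")


def score_segment_pairs(contacts: ContactScoreSet, segments: list[Segment],
                        d_max: int = DEFAULT_DMAX,
                        distance_mode: str = "end_gap") -> pd.DataFrame:
    """Median-pooled interaction score per segment pair.

    A contact contributes to the pair (segment containing pos1, segment
    containing pos2); intra-segment contacts give the segment its own
    interaction entry.  Pairs of segments farther apart than ``d_max``
    are omitted, as are pairs without any contributing contact.
    Segments must be non-overlapping within each chromosome.
    """
    segs_by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        segs_by_chrom.setdefault(s.chrom, []).append(s)
    rows = []
    dropped = 0
    for chrom, (p1, p2, sc) in contacts.by_chrom().items():
        segs = sorted(segs_by_chrom.get(chrom, []), key=lambda s: s.start)
        if not segs:
            dropped += p1.size
            continue
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        i1 = np.searchsorted(starts, p1, side="right") - 1
        i2 = np.searchsorted(starts, p2, side="right") - 1
        ok = (i1 >= 0) & (i2 >= 0)
        ok &= np.where(i1 >= 0, p1 < ends[np.maximum(i1, 0)], False)
        ok &= np.where(i2 >= 0, p2 < ends[np.maximum(i2, 0)], False)
        dropped += int((~ok).sum())
        if not ok.any():
            continue
        sub = pd.DataFrame({"a": np.minimum(i1[ok], i2[ok]),
                            "b": np.maximum(i1[ok], i2[ok]),
                            "score": sc[ok]})
        pooled = sub.groupby(["a", "b"])["score"].agg(["median", "size"]).reset_index()
        for a, b, med, n in pooled.itertuples(index=False):
            sa, sb = segs[int(a)], segs[int(b)]
            dist = 0 if a == b else _segment_distance(sa, sb, distance_mode)
            if dist > d_max:
                continue
            rows.append({"segment_a": sa.id, "segment_b": sb.id,
                         "median_score": float(med), "n_contacts": int(n),
                         "distance_bp": int(dist)})
    if dropped:
        logger.info("%d contacts fell outside all segments and were ignored", dropped)
    return pd.DataFrame(rows, columns=["segment_a", "segment_b", "median_score",
                                       "n_contacts", "distance_bp"])


def _pooled_medians_general(contacts: ContactScoreSet,
                            segments: list[Segment],
                            d_max: int,
                            distance_mode: str = "end_gap") -> np.ndarray:
    """Median scores for all candidate pairs, tolerant of overlapping segments.

    Used for the permutation null, where randomly re-placed segments may
    overlap each other; membership is tested pairwise rather than by the
    tiling lookup of :func:`score_segment_pairs`.  Returns only the
    medians (the permutation objective needs nothing else).
    """
    by_chrom = contacts.by_chrom()
    segs_by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        segs_by_chrom.setdefault(s.chrom, []).append(s)
    medians = []
    for chrom, segs in segs_by_chrom.items():
        if chrom not in by_chrom:
            continue
        p1, p2, sc = by_chrom[chrom]
        segs = sorted(segs, key=lambda s: s.start)
        # slice of contacts whose pos1 falls inside each segment
        slices = [(np.searchsorted(p1, s.start, side="left"),
                   np.searchsorted(p1, s.end - 1, side="right")) for s in segs]
        for ia, sa in enumerate(segs):
            for ib in range(ia, len(segs)):
                sb = segs[ib]
                dist = 0 if ia == ib else _segment_distance(sa, sb, distance_mode)
                if dist > d_max:
                    continue
                lo, hi = slices[ia]
                m1 = (p2[lo:hi] >= sb.start) & (p2[lo:hi] < sb.end)
                vals = sc[lo:hi][m1]
                if ia != ib:
                    lo2, hi2 = slices[ib]
                    m2 = (p2[lo2:hi2] >= sa.start) & (p2[lo2:hi2] < sa.end)
                    if m2.any():
                        vals = np.concatenate([vals, sc[lo2:hi2][m2]])
                if vals.size:
                    medians.append(np.median(vals))
    return np.asarray(medians)


# ---------------------------------------------------------------------------
# cutoff estimation by permutation
# ---------------------------------------------------------------------------

def _random_segments(segments: list[Segment], grid: GenomeGrid,
                     rng: np.random.Generator) -> list[Segment]:
    """Re-place every segment uniformly at random (lengths preserved).

    A segment of L bins lands wholly within one chromosome, chosen with
    probability proportional to its number of valid start bins; random
    placements may overlap one another, as in any genome-interval
    shuffle of a tiling set.
    """
    chroms = grid.chroms
    nbins = np.array([grid.n_bins_chrom(c) for c in chroms])
    out = []
    for k, seg in enumerate(segments):
        valid = np.maximum(nbins - seg.n_bins + 1, 0)
        if valid.sum() == 0:
            raise ValueError(f"no chromosome can host segment {seg.id}")
        ci = rng.choice(len(chroms), p=valid / valid.sum())
        s = int(rng.integers(0, valid[ci]))
        chrom = chroms[ci]
        start = s * grid.bin_size
        end = min(start + seg.n_bins * grid.bin_size, grid.chrom_sizes[chrom])
        out.append(Segment(id=f"rand{k:04d}", chrom=chrom, start=start, end=end,
                           mean_pc1=0.0, sd_pc1=0.0, n_bins=seg.n_bins,
                           start_bin=s, end_bin=s + seg.n_bins))
    return out


def _tail_counts(medians: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    srt = np.sort(medians)
    return srt.size - np.searchsorted(srt, cutoffs, side="left")


def estimate_cutoff(contacts: ContactScoreSet | list[ContactScoreSet],
                    segments: list[Segment] | list[list[Segment]],
                    grid: GenomeGrid,
                    n_perm: int = 100,
                    cutoff_grid: np.ndarray | None = None,
                    seed: int = 0,
                    d_max: int = DEFAULT_DMAX,
                    combine: str = "single") -> float:
    """Permutation-based interaction-score cutoff.

    For each candidate cutoff c the objective is the number of observed
    table entries with median score >= c minus the mean such count over
    ``n_perm`` random re-placements of the segment coordinates; the
    returned cutoff maximizes the objective, ties broken toward the
    smallest value.  With ``combine='mean_over_conditions'``, pass lists
    of contact sets / segment lists (one per condition): per-condition
    objectives are averaged before the argmax, mirroring a cutoff chosen
    jointly across timepoints.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if combine == "single":
        conditions = [(contacts, segments)]
    elif combine == "mean_over_conditions":
        conditions = list(zip(contacts, segments))
    else:
        raise ValueError(f"unknown combine mode {combine!r}")

    true_medians = []
    for con, segs in conditions:
        table = score_segment_pairs(con, segs, d_max=d_max)
        if table.empty:
            raise ValueError("interaction table is empty; cannot estimate a cutoff")
        true_medians.append(table["median_score"].to_numpy())

    if cutoff_grid is None:
        lo = min(np.floor(m.min()) for m in true_medians)
        hi = max(np.ceil(m.max()) for m in true_medians)
        cutoff_grid = np.arange(lo, hi + 1)
    cutoff_grid = np.asarray(cutoff_grid, dtype=float)
    if cutoff_grid.size == 0:
        raise ValueError("cutoff grid is empty")
    cutoff_grid = np.sort(cutoff_grid)

    rng = np.random.default_rng(seed)
    objective = np.zeros(cutoff_grid.size)
    for (con, segs), true_med in zip(conditions, true_medians):
        n_true = _tail_counts(true_med, cutoff_grid)
        n_rand = np.zeros(cutoff_grid.size)
        for _ in range(n_perm):
            rand_segs = _random_segments(segs, grid, rng)
            med = _pooled_medians_general(con, rand_segs, d_max)
            if med.size:
                n_rand += _tail_counts(med, cutoff_grid)
        objective += (n_true - n_rand / n_perm) / len(conditions)
    best = int(np.argmax(objective))  # first max == smallest cutoff on ties
    return float(cutoff_grid[best])


# ---------------------------------------------------------------------------
# PTC calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PTC:
    """A putative transcriptional condensate: connected enhancer-enriched
    segments linked by above-cutoff interaction scores."""

    ptc_id: str
    member_segment_ids: frozenset[str]
    chrom: str
    span_start: int
    span_end: int
    condition_label: str = ""


def call_ptcs(table: pd.DataFrame, annotations: pd.DataFrame,
              segments: list[Segment], cutoff: float,
              d_max: int = DEFAULT_DMAX,
              condition_label: str = "") -> list[PTC]:
    """Connected components of the binarized interaction graph.

    An edge joins two distinct enhancer-enriched segments iff their
    median score >= cutoff (inclusive) and they lie within ``d_max``;
    a segment with no qualifying edge still forms a singleton PTC iff
    its own intra-segment entry passes the cutoff.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    seg_by_id = {s.id: s for s in segments}
    lab = dict(zip(annotations["segment_id"], annotations["label"]))
    missing = sorted({sid for sid in pd.concat([table["segment_a"], table["segment_b"]])
                      if sid not in lab})
    if missing:
        raise ValueError(f"segments lack annotations: {missing[:5]}")
    enriched = {sid for sid, v in lab.items() if v == "enhancer_enriched"}

    g = nx.Graph()
    for a, b, med, _n, dist in table.itertuples(index=False):
        if med < cutoff:
            continue
        if a == b:
            if a in enriched:
                g.add_node(a)
        elif a in enriched and b in enriched and dist <= d_max:
            g.add_edge(a, b)
    ptcs = []
    comps = sorted(nx.connected_components(g),
                   key=lambda c: min((seg_by_id[m].chrom, seg_by_id[m].start)
                                     for m in c))
    for i, comp in enumerate(comps):
        members = sorted(comp)
        chroms = {seg_by_id[m].chrom for m in members}
        if len(chroms) != 1:  # cannot happen with intra-chromosomal edges
            raise AssertionError("PTC spans multiple chromosomes")
        chrom = chroms.pop()
        ptcs.append(PTC(
            ptc_id=f"PTC{i:04d}" + (f"_{condition_label}" if condition_label else ""),
            member_segment_ids=frozenset(members),
            chrom=chrom,
            span_start=min(seg_by_id[m].start for m in members),
            span_end=max(seg_by_id[m].end for m in members),
            condition_label=condition_label,
        ))
    return ptcs


def overlap_ptcs(ptcs_a: list[PTC], ptcs_b: list[PTC]) -> int:
    """Number of PTCs in ``ptcs_a`` whose span overlaps any PTC in ``ptcs_b``.

    Asymmetric by construction; a PTC overlapping several partners still
    counts once.  Overlap is >= 1 bp on the genomic span.
    """
    count = 0
    for a in ptcs_a:
        for b in ptcs_b:
            if (a.chrom == b.chrom and a.span_start < b.span_end
                    and b.span_start < a.span_end):
                count += 1
                break
    return count
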