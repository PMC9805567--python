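"""Bins x experiments signal matrix: normalization, transforms, PCA reduction.

The segmentation signal is one-dimensional: several coverage tracks
(ATAC, histone marks, TF occupancy) are binned on a common grid,
depth-normalized, variance-stabilized (log10 + per-track Z-score) and
projected onto their first principal component.  PC1 acts as a joint
"regulatory activity" coordinate along the chromosome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GenomeGrid

__all__ = [
    "BinnedTrackMatrix",
    "PCAResult",
    "normalize_tracks",
    "log10_zscore",
    "compute_pc1",
]


@dataclass
class BinnedTrackMatrix:
    """Non-negative signal of several experiments on a common genomic grid."""

    grid: GenomeGrid
    experiments: list[str]
    values: np.ndarray  # (n_bins, n_experiments)
    normalization_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D bins x experiments array")
        if self.values.shape[0] != self.grid.n_bins:
            raise ValueError(
                f"row count {self.values.shape[0]} != grid bin count {self.grid.n_bins}"
            )
        if self.values.shape[1] != len(self.experiments):
            raise ValueError("column count does not match experiment names")
        if len(set(self.experiments)) != len(self.experiments):
            raise ValueError("experiment names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite entries")

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.experiments.index(name)
        except ValueError:
            raise KeyError(f"unknown track {name!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.bin_frame()
        for j, name in enumerate(self.experiments):
            df[name] = self.values[:, j]
        return df


@dataclass(frozen=True)
class PCAResult:
    """First principal component of the standardized track matrix.

    ``pc1`` is oriented so it correlates non-negatively with the per-bin
    mean of the input (activity up == PC1 up); ``sign_flipped`` records
    whether the raw eigenvector was negated to achieve that.
    """

    pc1: np.ndarray
    variance_explained_pct: float
    loadings: np.ndarray
    sign_flipped: bool


def normalize_tracks(matrix: BinnedTrackMatrix, method: str = "cpm") -> BinnedTrackMatrix:
    """Depth-normalize each track.

    cpm scales every column to a total of 1e6; rpkm additionally divides
    by bin length in kb (bins at chromosome ends may be shorter than the
    nominal bin size); raw is the identity.
    """
    if method not in ("cpm", "rpkm", "raw"):
        raise ValueError(f"unknown normalization method {method!r}")
    if method == "raw":
        return dataclasses.replace(matrix, values=matrix.values.copy(),
                                   normalization_tag="raw")
    sums = matrix.values.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        names = [matrix.experiments[j] for j in zero]
        raise ValueError(f"all-zero track(s) cannot be {method}-normalized: {names}")
    vals = matrix.values * (1e6 / sums)
    if method == "rpkm":
        vals = vals / (matrix.grid.bin_lengths()[:, None] / 1e3)
    return dataclasses.replace(matrix, values=vals, normalization_tag=method)


def log10_zscore(matrix: BinnedTrackMatrix | np.ndarray,
                 pseudocount: float = 1.0,
                 experiments: list[str] | None = None) -> pd.DataFrame:
    """Per-track Z-scores of log10(x + pseudocount).

    Population SD (divide by n) is used.  A track with zero variance is
    rejected by name, as its Z-score is undefined.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if isinstance(matrix, BinnedTrackMatrix):
        vals = matrix.values
        names = matrix.experiments
    else:
        vals = np.asarray(matrix, dtype=float)
        names = experiments or [f"track{j}" for j in range(vals.shape[1])]
    logged = np.log10(vals + pseudocount)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0)  # ddof=0: population SD
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"constant track(s) have undefined Z-scores: {[names[j] for j in flat]}"
        )
    return pd.DataFrame((logged - mean) / sd, columns=names)


def compute_pc1(matrix: np.ndarray | pd.DataFrame) -> PCAResult:
    """Project a standardized bins x experiments matrix onto its first PC.

    The leading eigenvector of the column covariance gives the loadings;
    the projection of the (column-centered) data on it is the reduced
    signal.  Sign convention: pc1 must correlate non-negatively with the
    per-bin row mean; if that correlation is exactly zero the first
    loading is required to be non-negative instead.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 bins and 2 experiments")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / X.shape[0]
    total = np.trace(cov)
    if total <= 0:
        raise ValueError("matrix has zero variance; PCA undefined")
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    lam = evals[-1]
    pc1 = Xc @ v
    row_mean = X.mean(axis=1)
    corr = float(pc1 @ (row_mean - row_mean.mean()))
    flipped = False
    if corr < 0 or (corr == 0 and v[0] < 0):
        v = -v
        pc1 = -pc1
        flipped = True
    return PCAResult(
        pc1=pc1,
        variance_explained_pct=float(100.0 * lam / total),
        loadings=v,
        sign_flipped=flipped,
    )
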