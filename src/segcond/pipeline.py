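"""End-to-end orchestration: tracks -> segments -> annotation -> condensates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import annotation as ann
from . import hic
from .grid import GenomeGrid
from .segmentation import Segment, SegmentationConfig, segment_genome
from .track_matrix import BinnedTrackMatrix, PCAResult, compute_pc1, log10_zscore

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    grid: GenomeGrid
    pca: PCAResult
    segments: list[Segment]
    enhancer_bins: np.ndarray
    annotations: pd.DataFrame
    interaction_table: pd.DataFrame
    cutoff: float
    ptcs: list[hic.PTC]


def run_pipeline(matrix: BinnedTrackMatrix,
                 contacts: hic.ContactScoreSet,
                 marks: tuple[str, ...] = ann.DEFAULT_MARKS,
                 seg_cfg: SegmentationConfig = SegmentationConfig(),
                 z_threshold: float = 1.0,
                 pseudocount: float = 1.0,
                 n_shuffles: int = 1000,
                 alpha: float = 0.05,
                 cutoff: float | None = None,
                 n_perm: int = 100,
                 d_max: int = hic.DEFAULT_DMAX,
                 seed: int = 0,
                 condition_label: str = "",
                 pca_on_transformed: bool = True) -> PipelineResult:
    """Run the full condensate-calling pipeline on one condition.

    When ``cutoff`` is None it is estimated by permutation from the
    observed interaction table (mandatory when the contact scores come
    from the fallback normalizer, whose scale differs from the external
    one).  ``seed`` drives the background shuffles and the permutation
    test; the rest of the pipeline is deterministic.
    """
    grid = matrix.grid
    z = log10_zscore(matrix, pseudocount=pseudocount)
    pca_input = z if pca_on_transformed else pd.DataFrame(
        matrix.values, columns=matrix.experiments)
    pca = compute_pc1(pca_input)
    segments = segment_genome(pca.pc1, grid, seg_cfg)
    bins = ann.call_enhancer_bins(z, marks=marks, z_threshold=z_threshold)
    annotations = ann.annotate(segments, grid, bins, n_shuffles=n_shuffles,
                               seed=seed, alpha=alpha)
    table = hic.score_segment_pairs(contacts, segments, d_max=d_max)
    if cutoff is None:
        cutoff = hic.estimate_cutoff(contacts, segments, grid, n_perm=n_perm,
                                     seed=seed + 1, d_max=d_max)
    ptcs = hic.call_ptcs(table, annotations, segments, cutoff, d_max=d_max,
                         condition_label=condition_label)
    return PipelineResult(grid=grid, pca=pca, segments=segments,
                          enhancer_bins=bins, annotations=annotations,
                          interaction_table=table, cutoff=float(cutoff),
                          ptcs=ptcs)
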