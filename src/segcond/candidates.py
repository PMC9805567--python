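"""Downstream segment classes and candidate-gene selection.

Segments fall into four mutually exclusive categories: Condensate
(enhancer-enriched and part of a PTC), Enhancer (enriched but not in
any PTC), and the enhancer-depleted remainder split into Active vs
Repressed by the sign of the segment's mean reduced signal (PC1
correlates positively with all activity tracks, so positive mean marks
transcriptionally active chromatin).  Candidate genes are those inside
a PTC, expressed (TPM > 0) and with a promoter window (+/- 5 kb around
the TSS) touching at least one called enhancer bin; across an ordered
condition series, the condensate-specific candidates are genes passing
in every later condition but not the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GenomeGrid
from .hic import PTC
from .segmentation import Segment

__all__ = [
    "GeneRecord",
    "classify_segments_4way",
    "genes_in_category",
    "select_candidates",
]

CATEGORIES = ("Condensate", "Enhancer", "Active", "Repressed")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    tss: int
    tpm_by_condition: dict[str, float]

    def __post_init__(self) -> None:
        if not (self.start <= self.tss < self.end or self.tss == self.end):
            raise ValueError(f"{self.gene_id}: TSS {self.tss} outside gene span")
        if any(v < 0 for v in self.tpm_by_condition.values()):
            raise ValueError(f"{self.gene_id}: negative TPM")


def classify_segments_4way(annotations: pd.DataFrame, ptcs: list[PTC],
                           segments: list[Segment],
                           pc1_active_threshold: float = 0.0) -> pd.DataFrame:
    """Assign every segment to exactly one of the four categories."""
    lab = dict(zip(annotations["segment_id"], annotations["label"]))
    in_ptc: set[str] = set()
    for p in ptcs:
        in_ptc |= p.member_segment_ids
    rows = []
    for seg in segments:
        if seg.id not in lab:
            raise ValueError(f"segment {seg.id} has no annotation")
        if lab[seg.id] == "enhancer_enriched":
            cat = "Condensate" if seg.id in in_ptc else "Enhancer"
        else:
            cat = "Active" if seg.mean_pc1 > pc1_active_threshold else "Repressed"
        rows.append({"segment_id": seg.id, "chrom": seg.chrom,
                     "start": seg.start, "end": seg.end, "category": cat})
    return pd.DataFrame(rows)


def _overlaps(start: int, end: int, ostart: int, oend: int) -> bool:
    return start < oend and ostart < end


def genes_in_category(genes: list[GeneRecord], classes: pd.DataFrame,
                      category: str) -> list[str]:
    """Genes falling exclusively within segments of one category.

    A gene qualifies iff its span overlaps at least one segment of the
    requested category and no segment of any other category.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    out = []
    for g in genes:
        sub = classes[classes["chrom"] == g.chrom]
        hit = sub[[_overlaps(g.start, g.end, s, e)
                   for s, e in zip(sub["start"], sub["end"])]]
        if len(hit) and set(hit["category"]) == {category}:
            out.append(g.gene_id)
    return out


def select_candidates(genes: list[GeneRecord],
                      ptcs_by_condition: dict[str, list[PTC]],
                      enhancer_bins_by_condition: dict[str, np.ndarray],
                      grid: GenomeGrid,
                      condition_order: list[str] | None = None,
                      promoter_halfwidth: int = 5000) -> pd.DataFrame:
    """Per-condition gene filter and condensate-specific candidate flag.

    A gene passes in a condition iff (i) its span overlaps a PTC span,
    (ii) TPM > 0, and (iii) the promoter window [tss - hw, tss + hw]
    overlaps at least one enhancer bin (the joint accessibility +
    H3K27ac call stands in for "accessible and decorated").
    ``candidate_flag`` marks genes passing in every condition after the
    first of ``condition_order`` but NOT in the first — condensate
    recruitment specific to the later stages of the series.
    """
    conditions = condition_order or list(ptcs_by_condition)
    missing = [c for c in conditions
               if c not in ptcs_by_condition or c not in enhancer_bins_by_condition]
    if missing:
        raise ValueError(f"conditions lack PTCs or enhancer bins: {missing}")
    bs = grid.bin_size
    rows = []
    for g in genes:
        if g.chrom not in grid.chrom_sizes:
            import warnings
            warnings.warn(f"gene {g.gene_id} on unknown chromosome {g.chrom}; skipped",
                          stacklevel=2)
            continue
        row: dict = {"gene_id": g.gene_id, "chrom": g.chrom}
        passes = {}
        for cond in conditions:
            tpm = g.tpm_by_condition.get(cond, 0.0)
            in_ptc = any(
                p.chrom == g.chrom and _overlaps(g.start, g.end, p.span_start, p.span_end)
                for p in ptcs_by_condition[cond])
            bins = np.asarray(enhancer_bins_by_condition[cond])
            w0 = max(g.tss - promoter_halfwidth, 0)
            w1 = min(g.tss + promoter_halfwidth, grid.chrom_sizes[g.chrom])
            off = grid.offset(g.chrom)
            # bins overlapping the closed promoter window [w0, w1]
            b0 = w0 // bs
            b1 = min(w1 // bs, grid.n_bins_chrom(g.chrom) - 1)
            marked = bool(bins[off + b0: off + b1 + 1].any())
            passes[cond] = bool(in_ptc and tpm > 0 and marked)
            row[f"pass_{cond}"] = passes[cond]
            row[f"tpm_{cond}"] = tpm
        later = conditions[1:]
        row["candidate_flag"] = bool(
            later and all(passes[c] for c in later) and not passes[conditions[0]])
        rows.append(row)
    return pd.DataFrame(rows)
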