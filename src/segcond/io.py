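"""Plain-text readers and writers for the formats the CLI exchanges.

Coverage comes in as bedGraph (4 columns, 0-based half-open) or as a
pre-binned TSV matrix (chrom/start/end + one column per track); segments
go out as BED6-style TSV; annotations, interaction tables and PTC tables
are headered TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .candidates import GeneRecord
from .grid import GenomeGrid, make_grid
from .hic import PTC
from .segmentation import Segment
from .track_matrix import BinnedTrackMatrix

__all__ = [
    "read_chrom_sizes", "read_bedgraph",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_segments_bed", "read_segments_bed",
    "write_ptcs_tsv", "read_ptcs_tsv",
    "read_genes",
]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length (bp)."""
    sizes: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
        name, size = parts[0], int(parts[1])
        if name in sizes:
            raise ValueError(f"{path}:{ln}: duplicate chromosome {name!r}")
        if size <= 0:
            raise ValueError(f"{path}:{ln}: non-positive length for {name!r}")
        sizes[name] = size
    return sizes


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    if (df["value"] < 0).any():
        raise ValueError(f"{path}: negative coverage values")
    return df


def write_matrix_tsv(matrix: BinnedTrackMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_matrix_tsv(path: str | Path) -> BinnedTrackMatrix:
    """Rebuild a binned matrix from its TSV; grid is inferred from the bins."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(df.columns[:3]) != ["chrom", "start", "end"]:
        raise ValueError(f"{path}: first three columns must be chrom/start/end")
    tracks = list(df.columns[3:])
    if not tracks:
        raise ValueError(f"{path}: no track columns found")
    sizes = df.groupby("chrom", sort=False)["end"].max().to_dict()
    widths = (df["end"] - df["start"])
    bin_size = int(widths.max())
    grid = make_grid(sizes, bin_size)
    if len(df) != grid.n_bins:
        raise ValueError(f"{path}: rows do not tile the inferred grid")
    return BinnedTrackMatrix(grid=grid, experiments=tracks,
                             values=df[tracks].to_numpy(dtype=float))


def write_segments_bed(segments: list[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.id}\t{s.mean_pc1:.6g}\t.\n")


def read_segments_bed(path: str | Path, grid: GenomeGrid) -> list[Segment]:
    segments = []
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "id", "mean_pc1", "strand"],
                     dtype={"chrom": str})
    for row in df.itertuples(index=False):
        b0 = row.start // grid.bin_size
        b1 = -(-row.end // grid.bin_size)
        segments.append(Segment(
            id=str(row.id), chrom=row.chrom, start=int(row.start), end=int(row.end),
            mean_pc1=float(row.mean_pc1), sd_pc1=float("nan"),
            n_bins=b1 - b0, start_bin=b0, end_bin=b1))
    return segments


def write_ptcs_tsv(ptcs: list[PTC], path: str | Path) -> None:
    rows = [{
        "ptc_id": p.ptc_id,
        "condition": p.condition_label,
        "members": ",".join(sorted(p.member_segment_ids)),
        "chrom": p.chrom,
        "span_start": p.span_start,
        "span_end": p.span_end,
    } for p in ptcs]
    pd.DataFrame(rows, columns=["ptc_id", "condition", "members", "chrom",
                                "span_start", "span_end"]
                 ).to_csv(path, sep="\t", index=False)


def read_ptcs_tsv(path: str | Path) -> list[PTC]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "condition": str},
                     keep_default_na=False)
    return [PTC(ptc_id=r.ptc_id,
                member_segment_ids=frozenset(str(r.members).split(",")),
                chrom=r.chrom, span_start=int(r.span_start),
                span_end=int(r.span_end), condition_label=str(r.condition))
            for r in df.itertuples(index=False)]


def read_genes(path: str | Path, conditions: list[str] | None = None) -> list[GeneRecord]:
    """Headered TSV: gene_id, chrom, start, end [, tss] + tpm_<cond> columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    tpm_cols = [c for c in df.columns if c.startswith("tpm_")]
    genes = []
    for r in df.itertuples(index=False):
        tss = int(getattr(r, "tss", r.start))
        genes.append(GeneRecord(
            gene_id=str(r.gene_id), chrom=r.chrom, start=int(r.start),
            end=int(r.end), tss=tss,
            tpm_by_condition={c[len("tpm_"):]: float(getattr(r, c)) for c in tpm_cols}))
    return genes
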