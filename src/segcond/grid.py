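"""Fixed-resolution genomic binning.

The genome is tiled into fixed-size bins (default 5 kb — coarse enough
that chromatin-contact data can later be attached to the same grid).
All coordinates are 0-based half-open, the BED convention; the last bin
of each chromosome is truncated at the chromosome end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 5_000


@dataclass(frozen=True)
class GenomeGrid:
    """An ordered tiling of the genome into fixed-size bins.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp, in the order the
        chromosomes were given.  Order is preserved and defines bin order.
    bin_size
        Bin width in bp.
    """

    chrom_sizes: dict[str, int]
    bin_size: int = DEFAULT_BIN_SIZE
    _n_bins_per_chrom: dict[str, int] = field(init=False, repr=False)
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        nb: dict[str, int] = {}
        offsets: dict[str, int] = {}
        total = 0
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
            n = -(-size // self.bin_size)  # ceil division
            nb[chrom] = n
            offsets[chrom] = total
            total += n
        object.__setattr__(self, "_n_bins_per_chrom", nb)
        object.__setattr__(self, "_offsets", offsets)

    # -- basic geometry ------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def n_bins(self) -> int:
        return sum(self._n_bins_per_chrom.values())

    def n_bins_chrom(self, chrom: str) -> int:
        return self._n_bins_per_chrom[chrom]

    def offset(self, chrom: str) -> int:
        """Global index of the first bin of *chrom*."""
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        o = self._offsets[chrom]
        return slice(o, o + self._n_bins_per_chrom[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index containing genomic position *pos*."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
        return self._offsets[chrom] + pos // self.bin_size

    def bins(self) -> Iterator[tuple[str, int, int]]:
        """Yield (chrom, start, end) for every bin in grid order."""
        for chrom, size in self.chrom_sizes.items():
            for start in range(0, size, self.bin_size):
                yield chrom, start, min(start + self.bin_size, size)

    def bin_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.bins()), columns=["chrom", "start", "end"])

    def bin_lengths(self) -> np.ndarray:
        """Length in bp of every bin (last bin per chromosome may be short)."""
        out = np.full(self.n_bins, self.bin_size, dtype=float)
        for chrom, size in self.chrom_sizes.items():
            rem = size % self.bin_size
            if rem:
                out[self.offset(chrom) + self._n_bins_per_chrom[chrom] - 1] = rem
        return out


def make_grid(chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]],
              bin_size: int = DEFAULT_BIN_SIZE) -> GenomeGrid:
    """Build a :class:`GenomeGrid`, rejecting duplicate or degenerate chromosomes."""
    if isinstance(chrom_sizes, Mapping):
        pairs = list(chrom_sizes.items())
    else:
        pairs = list(chrom_sizes)
    names = [c for c, _ in pairs]
    if len(set(names)) != len(names):
        dupes = sorted({c for c in names if names.count(c) > 1})
        raise ValueError(f"duplicate chromosome name(s): {dupes}")
    return GenomeGrid(dict(pairs), bin_size)


def bin_track(intervals: Iterable[tuple[str, int, int, float]] | pd.DataFrame,
              grid: GenomeGrid) -> np.ndarray:
    """Accumulate interval coverage into per-bin signal mass.

    Each bin receives the length-weighted sum of overlapping interval
    values, i.e. ``value * bp_overlap``; bins without coverage are 0.
    Intervals are 0-based half-open and must lie within their chromosome.
    """
    if isinstance(intervals, pd.DataFrame):
        rows = intervals.itertuples(index=False)
    else:
        rows = iter(intervals)
    out = np.zeros(grid.n_bins, dtype=float)
    bs = grid.bin_size
    for chrom, start, end, value in rows:
        if chrom not in grid.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r} in coverage interval")
        size = grid.chrom_sizes[chrom]
        if start < 0 or end > size:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds [0, {size})"
            )
        if end <= start:
            continue
        off = grid.offset(chrom)
        b0 = start // bs
        b1 = (end - 1) // bs
        if b0 == b1:
            out[off + b0] += value * (end - start)
            continue
        # first / middle / last bins of a multi-bin interval
        out[off + b0] += value * ((b0 + 1) * bs - start)
        if b1 > b0 + 1:
            out[off + b0 + 1: off + b1] += value * bs
        out[off + b1] += value * (end - b1 * bs)
    return out
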