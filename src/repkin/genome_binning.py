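"""Fixed-width genomic tiling and per-interval feature tracks.

All downstream track statistics share one coordinate frame: the genome tiled
into non-overlapping, half-open intervals of a fixed width (default 10 kb).
Annotations, sequence composition and read coverage are projected onto that
grid as numeric tracks with explicit missing values.

Coordinates are 0-based half-open throughout (BED convention); 1-based
inclusive sources (RepeatMasker ``.out``) are converted on read in
:mod:`repkin.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WIDTH = 10_000

__all__ = [
    "DEFAULT_WIDTH",
    "IntervalGrid",
    "FeatureTrack",
    "bin_genome",
    "count_elements",
    "gc_track",
    "rpkm_track",
]


@dataclass(frozen=True)
class IntervalGrid:
    """Non-overlapping tiling of a genome into half-open intervals.

    Per chromosome there are ``ceil(length / width)`` intervals; the terminal
    interval may be shorter than ``width`` so that the union of intervals
    covers ``[0, length)`` exactly. Chromosomes keep the order in which they
    were supplied.
    """

    chrom_sizes: dict[str, int]
    width: int
    chroms: np.ndarray = field(repr=False)   # per-interval chromosome name
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.starts.size

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def _offsets(self) -> dict[str, int]:
        off, total = {}, 0
        for chrom, size in self.chrom_sizes.items():
            off[chrom] = total
            total += -(-size // self.width)
        return off

    def locate(self, chrom: np.ndarray | list, pos: np.ndarray | list) -> np.ndarray:
        """Map positions to global interval indices; -1 for off-grid points.

        ``pos`` is 0-based; a position belongs to the interval whose half-open
        range contains it.
        """
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        offsets = self._offsets()
        out = np.full(pos.shape, -1, dtype=np.int64)
        for c in np.unique(chrom):
            size = self.chrom_sizes.get(c)
            if size is None:
                continue
            sel = chrom == c
            p = pos[sel]
            ok = (p >= 0) & (p < size)
            idx = np.where(ok, offsets[c] + p // self.width, -1)
            out[sel] = idx
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends}
        )


@dataclass
class FeatureTrack:
    """One numeric value per grid interval.

    ``values`` is a float array aligned with ``grid``; missing values are
    NaN, never a silent zero. ``meta`` carries bookkeeping such as the number
    of annotations skipped because their chromosome is absent from the grid.
    """

    grid: IntervalGrid
    label: str
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError(
                f"track {self.label!r}: {self.values.shape[0]} values for "
                f"{len(self.grid)} intervals"
            )

    def __len__(self) -> int:
        return self.values.size


def bin_genome(chrom_sizes: dict[str, int], width: int = DEFAULT_WIDTH) -> IntervalGrid:
    """Tile every chromosome into fixed-width half-open intervals.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp, in the desired order.
    width
        Interval width in bp. The terminal interval of each chromosome is
        truncated to the chromosome end.
    """
    if not chrom_sizes:
        raise ValueError("no chromosomes")
    if width <= 0:
        raise ValueError(f"interval width must be positive, got {width}")
    chroms, starts, ends = [], [], []
    for chrom, size in chrom_sizes.items():
        size = int(size)
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        s = np.arange(0, size, width, dtype=np.int64)
        e = np.minimum(s + width, size)
        chroms.append(np.full(s.size, chrom, dtype=object))
        starts.append(s)
        ends.append(e)
    return IntervalGrid(
        chrom_sizes={c: int(v) for c, v in chrom_sizes.items()},
        width=int(width),
        chroms=np.concatenate(chroms),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
    )


def count_elements(
    grid: IntervalGrid,
    annotations: pd.DataFrame,
    class_filter: str | None = None,
) -> FeatureTrack:
    """Count annotated elements per interval (copy-number track).

    Each element is assigned to exactly one interval by its midpoint
    ``(start + end) // 2`` under half-open lookup, so boundary-spanning
    copies are never double counted. Annotations on chromosomes absent from
    the grid are skipped with a warning; the skip count is recorded in
    ``meta["n_skipped"]``.
    """
    ann = annotations
    if class_filter is not None:
        ann = ann[ann["repeat_class"] == class_filter]
    label = class_filter if class_filter is not None else "elements"
    values = np.zeros(len(grid), dtype=float)
    if len(ann):
        if (ann["start"] >= ann["end"]).any():
            raise ValueError("annotation with start >= end")
        mid = (ann["start"].to_numpy() + ann["end"].to_numpy()) // 2
        idx = grid.locate(ann["chrom"].to_numpy(), mid)
        n_skipped = int((idx < 0).sum())
        if n_skipped:
            warnings.warn(
                f"{n_skipped} annotation(s) on chromosomes absent from the grid "
                "were skipped",
                stacklevel=2,
            )
        np.add.at(values, idx[idx >= 0], 1.0)
    else:
        n_skipped = 0
    return FeatureTrack(grid, label, values, meta={"n_skipped": n_skipped})


def gc_track(grid: IntervalGrid, genome) -> FeatureTrack:
    """Per-interval GC fraction from a genome sequence.

    ``genome`` is a :class:`pyfaidx.Fasta` (or any mapping of chromosome name
    to sliceable sequence). GC = (#G + #C) / (#A + #C + #G + #T), case
    insensitive; intervals with no unambiguous base (all N) are missing.
    """
    for chrom in grid.chrom_sizes:
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} missing from genome sequence")
    values = np.full(len(grid), np.nan)
    for i in range(len(grid)):
        seq = str(genome[grid.chroms[i]][grid.starts[i]:grid.ends[i]]).upper()
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        if gc + at > 0:
            values[i] = gc / (gc + at)
    return FeatureTrack(grid, "GC", values)


def rpkm_track(
    grid: IntervalGrid,
    read_placements: pd.DataFrame,
    total_mapped_reads: int,
    label: str = "RPKM",
) -> FeatureTrack:
    """Reads per kilobase per million mapped reads, per interval.

    Placements are counted as single points at their 5' position
    (``pos`` column, 0-based); every placement of a multi-mapped read
    contributes. The true interval length is used, so terminal partial
    intervals are normalized by their actual span.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if (grid.lengths <= 0).any():
        raise ValueError("zero-length interval in grid")
    counts = np.zeros(len(grid), dtype=float)
    if len(read_placements):
        idx = grid.locate(
            read_placements["chrom"].to_numpy(), read_placements["pos"].to_numpy()
        )
        np.add.at(counts, idx[idx >= 0], 1.0)
    kb = grid.lengths / 1e3
    per_million = total_mapped_reads / 1e6
    return FeatureTrack(grid, label, counts / (kb * per_million))
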