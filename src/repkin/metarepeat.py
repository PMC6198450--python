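"""Metarepetitive-element accounting of (multi-mapped) sequencing reads.

Reads from repetitive DNA rarely map uniquely, so conventional coverage
analyses under-represent them. Here every read — including multi-mapped ones —
is assigned to a repeat class by a strict signature rule:

* a read whose placements all overlap annotation of one single repeat class
  carries that class's signature and is counted into it (even if the
  placements hit many distinct copies);
* placements overlapping two or more distinct classes make the signature
  ambiguous and the read is discarded;
* a read with no placement overlapping any repeat is non-repetitive.

Per-class counts normalized to the total of single-signature repeat reads
give the "metarepetitive element" coverage fractions; ratios of fractions
across timepoints give relative enrichment during the damage response.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "DISCARD",
    "NONREPEAT",
    "AlignedRead",
    "RepeatClassIndex",
    "RepeatClassCounts",
    "classify_read",
    "count_reads",
    "metarepeat_fractions",
    "relative_enrichment",
]

#: Sentinel outcomes of :func:`classify_read`.
DISCARD = "DISCARD"
NONREPEAT = "NONREPEAT"


@dataclass(frozen=True)
class AlignedRead:
    """A read with one or more genomic placements (half-open intervals)."""

    read_id: str
    placements: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        if not self.placements:
            raise ValueError(f"read {self.read_id!r} has no placements")


class RepeatClassIndex:
    """Interval index of repeat annotations for overlap queries.

    Parameters
    ----------
    annotations
        DataFrame with ``chrom``, ``start``, ``end`` and ``repeat_class``
        (half-open coordinates).
    grouping
        Optional map from annotation class/family names to reported classes
        (e.g., RepeatMasker families -> {Alu, LINE, SAT, LTR}). Annotation
        rows whose class is absent from the map are ignored, i.e., treated
        as non-repeat for the signature rule.
    """

    def __init__(self, annotations: pd.DataFrame, grouping: dict[str, str] | None = None):
        self.grouping = dict(grouping) if grouping else None
        self._trees: dict[str, IntervalTree] = {}
        self.classes: set[str] = set()
        for row in annotations.itertuples(index=False):
            cls = row.repeat_class
            if self.grouping is not None:
                cls = self.grouping.get(cls)
                if cls is None:
                    continue
            if row.start >= row.end:
                raise ValueError("annotation with start >= end")
            self._trees.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end, cls
            )
            self.classes.add(cls)

    def overlapping_classes(self, chrom: str, start: int, end: int) -> set[str]:
        """Classes whose annotation overlaps [start, end) by >= 1 bp."""
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


@dataclass
class RepeatClassCounts:
    """Per-timepoint outcome of classifying a read set."""

    timepoint: str
    counts: Counter = field(default_factory=Counter)
    n_nonrepeat: int = 0
    n_discarded: int = 0

    @property
    def n_counted(self) -> int:
        return sum(self.counts.values())

    @property
    def n_total(self) -> int:
        return self.n_counted + self.n_nonrepeat + self.n_discarded


def classify_read(
    read: AlignedRead,
    index: RepeatClassIndex,
    mixed_policy: str = "discard",
) -> str:
    """Assign a read to a repeat class, NONREPEAT or DISCARD.

    Any >= 1 bp overlap between a placement and an annotation counts as that
    placement being annotated with the class. ``mixed_policy`` controls reads
    whose placements mix exactly one repeat class with non-repeat positions:
    ``"discard"`` (default: the signature is not purely single-class) or
    ``"count"`` (assign the repeat class anyway).
    """
    if mixed_policy not in ("discard", "count"):
        raise ValueError(f"unknown mixed_policy {mixed_policy!r}")
    classes: set[str] = set()
    any_nonrepeat = False
    for chrom, start, end in read.placements:
        hit = index.overlapping_classes(chrom, start, end)
        if hit:
            classes |= hit
        else:
            any_nonrepeat = True
    if not classes:
        return NONREPEAT
    if len(classes) > 1:
        return DISCARD
    if any_nonrepeat and mixed_policy == "discard":
        return DISCARD
    return next(iter(classes))


def count_reads(
    reads,
    index: RepeatClassIndex,
    timepoint: str = "",
    mixed_policy: str = "discard",
) -> RepeatClassCounts:
    """Classify a read set and tally per-class counts.

    Conservation holds by construction:
    ``n_counted + n_nonrepeat + n_discarded == len(reads)``.
    """
    out = RepeatClassCounts(timepoint=timepoint)
    for read in reads:
        cls = classify_read(read, index, mixed_policy)
        if cls == NONREPEAT:
            out.n_nonrepeat += 1
        elif cls == DISCARD:
            out.n_discarded += 1
        else:
            out.counts[cls] += 1
    return out


def metarepeat_fractions(
    class_counts: RepeatClassCounts,
    classes: list[str] | None = None,
) -> dict[str, float]:
    """Per-class read fractions over single-signature repeat reads.

    The denominator is the total count over the reported ``classes``
    (default: every class observed); non-repeat and discarded reads are
    excluded, so the fractions sum to 1.
    """
    counts = class_counts.counts
    if classes is None:
        classes = sorted(counts)
    total = sum(counts.get(c, 0) for c in classes)
    if total <= 0:
        raise ValueError("no classifiable reads")
    return {c: counts.get(c, 0) / total for c in classes}


def relative_enrichment(
    counts_t: RepeatClassCounts,
    counts_baseline: RepeatClassCounts,
    classes: list[str] | None = None,
) -> dict[str, float]:
    """Per-class fraction ratio of a timepoint over the baseline.

    A fraction ratio is invariant to library size, which raw-count ratios
    are not. A class absent from the baseline yields a missing (NaN) ratio
    with a warning rather than an exception.
    """
    if classes is None:
        classes = sorted(set(counts_t.counts) | set(counts_baseline.counts))
    frac_t = metarepeat_fractions(counts_t, classes)
    frac_b = metarepeat_fractions(counts_baseline, classes)
    out: dict[str, float] = {}
    for c in classes:
        if frac_b[c] == 0:
            warnings.warn(f"class {c!r} has zero baseline fraction", stacklevel=2)
            out[c] = float("nan")
        else:
            out[c] = frac_t[c] / frac_b[c]
    return out
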