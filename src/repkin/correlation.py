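"""Spearman correlation matrices between feature tracks, with stratification.

Genome-wide association between repeat abundance and chromatin / replication
tracks is summarized by Spearman's rho per track pair, computed on the shared
interval grid after pairwise removal of missing intervals. Intervals can be
stratified into repeat-rich and repeat-poor subsets (e.g., > 10 L1 copies per
10-kb interval vs none) and each stratum correlated separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from repkin.genome_binning import FeatureTrack

__all__ = [
    "SpearmanResult",
    "CorrelationMatrix",
    "StratifiedSelection",
    "spearman_rho",
    "correlation_matrix",
    "stratify_intervals",
    "stratified_matrix",
]


class SpearmanResult(NamedTuple):
    rho: float
    pvalue: float
    n_used: int
    reason: str | None = None


@dataclass
class CorrelationMatrix:
    """Spearman rho / p-value / n-used per (row track, column track) cell."""

    rho: pd.DataFrame
    pvalue: pd.DataFrame
    n_used: pd.DataFrame
    reasons: pd.DataFrame

    @property
    def row_labels(self) -> list[str]:
        return list(self.rho.index)

    @property
    def col_labels(self) -> list[str]:
        return list(self.rho.columns)


@dataclass
class StratifiedSelection:
    """Interval index sets for repeat-rich and repeat-poor strata."""

    rich_indices: np.ndarray
    poor_indices: np.ndarray
    threshold_rich: float = 10
    threshold_poor: float = 0


def spearman_rho(x, y) -> SpearmanResult:
    """Spearman rank correlation with pairwise missing-value removal.

    Rho is the Pearson correlation of average fractional ranks (ties share
    their mean rank); the p-value uses the large-sample t approximation.
    Degenerate inputs (fewer than 3 complete pairs, or a constant vector)
    yield a missing rho with a reason code instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[keep], y[keep]
    n = xs.size
    if n < 3:
        return SpearmanResult(np.nan, np.nan, n, "too_few_pairs")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return SpearmanResult(np.nan, np.nan, n, "constant_input")
    rho, p = stats.spearmanr(xs, ys)
    return SpearmanResult(float(rho), float(p), n, None)


class _LabeledValues:
    """Track-like view carrying a label, used for stratified subsets."""

    def __init__(self, label: str, values: np.ndarray):
        self.label = label
        self.values = values


def _track_values(track) -> np.ndarray:
    if isinstance(track, (FeatureTrack, _LabeledValues)):
        return np.asarray(track.values, dtype=float)
    return np.asarray(track, dtype=float)


def _track_label(track, i: int) -> str:
    if isinstance(track, (FeatureTrack, _LabeledValues)):
        return track.label
    return f"track{i}"


def correlation_matrix(
    tracks_rows: Sequence, tracks_cols: Sequence | None = None
) -> CorrelationMatrix:
    """Cell-wise Spearman correlation between two sets of tracks.

    All tracks must share one grid (equivalently, one length). When
    ``tracks_cols`` is omitted the row set is correlated against itself.
    """
    if tracks_cols is None:
        tracks_cols = tracks_rows
    rows = [_track_values(t) for t in tracks_rows]
    cols = [_track_values(t) for t in tracks_cols]
    row_labels = [_track_label(t, i) for i, t in enumerate(tracks_rows)]
    col_labels = [_track_label(t, i) for i, t in enumerate(tracks_cols)]
    n = {v.size for v in rows} | {v.size for v in cols}
    if len(n) != 1:
        raise ValueError("tracks do not share a grid (mismatched lengths)")
    rho = np.full((len(rows), len(cols)), np.nan)
    pval = np.full_like(rho, np.nan)
    nused = np.zeros(rho.shape, dtype=int)
    reasons = np.full(rho.shape, None, dtype=object)
    for i, xv in enumerate(rows):
        for j, yv in enumerate(cols):
            r = spearman_rho(xv, yv)
            rho[i, j], pval[i, j], nused[i, j] = r.rho, r.pvalue, r.n_used
            reasons[i, j] = r.reason
    mk = lambda a: pd.DataFrame(a, index=row_labels, columns=col_labels)
    return CorrelationMatrix(mk(rho), mk(pval), mk(nused), mk(reasons))


def stratify_intervals(
    count_track,
    threshold_rich: float = 10,
    threshold_poor: float = 0,
) -> StratifiedSelection:
    """Split grid intervals into repeat-rich and repeat-poor index sets.

    Rich: count strictly greater than ``threshold_rich`` (default > 10 copies
    per interval). Poor: count exactly equal to ``threshold_poor`` (default
    no copies). The two sets are disjoint by construction for the defaults.
    """
    values = _track_values(count_track)
    rich = np.flatnonzero(values > threshold_rich)
    poor = np.flatnonzero(values == threshold_poor)
    if rich.size == 0:
        warnings.warn("rich stratum is empty", stacklevel=2)
    if poor.size == 0:
        warnings.warn("poor stratum is empty", stacklevel=2)
    return StratifiedSelection(rich, poor, threshold_rich, threshold_poor)


def stratified_matrix(
    tracks_rows: Sequence,
    tracks_cols: Sequence | None,
    selection: StratifiedSelection,
) -> tuple[CorrelationMatrix, CorrelationMatrix]:
    """Correlation matrices restricted to the rich and poor strata."""
    if tracks_cols is None:
        tracks_cols = tracks_rows

    def restrict(tracks, idx):
        return [_subset_track(t, idx) for t in tracks]

    rich = correlation_matrix(
        restrict(tracks_rows, selection.rich_indices),
        restrict(tracks_cols, selection.rich_indices),
    )
    poor = correlation_matrix(
        restrict(tracks_rows, selection.poor_indices),
        restrict(tracks_cols, selection.poor_indices),
    )
    return rich, poor


def _subset_track(track, idx: np.ndarray):
    values = _track_values(track)[idx]
    if isinstance(track, (FeatureTrack, _LabeledValues)):
        return _LabeledValues(track.label, values)
    return values
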