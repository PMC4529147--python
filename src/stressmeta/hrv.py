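"""Windowed heart-rate variability with bootstrap cluster inference.

HRV is the sample standard deviation of heart rate inside non-overlapping
one-minute windows.  Per-participant series are optionally smoothed with
locally weighted linear regression (tricube weights), then two groups are
compared window-by-window: participants are resampled with replacement
within each group (respecting within-participant autocorrelation), 95%
percentile bands are formed for each group mean and for their difference,
and clusters are maximal runs of windows whose two-sided bootstrap p falls
below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import AlignmentError, DomainError
from .types import HeartRateTrace


@dataclass(frozen=True)
class HRVSeries:
    participant_id: str
    window_starts_s: np.ndarray
    sd_bpm: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.window_starts_s, dtype=float)
        sd = np.asarray(self.sd_bpm, dtype=float)
        object.__setattr__(self, "window_starts_s", starts)
        object.__setattr__(self, "sd_bpm", sd)
        if starts.size != sd.size:
            raise DomainError("window_starts_s and sd_bpm must have equal length")
        if np.any(sd < 0):
            raise DomainError("sd_bpm must be non-negative")


@dataclass(frozen=True)
class ClusterResult:
    """Two-group comparison over a shared window grid.

    ``clusters`` holds (start, end) window indices (inclusive) of maximal
    runs with ``per_window_p < alpha``.  ``band_low``/``band_high`` are
    (2, n_windows) arrays of the 95% bootstrap band for each group mean
    (row 0 = first group passed, row 1 = second); ``diff_band_low/high``
    bound the difference (second minus first).
    """

    clusters: tuple
    per_window_p: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    diff_band_low: np.ndarray
    diff_band_high: np.ndarray
    observed_diff: np.ndarray
    alpha: float
    n_boot: int


def windowed_sd(trace: HeartRateTrace, window_s: int = 60) -> HRVSeries:
    """Per-window sample SD (denominator n-1); trailing partial window dropped."""
    if window_s <= 0:
        raise DomainError("window_s must be positive")
    per_window = int(round(window_s / trace.dt_s))
    if per_window < 2:
        raise DomainError("window too short for the sampling rate")
    n_windows = trace.bpm.size // per_window
    if n_windows < 1:
        raise DomainError("trace shorter than one window")
    chunk = trace.bpm[: n_windows * per_window].reshape(n_windows, per_window)
    sd = chunk.std(axis=1, ddof=1)
    starts = trace.times_s[0] + np.arange(n_windows) * float(window_s)
    return HRVSeries(
        participant_id=trace.participant_id, window_starts_s=starts, sd_bpm=sd
    )


def smooth_series(series: HRVSeries, span: float = 0.3) -> HRVSeries:
    """LOWESS-smooth the windowed-SD series (local linear, tricube weights)."""
    n = series.sd_bpm.size
    if n < 5:
        raise DomainError("need at least 5 windows to smooth")
    if not 0 < span <= 1:
        raise DomainError("span must lie in (0, 1]")
    if span * n < 3:
        raise DomainError(
            f"span {span} covers fewer than 3 of {n} points; increase span"
        )
    smoothed = lowess(
        series.sd_bpm,
        series.window_starts_s,
        frac=span,
        it=0,
        return_sorted=False,
    )
    smoothed = np.maximum(smoothed, 0.0)
    return HRVSeries(
        participant_id=series.participant_id,
        window_starts_s=series.window_starts_s.copy(),
        sd_bpm=smoothed,
    )


def _stack_group(series: Sequence[HRVSeries], grid: np.ndarray) -> np.ndarray:
    rows = []
    for s in series:
        if s.sd_bpm.size != grid.size or not np.allclose(s.window_starts_s, grid):
            raise AlignmentError(
                f"participant {s.participant_id} is not on the shared window grid"
            )
        rows.append(s.sd_bpm)
    mat = np.vstack(rows)
    # canonical row order: makes the bootstrap (hence the cluster output)
    # exactly invariant to the order participants are passed in
    order = np.lexsort(mat.T[::-1])
    return mat[order]


def group_cluster_test(
    series_by_group: tuple[Sequence[HRVSeries], Sequence[HRVSeries]],
    n_boot: int = 5000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    span: float | None = None,
) -> ClusterResult:
    """Bootstrap two-group comparison of windowed HRV.

    Parameters
    ----------
    series_by_group
        Two collections of :class:`HRVSeries` on a common window grid.
    span
        If given, each series is LOWESS-smoothed with this span first.
    """
    group_a, group_b = series_by_group
    if len(group_a) < 2 or len(group_b) < 2:
        raise DomainError("each group needs at least 2 participants")
    if n_boot < 1:
        raise DomainError("n_boot must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()

    if span is not None:
        group_a = [smooth_series(s, span) for s in group_a]
        group_b = [smooth_series(s, span) for s in group_b]

    grid = np.asarray(group_a[0].window_starts_s, dtype=float)
    a = _stack_group(group_a, grid)
    b = _stack_group(group_b, grid)

    idx_a = rng.integers(0, a.shape[0], size=(n_boot, a.shape[0]))
    idx_b = rng.integers(0, b.shape[0], size=(n_boot, b.shape[0]))
    means_a = a[idx_a].mean(axis=1)  # (n_boot, W)
    means_b = b[idx_b].mean(axis=1)
    diffs = means_b - means_a

    q = (2.5, 97.5)
    band_low = np.vstack(
        [np.percentile(means_a, q[0], axis=0), np.percentile(means_b, q[0], axis=0)]
    )
    band_high = np.vstack(
        [np.percentile(means_a, q[1], axis=0), np.percentile(means_b, q[1], axis=0)]
    )
    diff_low = np.percentile(diffs, q[0], axis=0)
    diff_high = np.percentile(diffs, q[1], axis=0)

    frac_le = (diffs <= 0).mean(axis=0)
    frac_ge = (diffs >= 0).mean(axis=0)
    p = 2.0 * np.minimum(frac_le, frac_ge)
    p = np.clip(p, 1.0 / n_boot, 1.0)

    below = p < alpha
    clusters = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append((start, i - 1))
            start = None
    if start is not None:
        clusters.append((start, below.size - 1))

    return ClusterResult(
        clusters=tuple(clusters),
        per_window_p=p,
        band_low=band_low,
        band_high=band_high,
        diff_band_low=diff_low,
        diff_band_high=diff_high,
        observed_diff=b.mean(axis=0) - a.mean(axis=0),
        alpha=alpha,
        n_boot=n_boot,
    )
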