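"""Assembling procedures for repeated square-wave transitions.

Two conventions are implemented for combining Nr repetitions before fitting:

* **stacking** — the native breaths of all repetitions are pooled unmodified
  into one sample (sorted by time); every datum is conserved, so the sample
  size — and hence the degrees of freedom — grows with Nr.

* **1-s-bins** — each repetition is first resampled onto an even grid by
  *cloning* the nearest native value (an oversampling step), then the grids
  are averaged bin-wise.  The sample size is the grid length, independent
  of Nr; averaging smooths the fluctuations of the native data.
"""

from __future__ import annotations

import numpy as np

from .series import AssembledSeries, BreathSeries, GridSeries

__all__ = ["resample_to_bins", "stack", "average_bins", "assemble"]


def resample_to_bins(series: BreathSeries, interval_s: float = 1.0) -> GridSeries:
    """Clone-resample one repetition onto a grid of multiples of ``interval_s``.

    The grid consists of integer multiples of the interval covering the
    native span (anchored so that t = 0 is a grid node, extending into the
    recorded baseline).  Each grid point takes a copy of the value of the
    nearest native breath; when a grid time is exactly midway between two
    breaths, the earlier breath wins.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    t, v = series.times, series.values
    if len(t) == 0:
        raise ValueError("empty breath series")
    k_lo = int(np.ceil(round(t[0] / interval_s, 9)))
    k_hi = int(np.floor(round(t[-1] / interval_s, 9)))
    if k_hi < k_lo:  # no grid node inside the span (interval wider than span)
        k_lo = k_hi = int(np.round(t[0] / interval_s))
    grid = np.arange(k_lo, k_hi + 1, dtype=float) * interval_s

    # nearest native breath; ties (equidistant) resolve to the earlier breath
    right = np.searchsorted(t, grid)
    left = np.clip(right - 1, 0, len(t) - 1)
    right = np.clip(right, 0, len(t) - 1)
    use_right = np.abs(t[right] - grid) < np.abs(grid - t[left])
    idx = np.where(use_right, right, left)
    return GridSeries(interval_s=interval_s, times=grid, values=v[idx])


def stack(series_list: list[BreathSeries]) -> AssembledSeries:
    """Pool the native data of the repetitions, sorted by time, unmodified.

    Stable sort: coincident times keep repetition order.  The multiset of
    (time, value) pairs is exactly conserved.
    """
    if len(series_list) == 0:
        raise ValueError("need at least one series to stack")
    times = np.concatenate([s.times for s in series_list])
    values = np.concatenate([s.values for s in series_list])
    order = np.argsort(times, kind="stable")
    return AssembledSeries(
        procedure="stacking", times=times[order], values=values[order],
        nr=len(series_list),
    )


def average_bins(grid_list: list[GridSeries]) -> AssembledSeries:
    """Bin-wise arithmetic mean of evenly resampled repetitions.

    All grids must share the interval and the t = 0 anchor.  Edge bins
    missing in some repetitions are averaged over the repetitions that have
    them; ``n_averaged`` records the per-bin count.  The output length is
    the union grid length, independent of the number of repetitions.
    """
    if len(grid_list) == 0:
        raise ValueError("need at least one grid to average")
    interval = grid_list[0].interval_s
    if any(abs(g.interval_s - interval) > 1e-9 for g in grid_list):
        raise ValueError("all grids must share the same interval_s")

    keys = [np.round(g.times / interval).astype(int) for g in grid_list]
    k_lo = min(k[0] for k in keys)
    k_hi = max(k[-1] for k in keys)
    n_bins = k_hi - k_lo + 1
    total = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=int)
    for g, k in zip(grid_list, keys):
        pos = k - k_lo
        total[pos] += g.values
        count[pos] += 1
    values = total / np.maximum(count, 1)
    times = np.arange(k_lo, k_hi + 1, dtype=float) * interval
    present = count > 0
    return AssembledSeries(
        procedure="bins", times=times[present], values=values[present],
        nr=len(grid_list), interval_s=interval, n_averaged=count[present],
    )


def assemble(series_list: list[BreathSeries], procedure: str,
             interval_s: float = 1.0) -> AssembledSeries:
    """Assemble repetitions with either procedure ('stacking' or 'bins')."""
    if procedure == "stacking":
        return stack(series_list)
    if procedure == "bins":
        return average_bins([resample_to_bins(s, interval_s) for s in series_list])
    raise ValueError(f"unknown procedure {procedure!r}")
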