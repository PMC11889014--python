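"""Independent brute-force oracle for the mono-exponential fit.

For fixed (tau, Td) the model is linear in (A_b, dA); the profiled residual
sum of squares is therefore available in closed form from the 2x2 normal
equations.  The oracle minimizes the profiled RSS over a dense (tau, Td)
grid and refines by repeated grid zooming — no gradient-based optimizer is
involved, so it is independent of the least-squares path it checks.
"""

from __future__ import annotations

import numpy as np


def _profiled_rss(t, y, tau_grid, td_grid):
    """Profiled RSS over all (tau, td) grid combinations, vectorized.

    Returns (rss, a, b) arrays of shape (n_tau, n_td) where a = A_b, b = dA.
    """
    t = t[None, None, :]
    tau = tau_grid[:, None, None]
    td = td_grid[None, :, None]
    r = -np.expm1(-np.maximum(t - td, 0.0) / tau)  # (n_tau, n_td, n)

    n = t.shape[-1]
    s1r = r.sum(axis=-1)
    srr = (r * r).sum(axis=-1)
    s1y = y.sum()
    sry = (r * y).sum(axis=-1)
    syy = float(y @ y)

    det = n * srr - s1r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (n * sry - s1r * s1y) / det
        a = (s1y - b * s1r) / n
    rss = syy - a * s1y - b * sry
    rss[~np.isfinite(rss)] = np.inf
    return rss, a, b


def brute_force_fit(times, values, dtr_s=0.0, include_baseline=True,
                    tau_range=(5.0, 100.0), td_range=(-5.0, 30.0),
                    n_grid=61, n_zoom=5):
    """Grid-search fit; returns (a_b, da, tau, td, rss).

    Final tau/td resolution ~ (range width / n_grid) * (4 / n_grid)**n_zoom.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    mask = (t < 0) | (t >= dtr_s) if include_baseline else t >= dtr_s
    t, y = t[mask], y[mask]

    tau_lo, tau_hi = tau_range
    td_lo, td_hi = td_range
    best = None
    for _ in range(n_zoom + 1):
        tau_grid = np.linspace(tau_lo, tau_hi, n_grid)
        td_grid = np.linspace(td_lo, td_hi, n_grid)
        rss, a, b = _profiled_rss(t, y, tau_grid, td_grid)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        best = (float(a[i, j]), float(b[i, j]),
                float(tau_grid[i]), float(td_grid[j]), float(rss[i, j]))
        tau_step = tau_grid[1] - tau_grid[0]
        td_step = td_grid[1] - td_grid[0]
        tau_lo = max(0.1, tau_grid[i] - 2 * tau_step)
        tau_hi = tau_grid[i] + 2 * tau_step
        td_lo = td_grid[j] - 2 * td_step
        td_hi = td_grid[j] + 2 * td_step
    return best
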