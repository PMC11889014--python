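"""Mono-exponential VO2 kinetics fitting by nonlinear least squares.

The model object / results object pair follows the statsmodels convention:
``MonoExpKinetics`` holds the data and fitting window, its :meth:`fit`
returns a :class:`KineticsFitResult` carrying estimates, asymptotic standard
errors (ASEs), degrees of freedom, residual sum of squares and a
:meth:`~KineticsFitResult.summary` table.

Model
-----
    VO2(t) = A_b                                  for t <  Td
    VO2(t) = A_b + dA * (1 - exp(-(t - Td)/tau))  for t >= Td

The exponential phase is only defined from the time delay onwards; the
piecewise constant extension lets recorded baseline breaths constrain A_b.
The join makes the objective non-smooth in Td, so the Jacobian is obtained
by finite differences rather than analytically.

The fitting window always keeps all baseline points (t < 0) and excludes the
early transient t in [0, dTr) — the conventional guard against the
cardiodynamic phase.  ASEs come from the usual large-sample covariance
s^2 * (J'J)^-1 with s^2 = RSS / df and df = n - 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import KineticParams, Protocol

__all__ = [
    "model_predict",
    "initial_values",
    "MonoExpKinetics",
    "KineticsFitResult",
    "fit_kinetics",
    "sweep_dtr",
    "DEFAULT_DTR_VALUES",
]

# dTr sweep convention: 41 fits, excluding 0..40 s after onset
DEFAULT_DTR_VALUES: tuple[int, ...] = tuple(range(41))

_N_PARAMS = 4
_TAU_BOUNDS = (0.1, 200.0)


def _profiled_rss_grid(t: np.ndarray, y: np.ndarray, tau_grid: np.ndarray,
                       td_grid: np.ndarray):
    """Profiled RSS over a (tau, td) grid; (A_b, dA) solved linearly per node.

    For fixed (tau, td) the model is linear in (A_b, dA), so the conditional
    minimum of the RSS is available from the 2x2 normal equations.  Used to
    escape the shallow local minima the piecewise kink at Td creates.
    """
    tt = t[None, None, :]
    tau = tau_grid[:, None, None]
    td = td_grid[None, :, None]
    r = -np.expm1(-np.maximum(tt - td, 0.0) / tau)

    n = len(t)
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


def model_predict(params: KineticParams | np.ndarray, t) -> np.ndarray:
    """Evaluate the piecewise mono-exponential model at times ``t`` (s)."""
    if isinstance(params, KineticParams):
        a_b, da, tau, td = params.a_b, params.da, params.tau, params.td
    else:
        a_b, da, tau, td = params
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    t = np.asarray(t, dtype=float)
    dt = t - td
    with np.errstate(over="ignore"):
        rise = -np.expm1(-np.maximum(dt, 0.0) / tau)
    return a_b + da * rise


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    """Accept any of the package's series containers or a (times, values) pair."""
    if hasattr(series, "times") and hasattr(series, "values"):
        return np.asarray(series.times, float), np.asarray(series.values, float)
    times, values = series
    return np.asarray(times, float), np.asarray(values, float)


def initial_values(series, protocol: Protocol | None = None) -> KineticParams:
    """Standard starting values for the nonlinear regression.

    tau0 = 25 s and Td0 = 0 s; A_b0 is the mean over the 3 min of baseline
    just before onset, and dA0 the mean over the final 3 min of exercise
    (the steady state) minus A_b0.
    """
    protocol = protocol or Protocol()
    t, v = _series_arrays(series)
    base = (t >= protocol.baseline_start_s) & (t < 0.0)
    steady = (t >= protocol.exercise_end_s - 180.0) & (t <= protocol.exercise_end_s)
    if not base.any():
        raise ValueError("no baseline data (t < 0) to initialize A_b")
    if not steady.any():
        raise ValueError("no steady-state data (final 3 min) to initialize dA")
    a_b0 = float(v[base].mean())
    da0 = float(v[steady].mean()) - a_b0
    return KineticParams(a_b=a_b0, da=da0, tau=25.0, td=0.0)


@dataclass
class KineticsFitResult:
    """Nonlinear-regression output for one series and one fitting window."""

    params: KineticParams
    ase: np.ndarray          # asymptotic SEs, order (a_b, da, tau, td)
    df: int                  # degrees of freedom = n_points - 4
    n_points: int
    rss: float
    converged: bool
    dtr_s: float
    chi2: float | None = None       # rss / noise_sd^2, simulation mode only
    chi2_pvalue: float | None = None

    @property
    def bse(self) -> pd.Series:
        """Standard errors as a named Series (statsmodels-style alias)."""
        return pd.Series(self.ase, index=KineticParams.names)

    @property
    def s2(self) -> float:
        """Residual variance estimate RSS / df."""
        return self.rss / self.df

    def ase_for(self, name: str) -> float:
        return float(self.ase[KineticParams.names.index(name)])

    def estimate_for(self, name: str) -> float:
        return float(getattr(self.params, name))

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Per-parameter interval: estimate +/- t_df(alpha) * ASE, two-tailed."""
        tq = stats.t.ppf(0.5 + level / 2.0, self.df)
        est = self.params.as_array()
        return pd.DataFrame(
            {"lo": est - tq * self.ase, "hi": est + tq * self.ase},
            index=KineticParams.names,
        )

    def summary(self, level: float = 0.95) -> str:
        ci = self.conf_int(level)
        lines = [
            "Mono-exponential VO2 kinetics fit",
            "=" * 58,
            f"n points: {self.n_points:6d}    df: {self.df:6d}    dTr: {self.dtr_s:g} s",
            f"RSS: {self.rss:.6g}    s^2: {self.s2:.6g}    converged: {self.converged}",
        ]
        if self.chi2 is not None:
            lines.append(f"chi^2: {self.chi2:.4g}    p(chi^2): {self.chi2_pvalue:.4g}")
        lines.append("-" * 58)
        lines.append(f"{'param':>6} {'estimate':>12} {'ASE':>10} "
                     f"{'[' + format(level, '.0%'):>9} {'CI]':>10}")
        for i, name in enumerate(KineticParams.names):
            lines.append(
                f"{name:>6} {self.params.as_array()[i]:12.4f} {self.ase[i]:10.4f} "
                f"{ci['lo'].iloc[i]:10.3f} {ci['hi'].iloc[i]:10.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "a_b": self.params.a_b, "da": self.params.da,
            "tau": self.params.tau, "td": self.params.td,
            "ase_a_b": float(self.ase[0]), "ase_da": float(self.ase[1]),
            "ase_tau": float(self.ase[2]), "ase_td": float(self.ase[3]),
            "df": self.df, "n_points": self.n_points, "rss": self.rss,
            "converged": self.converged, "dtr_s": self.dtr_s,
        }
        if self.chi2 is not None:
            d["chi2"] = self.chi2
            d["chi2_pvalue"] = self.chi2_pvalue
        return d


class MonoExpKinetics:
    """Mono-exponential kinetics model bound to one VO2 series.

    Parameters
    ----------
    times, values : array-like
        Breath (or grid) timestamps in s relative to exercise onset, and VO2
        in ml·min⁻¹.  Any of the package's series containers can be passed
        through :meth:`from_series`.
    protocol : Protocol, optional
        Used only to locate the baseline and steady-state windows for the
        default starting values.
    include_baseline : bool
        Whether recorded baseline points (t < 0) enter the fitting window.
        On by default: A_b is estimable only from baseline.  The switch
        exposes the sensitivity of results to that convention.
    """

    def __init__(self, times, values, protocol: Protocol | None = None,
                 include_baseline: bool = True):
        self.times, self.endog = _series_arrays((times, values))
        if len(self.times) != len(self.endog):
            raise ValueError("times and values length mismatch")
        self.protocol = protocol or Protocol()
        self.include_baseline = include_baseline

    @classmethod
    def from_series(cls, series, **kwargs) -> "MonoExpKinetics":
        t, v = _series_arrays(series)
        return cls(t, v, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time_s",
                       value_col: str = "vo2_ml_min", **kwargs) -> "MonoExpKinetics":
        return cls(df[time_col].to_numpy(), df[value_col].to_numpy(), **kwargs)

    def predict(self, params: KineticParams, t=None) -> np.ndarray:
        return model_predict(params, self.times if t is None else t)

    def window_mask(self, dtr_s: float) -> np.ndarray:
        if dtr_s < 0:
            raise ValueError("dTr must be >= 0")
        after = self.times >= dtr_s
        if self.include_baseline:
            return (self.times < 0.0) | after
        return after

    def fit(self, dtr_s: float = 0.0, start: KineticParams | None = None,
            noise_sd: float | None = None) -> KineticsFitResult:
        """Least-squares fit over the window (t < 0) ∪ (t >= dTr).

        Levenberg–Marquardt-style trust-region minimization with tau bounded
        to (0.1, 200) s; finite-difference Jacobian.  ``noise_sd``, when the
        true noise SD is known (simulation), adds a chi-square fit check.
        """
        mask = self.window_mask(dtr_s)
        t, y = self.times[mask], self.endog[mask]
        n = len(t)
        if n < _N_PARAMS + 1:
            raise ValueError(f"fitting window has {n} points; need >= {_N_PARAMS + 1}")
        df = n - _N_PARAMS

        x0 = (start or initial_values((self.times, self.endog), self.protocol)).as_array()
        x0[2] = np.clip(x0[2], *_TAU_BOUNDS)

        def resid(theta):
            return model_predict(theta, t) - y

        lower = [-np.inf, -np.inf, _TAU_BOUNDS[0], -np.inf]
        upper = [np.inf, np.inf, _TAU_BOUNDS[1], np.inf]

        def solve(start):
            return optimize.least_squares(
                resid, start, bounds=(lower, upper), method="trf",
                xtol=1e-8, ftol=1e-8, gtol=1e-8,
                x_scale=[100.0, 100.0, 10.0, 5.0],
                max_nfev=200 * (_N_PARAMS + 1),
            )

        res = solve(x0)
        # the kink at Td makes the objective piecewise-smooth: scan the
        # profiled RSS on a local (tau, td) grid and restart if the first
        # pass stalled short of the global basin
        tau_hat, td_hat = res.x[2], res.x[3]
        tau_grid = np.linspace(max(_TAU_BOUNDS[0], 0.8 * tau_hat),
                               min(_TAU_BOUNDS[1], 1.2 * tau_hat), 21)
        td_grid = np.linspace(td_hat - 2.5, td_hat + 2.5, 41)
        rss_grid, a_grid, b_grid = _profiled_rss_grid(t, y, tau_grid, td_grid)
        i, j = np.unravel_index(np.argmin(rss_grid), rss_grid.shape)
        if rss_grid[i, j] < res.cost * 2.0 * (1.0 - 1e-12):
            restart = np.array([a_grid[i, j], b_grid[i, j],
                                tau_grid[i], td_grid[j]])
            res2 = solve(restart)
            if res2.cost < res.cost:
                res = res2

        rss = float(res.cost * 2.0)
        s2 = rss / df
        jtj = res.jac.T @ res.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(jtj)
        ase = np.sqrt(np.clip(np.diag(cov), 0.0, None))

        chi2 = chi2_p = None
        if noise_sd is not None and noise_sd > 0:
            chi2 = rss / noise_sd**2
            chi2_p = float(stats.chi2.sf(chi2, df))

        return KineticsFitResult(
            params=KineticParams.from_array(res.x),
            ase=ase, df=df, n_points=n, rss=rss,
            converged=bool(res.status > 0 and np.all(np.isfinite(res.x))),
            dtr_s=float(dtr_s), chi2=chi2, chi2_pvalue=chi2_p,
        )

    def fit_dtr_sweep(self, dtr_values=DEFAULT_DTR_VALUES,
                      start: KineticParams | None = None) -> list[KineticsFitResult]:
        """One fit per excluded period dTr (default 0..40 s, 41 fits)."""
        dtr_values = list(dtr_values)
        if any(d < 0 for d in dtr_values):
            raise ValueError("dTr values must be >= 0")
        if sorted(dtr_values) != dtr_values:
            raise ValueError("dTr values must be sorted ascending")
        return [self.fit(d, start=start) for d in dtr_values]


def fit_kinetics(series, dtr_s: float = 0.0, init: KineticParams | None = None,
                 protocol: Protocol | None = None,
                 include_baseline: bool = True,
                 noise_sd: float | None = None) -> KineticsFitResult:
    """Functional wrapper: fit any series container in one call."""
    model = MonoExpKinetics.from_series(series, protocol=protocol,
                                        include_baseline=include_baseline)
    return model.fit(dtr_s, start=init, noise_sd=noise_sd)


def sweep_dtr(series, dtr_values=DEFAULT_DTR_VALUES,
              init: KineticParams | None = None,
              protocol: Protocol | None = None) -> list[KineticsFitResult]:
    """Functional wrapper for the dTr sweep."""
    model = MonoExpKinetics.from_series(series, protocol=protocol)
    return model.fit_dtr_sweep(dtr_values, start=init)


def fits_to_frame(fits: list[KineticsFitResult], **extra) -> pd.DataFrame:
    """Flatten fit results to one row per fit; ``extra`` adds constant columns."""
    df = pd.DataFrame([f.to_dict() for f in fits])
    for k, v in extra.items():
        df[k] = v
    return df
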