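"""Confidence-interval construction and coverage experiments.

The question under study: are the asymptotic standard errors (ASEs) returned
by nonlinear regression of VO2 kinetics valid — i.e., does the interval

    estimate ± t_df(alpha) · ASE                       (the candidate CI)

contain the true parameter in ~alpha of cases?  Truth is either the known
generator value (simulation only) or the "surrogate of the true" value: the
parameter fitted after assembling *all* of a subject's repetitions with the
same procedure.  Coverage is the percentage of single-repetition CIs that
contain the truth, pooled over subjects and repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import assemble, resample_to_bins
from .kinetics import KineticsFitResult, MonoExpKinetics, fit_kinetics
from .params import BreathNoiseModel, KineticParams, Protocol, SubjectSampler
from .series import BreathSeries, Cohort, Subject
from .synth import generate_cohort

__all__ = [
    "ConfidenceInterval",
    "CoverageResult",
    "ASECurve",
    "confidence_interval",
    "surrogate_truth",
    "coverage",
    "run_coverage_experiment",
    "simulate_coverage",
    "pool_coverage",
    "coverage_to_frame",
    "fit_ase_vs_nr",
    "ase_vs_nr_table",
    "resampling_sweep",
]


@dataclass(frozen=True)
class ConfidenceInterval:
    """Candidate CI: estimate ± t_df(alpha)·ASE, two-tailed."""

    lo: float
    hi: float
    level: float
    df: int

    def contains(self, x: float, atol: float = 0.0) -> bool:
        """Closed interval: boundary ties count as covered.

        ``atol`` is a floating-point guard for degenerate (zero-width)
        intervals, where the estimate matches the truth only to optimizer
        precision; it is negligible against any real CI width.
        """
        return self.lo - atol <= x <= self.hi + atol


@dataclass
class CoverageResult:
    """Coverage of the candidate CIs for one procedure, parameter and dTr."""

    procedure: str
    parameter: str
    dtr_s: float
    n_cases: int
    n_covered: int
    n_excluded: int = 0  # non-converged fits dropped from both counts

    def __post_init__(self) -> None:
        if not (0 <= self.n_covered <= self.n_cases):
            raise ValueError("need 0 <= n_covered <= n_cases")

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.n_covered / self.n_cases


@dataclass(frozen=True)
class ASECurve:
    """Fit of ASE(Nr) = k / sqrt(Nr); k is the ASE extrapolated at Nr = 1."""

    k: float
    rss: float

    def predict(self, nr) -> np.ndarray:
        return self.k / np.sqrt(np.asarray(nr, dtype=float))


def confidence_interval(estimate: float, ase: float, df: int,
                        level: float = 0.95) -> ConfidenceInterval:
    """Two-tailed t interval around a nonlinear-regression estimate."""
    if ase < 0:
        raise ValueError("ase must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    half = stats.t.ppf(0.5 + level / 2.0, df) * ase
    return ConfidenceInterval(lo=estimate - half, hi=estimate + half,
                              level=level, df=df)


def surrogate_truth(subject_reps: list[BreathSeries], procedure: str,
                    dtr_s: float, interval_s: float = 1.0,
                    protocol: Protocol | None = None) -> KineticParams:
    """'Surrogate of the true' value: fit of all repetitions assembled together.

    The surrogate must be built with the *same* procedure as the fits it is
    compared against (stacking truth for stacking CIs, bin-averaged truth
    for 1-s-bins CIs).
    """
    if len(subject_reps) < 2:
        raise ValueError("surrogate truth needs >= 2 repetitions")
    assembled = assemble(subject_reps, procedure, interval_s)
    res = fit_kinetics(assembled, dtr_s, protocol=protocol)
    if not res.converged:
        raise RuntimeError(
            f"surrogate fit did not converge (procedure={procedure}, dTr={dtr_s})"
        )
    return res.params


def coverage(cis: list[ConfidenceInterval], truths, *, procedure: str = "",
             parameter: str = "", dtr_s: float = float("nan"),
             n_excluded: int = 0, atol: float = 0.0) -> CoverageResult:
    """Count CIs whose closed interval contains the matched truth."""
    truths = list(np.atleast_1d(truths))
    if len(cis) != len(truths):
        raise ValueError("cis and truths must have equal length")
    if len(cis) == 0:
        raise ValueError("need at least one case")
    atols = np.broadcast_to(np.asarray(atol, dtype=float), (len(cis),))
    n_cov = sum(ci.contains(tr, a) for ci, tr, a in zip(cis, truths, atols))
    return CoverageResult(procedure=procedure, parameter=parameter, dtr_s=dtr_s,
                          n_cases=len(cis), n_covered=int(n_cov),
                          n_excluded=n_excluded)


def _rep_models(subject: Subject, procedure: str, interval_s: float,
                protocol: Protocol | None) -> list[MonoExpKinetics]:
    """Per-repetition Nr=1 fit inputs: native breaths (stacking) or cloned grid (bins)."""
    out = []
    for rep in subject.reps:
        series = rep if procedure == "stacking" else resample_to_bins(rep, interval_s)
        out.append(MonoExpKinetics.from_series(series, protocol=protocol))
    return out


def run_coverage_experiment(
    cohort: Cohort,
    procedure: str,
    dtr_values=(20.0,),
    level: float = 0.95,
    truth_mode: str = "surrogate",
    interval_s: float = 1.0,
    protocol: Protocol | None = None,
    parameters: tuple[str, ...] = ("tau", "td"),
    numerical_atol: float = 1e-6,
) -> list[CoverageResult]:
    """Coverage of single-repetition CIs pooled over a cohort, per dTr.

    For every subject and every repetition: assemble at Nr = 1 with the
    procedure (i.e. native breaths for stacking, a cloned 1-s grid for
    bins), fit, and build the t-based CI for each requested parameter.
    Truth is the surrogate (all repetitions assembled, same procedure and
    same dTr) or the generator parameters.  Non-converged fits — and all of
    a subject's cases at a dTr whose surrogate fit fails — are excluded
    from numerator and denominator and counted in ``n_excluded``.
    """
    if procedure not in ("stacking", "bins"):
        raise ValueError(f"unknown procedure {procedure!r}")
    if truth_mode not in ("surrogate", "generator"):
        raise ValueError(f"unknown truth_mode {truth_mode!r}")
    if truth_mode == "surrogate" and any(len(s.reps) < 2 for s in cohort):
        raise ValueError("surrogate truth requires >= 2 repetitions per subject")

    per_subject = []
    for subject in cohort:
        models = _rep_models(subject, procedure, interval_s, protocol)
        surrogate_series = (
            assemble(subject.reps, procedure, interval_s)
            if truth_mode == "surrogate" else None
        )
        per_subject.append((subject, models, surrogate_series))

    results = []
    for dtr in dtr_values:
        cis: dict[str, list[ConfidenceInterval]] = {p: [] for p in parameters}
        truths: dict[str, list[float]] = {p: [] for p in parameters}
        atols: dict[str, list[float]] = {p: [] for p in parameters}
        n_excluded = 0
        for subject, models, surrogate_series in per_subject:
            if truth_mode == "surrogate":
                truth_fit = fit_kinetics(surrogate_series, dtr, protocol=protocol)
                if not truth_fit.converged:
                    n_excluded += len(models)
                    continue
                truth = truth_fit.params
            else:
                truth = subject.params
            for model in models:
                res = model.fit(dtr)
                if not res.converged:
                    n_excluded += 1
                    continue
                for p in parameters:
                    est = res.estimate_for(p)
                    cis[p].append(confidence_interval(
                        est, res.ase_for(p), res.df, level))
                    truths[p].append(getattr(truth, p))
                    atols[p].append(numerical_atol * max(1.0, abs(est)))
        if all(len(cis[p]) == 0 for p in parameters):
            raise RuntimeError(f"all fits failed at dTr = {dtr}")
        for p in parameters:
            results.append(coverage(cis[p], truths[p], procedure=procedure,
                                    parameter=p, dtr_s=float(dtr),
                                    n_excluded=n_excluded, atol=atols[p]))
    return results


def pool_coverage(results: list[CoverageResult]) -> list[CoverageResult]:
    """Sum case counts over replicates sharing (procedure, parameter, dTr)."""
    pooled: dict[tuple, CoverageResult] = {}
    for r in results:
        key = (r.procedure, r.parameter, r.dtr_s)
        if key in pooled:
            p = pooled[key]
            pooled[key] = CoverageResult(
                procedure=r.procedure, parameter=r.parameter, dtr_s=r.dtr_s,
                n_cases=p.n_cases + r.n_cases,
                n_covered=p.n_covered + r.n_covered,
                n_excluded=p.n_excluded + r.n_excluded,
            )
        else:
            pooled[key] = r
    return list(pooled.values())


def simulate_coverage(
    procedure: str,
    dtr_values=(20.0,),
    n_replicates: int = 1,
    seed=0,
    n_subjects: int = 10,
    n_reps: int = 10,
    truth_mode: str = "surrogate",
    level: float = 0.95,
    sampler: SubjectSampler | None = None,
    protocol: Protocol | None = None,
    noise: BreathNoiseModel | None = None,
    interval_s: float = 1.0,
    parameters: tuple[str, ...] = ("tau", "td"),
) -> list[CoverageResult]:
    """End-to-end coverage simulation: generate cohorts, fit, pool replicates.

    ``n_replicates`` repeats the whole cohort design with seeds derived from
    ``seed`` to shrink the binomial Monte-Carlo error of the coverage
    percentage.
    """
    ss = np.random.SeedSequence(seed)
    all_results: list[CoverageResult] = []
    for child in ss.spawn(n_replicates):
        cohort = generate_cohort(n_subjects, n_reps, child, subject_sampler=sampler,
                                 protocol=protocol, noise=noise)
        all_results.extend(
            run_coverage_experiment(cohort, procedure, dtr_values, level,
                                    truth_mode, interval_s, protocol, parameters)
        )
    return pool_coverage(all_results)


def coverage_to_frame(results: list[CoverageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"procedure": r.procedure, "parameter": r.parameter, "dtr_s": r.dtr_s,
             "n_cases": r.n_cases, "n_covered": r.n_covered,
             "coverage_pct": r.coverage_pct, "n_excluded": r.n_excluded}
            for r in results
        ]
    )


def fit_ase_vs_nr(nr_values, ase_values) -> ASECurve:
    """Least-squares fit of the law ASE(Nr) = k / sqrt(Nr).

    The model is linear in k, so the estimate is closed-form:
    k = sum(ase/sqrt(Nr)) / sum(1/Nr).
    """
    nr = np.asarray(nr_values, dtype=float)
    ase = np.asarray(ase_values, dtype=float)
    if nr.shape != ase.shape or nr.size < 2:
        raise ValueError("need >= 2 matched (Nr, ASE) points")
    if np.any(ase <= 0) or np.any(nr < 1):
        raise ValueError("ASE values must be positive and Nr >= 1")
    x = 1.0 / np.sqrt(nr)
    k = float(np.sum(ase * x) / np.sum(x * x))
    rss = float(np.sum((ase - k * x) ** 2))
    return ASECurve(k=k, rss=rss)


def ase_vs_nr_table(reps: list[BreathSeries], procedure: str,
                    dtr_s: float = 20.0, interval_s: float = 1.0,
                    protocol: Protocol | None = None) -> pd.DataFrame:
    """ASEs and df as a function of Nr: assemble the first Nr reps, fit, tabulate.

    Repetitions are assembled following their given (performance) order:
    the first alone, then the first two, and so on.
    """
    rows = []
    for nr in range(1, len(reps) + 1):
        assembled = assemble(reps[:nr], procedure, interval_s)
        res = fit_kinetics(assembled, dtr_s, protocol=protocol)
        rows.append({"nr": nr, "procedure": procedure,
                     "tau": res.params.tau, "td": res.params.td,
                     "ase_tau": res.ase_for("tau"), "ase_td": res.ase_for("td"),
                     "df": res.df, "converged": res.converged})
    return pd.DataFrame(rows)


def resampling_sweep(series: BreathSeries, intervals, dtr_s: float = 20.0,
                     protocol: Protocol | None = None
                     ) -> tuple[pd.DataFrame, KineticsFitResult]:
    """Effect of the resampling interval on ASE_tau and df for one repetition.

    Returns the table of (interval_s, ase_tau, df) for clone-resampled fits
    plus the native (stacking-style, unmanipulated) fit as reference.
    """
    if np.any(np.asarray(intervals, dtype=float) <= 0):
        raise ValueError("intervals must be positive")
    rows = []
    for interval in intervals:
        grid = resample_to_bins(series, float(interval))
        res = fit_kinetics(grid, dtr_s, protocol=protocol)
        rows.append({"interval_s": float(interval), "tau": res.params.tau,
                     "ase_tau": res.ase_for("tau"), "df": res.df,
                     "converged": res.converged})
    native = fit_kinetics(series, dtr_s, protocol=protocol)
    return pd.DataFrame(rows), native
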