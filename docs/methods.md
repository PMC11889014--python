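# Methods

## Model

Phase-II V̇O₂ kinetics during a square-wave moderate-intensity transition are
described by the mono-exponential

    V̇O₂(t) = A_b + ΔA · (1 − e^−(t − Td)/τ)   for t ≥ Td,

extended piecewise as the constant `A_b` for t < Td. The exponential is
only physically meaningful from the time delay onwards; the constant
extension lets recorded baseline breaths constrain `A_b`. All four symbols
are fitted parameters (p = 4), so df = n − 4. The model assumes no slow
component and no separately modelled cardiodynamic phase; the early
transient is instead handled by the fitting-window convention below.

## Fitting

Nonlinear least squares via a trust-region reflective algorithm
(`scipy.optimize.least_squares`) with τ bounded to (0.1, 200) s to prevent
pathological fits on degenerate inputs, and the other parameters free.
Relative tolerances are 1e-8 on parameters, cost and gradient, with at most
200 iterations' worth of function evaluations. The piecewise join at Td
makes the objective non-smooth there, so the Jacobian is obtained by finite
differences, and ASEs come from the standard large-sample covariance
s²·(JᵀJ)⁻¹ with s² = RSS/df, evaluated at the solution.

The kink at Td also creates shallow local minima when Td falls near a
sparsely sampled region (e.g. the edge of the exclusion window). After the
first optimizer pass the profiled RSS — for fixed (τ, Td) the model is
linear in (A_b, ΔA), so the conditional minimum is closed-form — is scanned
on a local 21×41 (τ, Td) grid (τ ± 20%, Td ± 2.5 s); if a better basin is
found the optimizer restarts there and the lower-RSS solution wins. The
test suite checks the resulting fits against an independent zooming
grid-search oracle to 10⁻³ s on τ.

**Starting values** follow the field's convention: τ₀ = 25 s, Td₀ = 0 s,
A_b₀ = mean of the 3 min of baseline just before onset, ΔA₀ = mean of the
final 3 min of exercise (steady state) minus A_b₀.

**Fitting window.** All recorded baseline points (t < 0) are always
included — A_b is estimable only from baseline — and the ΔTr exclusion
removes only t ∈ [0, ΔTr). This choice keeps the 1-s-bins df constant in Nr,
as expected for a fixed total window. Whether baseline points belong in the
window at all is genuinely open; `include_baseline=False` exposes the
sensitivity. The ΔTr sweep convention is 41 fits, ΔTr = 0…40 s; analyses
focus on ΔTr = 0 and 20 s (the usual guard against the cardiodynamic phase).

**χ² reporting.** RSS and df are always reported. A χ² statistic
(RSS/σ²) and its p-value are computed only when the true noise SD is
supplied (simulation mode), since no normalization is defensible otherwise.

## Assembling procedures

* **stacking**: pooled multiset of all native (time, value) pairs, sorted by
  time with stable tie order. Nothing is modified; df grows by roughly one
  repetition's breath count per added repetition.
* **1-s-bins**: each repetition is clone-resampled to a grid of integer
  multiples of the interval (1 s by default), anchored so t = 0 is a node
  and extended over the recorded baseline (baseline data are needed for
  A_b; the grid therefore covers the full span, a choice the
  `include_baseline` switch makes testable). Each grid node copies the
  value of the nearest native breath; exact midway ties go to the earlier
  breath (deterministic and order-independent). Grids are then averaged
  bin-wise; edge bins missing in some repetitions average over the
  available ones, with the count recorded per bin.

## Confidence intervals and coverage

The candidate interval is estimate ± t_df(α)·ASE (two-tailed, α = 0.95 by
default). Coverage counts closed-interval hits; a tiny floating-point guard
(10⁻⁶ relative to the estimate) protects the degenerate noiseless case,
where a zero-width interval sits on the truth only to optimizer precision —
it is negligible against any real interval width. Truth is either the known
generator parameter (simulation) or the surrogate: the fit of all of a
subject's repetitions assembled with the same procedure at the same ΔTr.
Surrogate truth is not independent of the evaluated fits (each repetition
contributes to its own surrogate), which inflates coverage somewhat — the
reason bins coverage against the surrogate (~75%) sits above the ~70%
obtained against independent truth. Non-converged fits are excluded from
numerator and denominator and counted; a failed surrogate fit excludes that
subject's cases at that ΔTr.

The ASE-vs-Nr law ASE = k/√Nr is linear in k, so k is estimated closed-form
as Σ(ASE/√Nr) / Σ(1/Nr), with the RSS reported.

## Synthetic-data generator

One parameter draw per subject — τ ~ U(25, 35) s, Td ~ U(12, 20) s,
A_b ~ U(600, 900), ΔA ~ U(800, 1200) ml·min⁻¹ — shared by all of that
subject's repetitions, which differ only in breath timing and noise. These
ranges bracket moderate-intensity phase-II kinetics in healthy adults.
Breath durations are iid truncated normal (mean 3.5 s, SD 0.6 s, minimum
1.5 s — the typical 3–4-s breath of these protocols); the timestamp is the
end of the breath, matching expiration-based breath detection, and
durations accumulate from the start of the 3-min baseline to the end of the
6-min bout. Noise is additive iid Gaussian per breath, homoscedastic across
baseline and exercise, default SD 100 ml·min⁻¹. The noise SD of real
breath-by-breath data varies by device and algorithm and is left
configurable; coverage is invariant to it (ASEs scale with the residual
SD), which the suite verifies, so the default is not critical.

The generator deliberately omits: inter-breath autocorrelation, the
cardiodynamic phase, any slow component, heteroscedasticity, and raw
flow/gas-fraction traces. Passing tests therefore demonstrate the
statistical mechanism — information cloning deflates ASEs and breaks CI
coverage — under clean mono-exponential conditions; they do not certify
behavior under model misspecification on real data.

## Problem sizes and determinism

The acceptance script uses 10 cohort replicates (~1000 cases) for the
stacking coverage at ΔTr = 20 s, 3 replicates for the full 41-point ΔTr
sweep with the bins procedure, and 600 independent single repetitions for
the oversampling-vs-known-truth experiment — sizes at which the binomial
Monte-Carlo error of a coverage percentage is ≲ 1–2 points. All randomness
flows from a single seed through `numpy.random.SeedSequence` spawning, so
every experiment is exactly reproducible.

## Known limitations

* Mono-exponential only; bi-exponential (cardiodynamic + primary) fitting is
  out of scope.
* Ordinary (unweighted) least squares; no robust loss, no outlier cleaning.
* The surrogate-truth design inherits its non-independence by construction;
  it is the intended comparison, not a defect, but absolute coverage values
  against the surrogate should not be read as calibration statements.
* The noiseless 1-s-bins case is *not* exactly on-curve: cloning shifts
  values to grid times, so bins fits of noiseless data recover the truth
  only approximately (≲ 0.5% on τ for 1-s grids), unlike stacking which is
  exact.
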