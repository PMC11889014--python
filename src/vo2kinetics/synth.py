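"""Synthetic breath-by-breath VO2 generator.

Emulates repeated square-wave moderate-intensity transitions: each repetition
is a mono-exponential response sampled at irregular breath times (iid
truncated-normal breath durations, timestamp = end of breath) with additive
iid Gaussian breath noise.  One parameter draw per subject is shared by all
of that subject's repetitions, which differ only in breath timing and noise.

No cardiodynamic phase and no slow component are simulated: the target domain
is moderate intensity, where the steady state shows no drift, and the fitting
convention excludes the early transient via the dTr window instead.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .kinetics import model_predict
from .params import BreathNoiseModel, KineticParams, Protocol, SubjectSampler
from .series import BreathSeries, Cohort, Subject

__all__ = ["generate_breath_series", "generate_cohort"]


def _breath_times(protocol: Protocol, noise: BreathNoiseModel,
                  rng: np.random.Generator) -> np.ndarray:
    """Accumulate truncated-normal breath durations from the recording start."""
    a = (noise.min_breath_s - noise.mean_breath_s) / noise.breath_sd_s
    dist = stats.truncnorm(a, np.inf, loc=noise.mean_breath_s, scale=noise.breath_sd_s)
    span = protocol.span_s
    # draw in blocks until the cumulative time covers the protocol
    n_guess = int(span / noise.mean_breath_s * 1.3) + 20
    durations = dist.rvs(size=n_guess, random_state=rng)
    while durations.sum() < span:
        durations = np.concatenate(
            [durations, dist.rvs(size=n_guess, random_state=rng)]
        )
    times = protocol.baseline_start_s + np.cumsum(durations)
    return times[times <= protocol.exercise_end_s]


def generate_breath_series(
    params: KineticParams,
    protocol: Protocol,
    noise: BreathNoiseModel,
    seed,
    rep_id: str = "rep01",
) -> BreathSeries:
    """Simulate one repetition of the square-wave transition.

    Parameters
    ----------
    params : KineticParams
        True kinetics of the response (``da`` must be positive).
    protocol : Protocol
        Recording window relative to exercise onset.
    noise : BreathNoiseModel
        Breath-duration distribution and additive VO2 noise SD.
    seed : int | numpy.random.Generator | numpy.random.SeedSequence
        Source of randomness; identical seeds give identical series.
    """
    if not (params.da > 0):
        raise ValueError(f"generator requires da > 0, got {params.da}")
    rng = np.random.default_rng(seed)
    times = _breath_times(protocol, noise, rng)
    values = model_predict(params, times)
    if noise.sd > 0:
        values = values + rng.normal(0.0, noise.sd, size=times.shape)
    return BreathSeries(rep_id=rep_id, times=times, values=values)


def generate_cohort(
    n_subjects: int,
    n_reps: int,
    seed,
    subject_sampler: SubjectSampler | None = None,
    protocol: Protocol | None = None,
    noise: BreathNoiseModel | None = None,
) -> Cohort:
    """Simulate a cohort: ``n_subjects`` subjects x ``n_reps`` repetitions each.

    Per subject, one ``KineticParams`` draw is shared by all repetitions; the
    repetitions differ only in breath timing and noise realizations.  The
    study design this emulates is 10 subjects x 10 repetitions.
    """
    if n_subjects < 1 or n_reps < 1:
        raise ValueError("n_subjects and n_reps must be >= 1")
    subject_sampler = subject_sampler or SubjectSampler()
    protocol = protocol or Protocol()
    noise = noise or BreathNoiseModel()

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    subjects = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        param_seq, *rep_seqs = child.spawn(n_reps + 1)
        params = subject_sampler.draw(np.random.default_rng(param_seq))
        reps = [
            generate_breath_series(
                params, protocol, noise, rep_seqs[j], rep_id=f"rep{j + 1:02d}"
            )
            for j in range(n_reps)
        ]
        subjects.append(Subject(subject_id=f"S{i + 1:02d}", params=params, reps=reps))
    return Cohort(subjects=subjects)
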