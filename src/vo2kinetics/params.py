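"""Core parameter containers for square-wave VO2 kinetics.

The mono-exponential phase-II response to a square-wave exercise transition is

    VO2(t) = A_b + dA * (1 - exp(-(t - Td) / tau))    for t >= Td,

with constant baseline ``A_b`` for t < Td.  ``tau`` is the time constant (s),
``Td`` the time delay (s), ``A_b`` the baseline uptake and ``dA`` the
steady-state amplitude (both ml·min⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KineticParams", "Protocol", "BreathNoiseModel", "SubjectSampler"]


@dataclass(frozen=True)
class KineticParams:
    """The four parameters of the mono-exponential square-wave model."""

    a_b: float   # baseline VO2 (ml·min⁻¹)
    da: float    # amplitude above baseline (ml·min⁻¹)
    tau: float   # time constant (s)
    td: float    # time delay after exercise onset (s)

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not np.isfinite(self.td):
            raise ValueError(f"Td must be finite, got {self.td}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a_b, self.da, self.tau, self.td], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "KineticParams":
        a_b, da, tau, td = (float(v) for v in theta)
        return cls(a_b=a_b, da=da, tau=tau, td=td)

    names = ("a_b", "da", "tau", "td")


@dataclass(frozen=True)
class Protocol:
    """Timing of the square-wave protocol relative to exercise onset (t = 0 s).

    Default: 3 min of recorded low-power baseline followed by a 6-min
    moderate-intensity bout.
    """

    baseline_start_s: float = -180.0
    exercise_end_s: float = 360.0
    exercise_onset_s: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not (self.baseline_start_s < 0.0 < self.exercise_end_s):
            raise ValueError(
                "protocol requires baseline_start_s < 0 < exercise_end_s, "
                f"got {self.baseline_start_s}, {self.exercise_end_s}"
            )

    @property
    def span_s(self) -> float:
        return self.exercise_end_s - self.baseline_start_s


@dataclass(frozen=True)
class BreathNoiseModel:
    """Breath-timing and additive-noise model for the synthetic generator.

    Breath durations are iid truncated normal (lower truncation at
    ``min_breath_s``); each breath's VO2 carries iid Gaussian noise of SD
    ``sd``, homoscedastic across baseline and exercise.
    """

    sd: float = 100.0            # per-breath VO2 noise SD (ml·min⁻¹)
    mean_breath_s: float = 3.5   # mean breath duration (s)
    breath_sd_s: float = 0.6     # SD of breath duration (s)
    min_breath_s: float = 1.5    # lower truncation of breath duration (s)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.sd}")
        if not (self.mean_breath_s > self.min_breath_s > 0):
            raise ValueError(
                "breath durations require mean_breath_s > min_breath_s > 0, "
                f"got {self.mean_breath_s}, {self.min_breath_s}"
            )
        if not (self.breath_sd_s > 0):
            raise ValueError(
                f"degenerate breath-duration distribution: breath_sd_s = {self.breath_sd_s}"
            )


@dataclass(frozen=True)
class SubjectSampler:
    """Uniform ranges from which one KineticParams draw per subject is taken.

    Defaults bracket moderate-intensity phase-II kinetics in healthy adults:
    tau ~ U(25, 35) s, Td ~ U(12, 20) s, A_b ~ U(600, 900) and
    dA ~ U(800, 1200) ml·min⁻¹.
    """

    tau_range: tuple[float, float] = (25.0, 35.0)
    td_range: tuple[float, float] = (12.0, 20.0)
    a_b_range: tuple[float, float] = (600.0, 900.0)
    da_range: tuple[float, float] = (800.0, 1200.0)

    def __post_init__(self) -> None:
        for name in ("tau_range", "td_range", "a_b_range", "da_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"{name} has lo > hi: ({lo}, {hi})")
        if self.tau_range[0] <= 0:
            raise ValueError("tau_range must be positive")
        if self.da_range[0] <= 0:
            raise ValueError("da_range must be positive")

    def draw(self, rng: np.random.Generator) -> KineticParams:
        return KineticParams(
            a_b=float(rng.uniform(*self.a_b_range)),
            da=float(rng.uniform(*self.da_range)),
            tau=float(rng.uniform(*self.tau_range)),
            td=float(rng.uniform(*self.td_range)),
        )
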