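"""Experiment configuration: one flat record mapping to YAML/JSON."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import BreathNoiseModel, Protocol, SubjectSampler

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """All knobs of a coverage experiment, serializable to YAML or JSON."""

    # cohort design
    n_subjects: int = 10
    n_reps: int = 10
    n_replicates: int = 1
    seed: int = 0
    # generator
    noise_sd: float = 100.0
    mean_breath_s: float = 3.5
    breath_sd_s: float = 0.6
    min_breath_s: float = 1.5
    baseline_start_s: float = -180.0
    exercise_end_s: float = 360.0
    tau_range: tuple[float, float] = (25.0, 35.0)
    td_range: tuple[float, float] = (12.0, 20.0)
    a_b_range: tuple[float, float] = (600.0, 900.0)
    da_range: tuple[float, float] = (800.0, 1200.0)
    # analysis
    procedure: str = "stacking"
    interval_s: float = 1.0
    dtr: list[float] = field(default_factory=lambda: [20.0])
    level: float = 0.95
    truth_mode: str = "surrogate"

    def noise_model(self) -> BreathNoiseModel:
        return BreathNoiseModel(sd=self.noise_sd, mean_breath_s=self.mean_breath_s,
                                breath_sd_s=self.breath_sd_s,
                                min_breath_s=self.min_breath_s)

    def protocol(self) -> Protocol:
        return Protocol(baseline_start_s=self.baseline_start_s,
                        exercise_end_s=self.exercise_end_s)

    def sampler(self) -> SubjectSampler:
        return SubjectSampler(tau_range=tuple(self.tau_range),
                              td_range=tuple(self.td_range),
                              a_b_range=tuple(self.a_b_range),
                              da_range=tuple(self.da_range))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
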