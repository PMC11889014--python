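"""Time-series containers: native breaths, evenly resampled grids, assemblies.

All timestamps are seconds relative to exercise onset (t = 0 s); VO2 values
are ml·min⁻¹.  The breath-table interchange format is a flat CSV with columns
``subject_id, rep_id, time_s, vo2_ml_min`` (one row per breath).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import KineticParams

__all__ = [
    "BreathSeries",
    "GridSeries",
    "AssembledSeries",
    "Subject",
    "Cohort",
    "read_breath_csv",
    "write_breath_csv",
]

BREATH_COLUMNS = ["subject_id", "rep_id", "time_s", "vo2_ml_min"]


def _as_series_arrays(times, values) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be equal-length 1-D arrays")
    return t, v


@dataclass
class BreathSeries:
    """One repetition's native breath-by-breath record."""

    rep_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times, self.values = _as_series_arrays(self.times, self.values)
        if len(self.times) == 0:
            raise ValueError("empty breath series")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("breath times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class GridSeries:
    """Evenly resampled series on a grid of integer multiples of interval_s.

    ``n_averaged`` records how many repetitions contributed to each bin
    (all ones for a single cloned repetition).
    """

    interval_s: float
    times: np.ndarray
    values: np.ndarray
    n_averaged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times, self.values = _as_series_arrays(self.times, self.values)
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")
        if self.n_averaged is None:
            self.n_averaged = np.ones(len(self.times), dtype=int)
        else:
            self.n_averaged = np.asarray(self.n_averaged, dtype=int)
        steps = np.diff(self.times)
        if len(steps) and not np.allclose(steps, self.interval_s):
            raise ValueError("grid times must be evenly spaced by interval_s")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class AssembledSeries:
    """Result of assembling Nr repetitions: pooled ('stacking') or bin-averaged ('bins')."""

    procedure: str  # "stacking" | "bins"
    times: np.ndarray
    values: np.ndarray
    nr: int
    interval_s: float | None = None
    n_averaged: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.procedure not in ("stacking", "bins"):
            raise ValueError(f"unknown procedure {self.procedure!r}")
        self.times, self.values = _as_series_arrays(self.times, self.values)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Subject:
    """One subject: the kinetic parameters shared by all repetitions, and the reps."""

    subject_id: str
    params: KineticParams
    reps: list[BreathSeries] = field(default_factory=list)


@dataclass
class Cohort:
    subjects: list[Subject]

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the breath-table schema (one row per breath)."""
        rows = []
        for s in self.subjects:
            for rep in s.reps:
                rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": s.subject_id,
                            "rep_id": rep.rep_id,
                            "time_s": rep.times,
                            "vo2_ml_min": rep.values,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def params_frame(self) -> pd.DataFrame:
        """Per-subject generating parameters (simulation truth)."""
        return pd.DataFrame(
            [
                {"subject_id": s.subject_id, "a_b": s.params.a_b, "da": s.params.da,
                 "tau": s.params.tau, "td": s.params.td}
                for s in self.subjects
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, params_df: pd.DataFrame | None = None) -> "Cohort":
        """Rebuild a cohort from the breath table (and optionally true params).

        Without ``params_df`` the generating parameters are unknown; a
        placeholder is stored and only surrogate-truth analyses are valid.
        """
        missing = [c for c in BREATH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"breath table missing columns: {missing}")
        truth = {}
        if params_df is not None:
            for _, row in params_df.iterrows():
                truth[str(row["subject_id"])] = KineticParams(
                    a_b=row["a_b"], da=row["da"], tau=row["tau"], td=row["td"]
                )
        subjects = []
        for sid, sdf in df.groupby("subject_id", sort=True):
            reps = []
            for rid, rdf in sdf.groupby("rep_id", sort=True):
                rdf = rdf.sort_values("time_s")
                reps.append(
                    BreathSeries(
                        rep_id=str(rid),
                        times=rdf["time_s"].to_numpy(),
                        values=rdf["vo2_ml_min"].to_numpy(),
                    )
                )
            placeholder = KineticParams(a_b=np.nan, da=np.nan, tau=1.0, td=0.0)
            subjects.append(
                Subject(subject_id=str(sid), params=truth.get(str(sid), placeholder), reps=reps)
            )
        return cls(subjects=subjects)


def write_breath_csv(cohort: Cohort, path) -> None:
    # %.17g keeps the float64 roundtrip lossless
    cohort.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_breath_csv(path, params_path=None) -> Cohort:
    # round_trip parsing keeps the written %.17g floats bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    params_df = (pd.read_csv(params_path, float_precision="round_trip")
                 if params_path is not None else None)
    return Cohort.from_frame(df, params_df)
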