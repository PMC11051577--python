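"""Longitudinal study records and their on-disk CSV/JSON representation.

One :class:`LongitudinalRecord` holds everything measured at one time point of
a longitudinal exercise study: subject anthropometrics, environment, lifestyle
factors, the anaerobic threshold, and steady-state observations of the ten
cardiorespiratory variables on a grid of exercise stimulus levels.

On disk a study is a pair of files:

* a long-format CSV with one row per (record, variable, stimulus level):
  ``record_id, subject_id, time_years, variable, stimulus_vo2, stimulus_vco2,
  value`` (UTF-8, comma separator, ``.`` decimal);
* a companion JSON file with per-record anthropometrics, environment, factors
  and AT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MissingFieldError
from .model import VARIABLE_NAMES, EnvironmentConditions, StimulusLevel

CSV_COLUMNS = [
    "record_id", "subject_id", "time_years", "variable",
    "stimulus_vo2", "stimulus_vco2", "value",
]


@dataclass(frozen=True)
class SubjectAnthropometrics:
    """Height (cm), weight (kg) and age (years); fields may be absent."""

    height: float | None = None
    weight: float | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        for name in ("height", "weight", "age"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")

    def require(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise MissingFieldError(name)
        return v


@dataclass
class LongitudinalRecord:
    """One time point of a longitudinal study (see module docstring)."""

    record_id: str
    subject_id: str
    time_years: float
    stimulus_vo2: np.ndarray
    stimulus_vco2: np.ndarray
    observations: pd.DataFrame  # rows = variable names, columns = level index
    anthro: SubjectAnthropometrics | None = None
    env: EnvironmentConditions = field(default_factory=EnvironmentConditions)
    activity_h_week: float | None = None
    sleep_h_day: float | None = None
    at_vco2: float | None = None
    breath_series: "object | None" = None  # standardization.BreathSeries
    vtn: float | None = None  # basal tidal volume measurement, L

    def __post_init__(self) -> None:
        self.stimulus_vo2 = np.asarray(self.stimulus_vo2, dtype=float)
        self.stimulus_vco2 = np.asarray(self.stimulus_vco2, dtype=float)
        if self.stimulus_vo2.shape != self.stimulus_vco2.shape:
            raise ValueError("stimulus_vo2 and stimulus_vco2 must have equal length")
        if self.observations.shape[1] != self.stimulus_vo2.size:
            raise ValueError("observations must have one column per stimulus level")

    @property
    def n_levels(self) -> int:
        return self.stimulus_vo2.size

    @property
    def stimuli(self) -> list[StimulusLevel]:
        return [
            StimulusLevel(vo2=float(o), vco2=float(c))
            for o, c in zip(self.stimulus_vo2, self.stimulus_vco2)
        ]

    def observation_matrix(self, variables=VARIABLE_NAMES) -> np.ndarray:
        """Observations as a ``(n_variables, n_levels)`` array in the given order."""
        missing = [v for v in variables if v not in self.observations.index]
        if missing:
            raise MissingFieldError(missing[0])
        return self.observations.loc[list(variables)].to_numpy(dtype=float)

    def resting_vtn(self) -> float:
        """Basal tidal volume: explicit measurement, else VT at the lowest stimulus."""
        if self.vtn is not None:
            return self.vtn
        if "vt" not in self.observations.index:
            raise MissingFieldError("vtn")
        rest = int(np.argmin(self.stimulus_vco2))
        return float(self.observations.loc["vt"].iloc[rest])


def _record_meta(rec: LongitudinalRecord) -> dict:
    meta: dict = {
        "record_id": rec.record_id,
        "subject_id": rec.subject_id,
        "time_years": rec.time_years,
        "environment": {"fio2": rec.env.fio2, "fico2": rec.env.fico2, "patm": rec.env.patm},
        "factors": {"activity_h_week": rec.activity_h_week, "sleep_h_day": rec.sleep_h_day},
        "at_vco2": rec.at_vco2,
        "vtn": rec.vtn,
    }
    if rec.anthro is not None:
        meta["anthropometrics"] = {
            "height": rec.anthro.height, "weight": rec.anthro.weight, "age": rec.anthro.age,
        }
    return meta


def write_records(records: list[LongitudinalRecord], csv_path, json_path) -> None:
    """Write a study to the long-format CSV plus companion JSON metadata."""
    rows = []
    for rec in records:
        for var in rec.observations.index:
            for k in range(rec.n_levels):
                rows.append({
                    "record_id": rec.record_id,
                    "subject_id": rec.subject_id,
                    "time_years": rec.time_years,
                    "variable": var,
                    "stimulus_vo2": rec.stimulus_vo2[k],
                    "stimulus_vco2": rec.stimulus_vco2[k],
                    "value": float(rec.observations.loc[var].iloc[k]),
                })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(csv_path, index=False)
    meta = [_record_meta(rec) for rec in records]
    Path(json_path).write_text(json.dumps(meta, indent=1))


def read_records(csv_path, json_path) -> list[LongitudinalRecord]:
    """Read a study written by :func:`write_records`, ordered by time."""
    df = pd.read_csv(csv_path)
    meta = {m["record_id"]: m for m in json.loads(Path(json_path).read_text())}
    records = []
    for rid, group in df.groupby("record_id", sort=False):
        m = meta.get(str(rid), {})
        pivot = group.pivot_table(
            index="variable", columns="stimulus_vco2", values="value", sort=True
        )
        stim = group.drop_duplicates("stimulus_vco2").sort_values("stimulus_vco2")
        anthro = None
        if "anthropometrics" in m:
            anthro = SubjectAnthropometrics(**m["anthropometrics"])
        envd = m.get("environment")
        env = EnvironmentConditions(**envd) if envd else EnvironmentConditions()
        factors = m.get("factors", {})
        pivot.columns = range(len(pivot.columns))
        records.append(LongitudinalRecord(
            record_id=str(rid),
            subject_id=str(group["subject_id"].iloc[0]),
            time_years=float(group["time_years"].iloc[0]),
            stimulus_vo2=stim["stimulus_vo2"].to_numpy(),
            stimulus_vco2=stim["stimulus_vco2"].to_numpy(),
            observations=pivot,
            anthro=anthro,
            env=env,
            activity_h_week=factors.get("activity_h_week"),
            sleep_h_day=factors.get("sleep_h_day"),
            at_vco2=m.get("at_vco2"),
            vtn=m.get("vtn"),
        ))
    records.sort(key=lambda r: r.time_years)
    return records
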