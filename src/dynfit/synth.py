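"""Synthetic longitudinal studies with known ground truth.

Real longitudinal cardiorespiratory records are rarely shareable, so every
stage of the fitting strategy is exercised against generated studies whose
"true" parameters are known: per-subject parameter trajectories drift slowly
with time and lifestyle factors, steady-state observations are produced by
the model on the standard 8-level stimulus grid (equidistant VCO2 from 0.3
L/min to the record's anaerobic threshold, VO2 from a fixed respiratory
exchange ratio of 0.9), and measurements carry multiplicative lognormal
noise (physiological variables are positive and their errors roughly
proportional; default coefficient of variation 3%).

The hidden truth travels in a separate :class:`StudyTruth` object (and a
sidecar JSON on disk) that the fitting code paths never receive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DynfitError
from .model import EnvironmentConditions, PhysiologicalModel, StimulusLevel
from .optimization import FitResult
from .parameters import ParameterSet
from .records import LongitudinalRecord, SubjectAnthropometrics

#: Fixed respiratory exchange ratio VCO2/VO2 used below the anaerobic threshold.
RER = 0.9
REST_VCO2 = 0.3  # L/min, resting CO2 output anchoring the stimulus grid


@dataclass(frozen=True)
class ParameterDrift:
    """Drift law for one parameter's true value.

    ``value(t) = intercept + slope * t + sum(coeff * factor(t)) + AR(1) noise``
    with factors measured as deviations from the first record.
    """

    slope: float = 0.0                 # per year
    coeff_activity: float = 0.0        # per h/week
    coeff_sleep: float = 0.0           # per h/day
    coeff_at: float = 0.0              # per L/min
    ar1_sd: float = 0.0                # innovation standard deviation
    ar1_rho: float = 0.5
    intercept: float | None = None     # defaults to the parameter's nominal


@dataclass(frozen=True)
class DriftSpec:
    """Per-parameter drift laws plus the generator seed."""

    drifts: Mapping[str, ParameterDrift] = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the generated study (sizes, times, factors, noise)."""

    n_subjects: int = 1
    times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)    # record times, years
    at_vco2: tuple[float, ...] = (1.2, 1.25, 1.3, 1.35)  # per record, L/min
    activity: tuple[float, ...] = (5.0, 4.0, 3.0, 2.0)   # h/week
    sleep: tuple[float, ...] = (7.0, 7.0, 6.5, 7.0)      # h/day
    height_cm: float = 170.0
    weight_kg: float = 75.0
    age0_years: float = 30.0
    n_levels: int = 8
    noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("record times must be strictly increasing")
        for name in ("at_vco2", "activity", "sleep"):
            if len(getattr(self, name)) != len(self.times):
                raise ValueError(f"{name} must align with times")


@dataclass
class StudyTruth:
    """Hidden ground truth: true parameter values per subject per record."""

    values: dict[str, list[dict[str, float]]]  # subject -> per-record name->value

    def frame(self, subject: str) -> pd.DataFrame:
        return pd.DataFrame(self.values[subject])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.values, indent=1))

    @classmethod
    def from_json(cls, path) -> "StudyTruth":
        return cls(values=json.loads(Path(path).read_text()))


def stimulus_grid(at_vco2: float, n_levels: int = 8, rer: float = RER):
    """Equidistant VCO2 grid from 0.3 L/min to AT; VO2 via the fixed RER."""
    vco2 = np.linspace(REST_VCO2, at_vco2, n_levels)
    vo2 = vco2 / rer
    return vo2, vco2


def generate_drift_trajectories(
    spec: DriftSpec, design: StudyDesign, params: ParameterSet
) -> StudyTruth:
    """True parameter values per subject and record under the drift laws.

    Parameters without a drift law stay at their nominal value. Values
    wandering outside a parameter's bounds are clipped (with a warning via
    numpy's clip semantics this is silent; the clip is part of the truth).
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, list[dict[str, float]]] = {}
    times = np.asarray(design.times)
    d_act = np.asarray(design.activity) - design.activity[0]
    d_sleep = np.asarray(design.sleep) - design.sleep[0]
    d_at = np.asarray(design.at_vco2) - design.at_vco2[0]
    for s in range(design.n_subjects):
        subject = f"S{s + 1}"
        per_record: list[dict[str, float]] = [dict() for _ in times]
        for name, law in spec.drifts.items():
            p = params[name]
            base = law.intercept if law.intercept is not None else p.nominal
            noise = np.zeros_like(times)
            if law.ar1_sd > 0:
                e = rng.normal(0.0, law.ar1_sd, size=times.size)
                for i in range(1, times.size):
                    noise[i] = law.ar1_rho * noise[i - 1] + e[i]
            vals = (
                base
                + law.slope * times
                + law.coeff_activity * d_act
                + law.coeff_sleep * d_sleep
                + law.coeff_at * d_at
                + noise
            )
            vals = np.clip(vals, p.bound_low, p.bound_high)
            for i, v in enumerate(vals):
                per_record[i][name] = float(v)
        # untouched parameters: nominal
        for i in range(times.size):
            for p in params:
                per_record[i].setdefault(p.name, p.nominal)
        out[subject] = per_record
    return StudyTruth(values=out)


def generate_longitudinal_study(
    model: PhysiologicalModel,
    spec: DriftSpec,
    design: StudyDesign,
    env: EnvironmentConditions = EnvironmentConditions(),
) -> tuple[list[LongitudinalRecord], StudyTruth]:
    """Generate observed records plus the hidden truth.

    Observations are the model's steady-state outputs at the true parameters,
    multiplied by lognormal noise with coefficient of variation
    ``design.noise_cv``. Returns records ordered by (subject, time).
    """
    truth = generate_drift_trajectories(spec, design, model.default_parameters())
    rng = np.random.default_rng(design.seed + 1)
    sigma = float(np.sqrt(np.log(1.0 + design.noise_cv**2)))
    params0 = model.default_parameters()
    variables = list(model.variable_names)
    records: list[LongitudinalRecord] = []
    for s in range(design.n_subjects):
        subject = f"S{s + 1}"
        for i, t in enumerate(design.times):
            vo2, vco2 = stimulus_grid(design.at_vco2[i], design.n_levels)
            stims = [StimulusLevel(o, c) for o, c in zip(vo2, vco2)]
            true_params = params0.with_values(truth.values[subject][i])
            try:
                clean = model.simulate_grid(true_params, stims, env)
            except DynfitError as err:
                raise DynfitError(
                    f"generation failed for subject {subject} record {i}: {err}"
                ) from err
            if design.noise_cv > 0:
                noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=clean.shape)
                obs = clean * noise
            else:
                obs = clean.copy()
            records.append(LongitudinalRecord(
                record_id=f"{subject}-R{i + 1}",
                subject_id=subject,
                time_years=float(t),
                stimulus_vo2=vo2,
                stimulus_vco2=vco2,
                observations=pd.DataFrame(obs, index=variables),
                anthro=SubjectAnthropometrics(
                    height=design.height_cm, weight=design.weight_kg,
                    age=design.age0_years + float(t),
                ),
                env=env,
                activity_h_week=design.activity[i],
                sleep_h_day=design.sleep[i],
                at_vco2=design.at_vco2[i],
            ))
    return records, truth


def drifting_gain_scenario(
    seed: int,
    parameter: str = "GHR",
    slope_pct_per_year: float = -5.0,
    nominal: float | None = None,
) -> tuple[DriftSpec, StudyDesign]:
    """Reference benchmark scenario: one gain drifting 5% of nominal per year.

    Emulates a personalized longitudinal series (one subject, four yearly
    records) in which the heart-rate gain declines with age — the textbook
    chronotropic decline — while every other parameter stays at its true
    nominal value. Observation noise is the default 3% CV.
    """
    if nominal is None:
        from .parameters import load_default_parameters
        nominal = load_default_parameters()[parameter].nominal
    spec = DriftSpec(
        drifts={parameter: ParameterDrift(slope=slope_pct_per_year / 100.0 * nominal)},
        seed=seed,
    )
    design = StudyDesign(seed=seed)
    return spec, design


def parameter_recovery_report(
    truth: StudyTruth,
    fit_results: Sequence[FitResult],
    subject: str = "S1",
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Relative recovery errors |fitted - true| / |true| per parameter and record.

    Returns a tidy frame with columns parameter, record, rel_error plus
    summary rows are available through ``.groupby('parameter')``.
    """
    per_record = truth.values[subject]
    rows = []
    for i, fr in enumerate(fit_results):
        true_vals = per_record[i]
        fitted = fr.params.to_dict()
        for name in (names if names is not None else fitted):
            if name not in true_vals or name not in fitted:
                continue
            tv = true_vals[name]
            rows.append({
                "parameter": name,
                "record": i,
                "rel_error": abs(fitted[name] - tv) / abs(tv) if tv != 0 else np.nan,
            })
    return pd.DataFrame(rows, columns=["parameter", "record", "rel_error"])
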