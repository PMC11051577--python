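"""End-to-end orchestration of the dynamic fitting strategy with file handoff.

Each pipeline step writes inspectable artifacts into the run directory and
later steps read them back, so any stage can be re-run or examined in
isolation:

``synth``     records.csv / records.json + truth.json (hidden-truth sidecar)
``fit``       fits.json — sequential time-specific fits with warm starts
``trend``     trend_report.csv — per-parameter ARX models and gate outcomes
``predict``   predicted_params.json — gated parameter predictions
``validate``  validation.json — PE per approach + pairwise Wilcoxon p-values
``all``       the whole chain on one configuration

Every artifact embeds the configuration hash and seed; reruns with identical
inputs are byte-identical apart from the manifest timestamp.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .exceptions import ConfigError, DependencyError
from .model import CardioRespSurrogate
from .optimization import FitResult, OptimizerSettings, cost_function, fit_longitudinal
from .records import read_records, write_records
from .synth import DriftSpec, ParameterDrift, StudyDesign, generate_longitudinal_study
from .trend import (
    FactorSeries, TrendConfig, predict_next_parameters, predicted_parameter_set,
    trend_report,
)
from .validation import compare_approaches, validation_table

COMMANDS = ("synth", "fit", "trend", "predict", "validate", "all")

_CONFIG_KEYS = {
    "model", "out_dir", "records_csv", "records_json", "seed",
    "selection", "optimizer", "trend", "validation", "synth",
}
_SELECTION_KEYS = {"target_size", "collinearity_threshold", "dominance_ratio"}
_OPTIMIZER_KEYS = {"sigma0", "popsize", "max_evaluations", "tol_cf", "stage2_tolerance"}
_TREND_KEYS = {"ts_grid", "na_max", "nb_max", "gof_threshold", "range_fraction",
               "significant_rel_change", "horizon_years"}
_VALIDATION_KEYS = {"at_from_preceding_record"}
_SYNTH_KEYS = {"n_subjects", "times", "at_vco2", "activity", "sleep", "noise_cv",
               "n_levels", "drift"}


@dataclass
class RunConfig:
    """Validated run configuration (see ``dynfit --help`` for the file format)."""

    model: str = "surrogate"
    out_dir: str = "dynfit_run"
    records_csv: str | None = None
    records_json: str | None = None
    seed: int = 0
    selection: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)
    trend: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        for section, allowed in [
            (raw, _CONFIG_KEYS), (raw.get("selection", {}), _SELECTION_KEYS),
            (raw.get("optimizer", {}), _OPTIMIZER_KEYS), (raw.get("trend", {}), _TREND_KEYS),
            (raw.get("validation", {}), _VALIDATION_KEYS), (raw.get("synth", {}), _SYNTH_KEYS),
        ]:
            unknown = set(section) - allowed
            if unknown:
                raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        # paths are excluded: artifacts should not depend on where they live
        payload = asdict(self)
        for key in ("out_dir", "records_csv", "records_json"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def optimizer_settings(self) -> OptimizerSettings:
        return OptimizerSettings(seed=self.seed, **self.optimizer)

    def trend_config(self) -> TrendConfig:
        kw = dict(self.trend)
        if "ts_grid" in kw:
            kw["ts_grid"] = tuple(kw["ts_grid"])
        return TrendConfig(**kw)


def _model_for(config: RunConfig):
    if config.model != "surrogate":
        raise ConfigError(f"unknown model {config.model!r}")
    return CardioRespSurrogate()


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.content_hash(), "seed": config.seed}


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {**_stamp(config), **payload}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing artifact {path.name}: run '{producer}' first")
    return path


def _load_records(config: RunConfig, out: Path):
    csv = Path(config.records_csv) if config.records_csv else _require(out / "records.csv", "synth")
    js = Path(config.records_json) if config.records_json else _require(out / "records.json", "synth")
    return read_records(_require(csv, "synth"), _require(js, "synth"))


def _load_fits(config: RunConfig, out: Path, model) -> list[FitResult]:
    payload = json.loads(_require(out / "fits.json", "fit").read_text())
    defaults = model.default_parameters()
    fits = []
    for fr in payload["fits"]:
        params = defaults.with_values(fr["params"])
        from .optimization import CostBreakdown
        cb = lambda v: CostBreakdown(cf=v, per_variable={}, n_variables=0, n_levels=0)
        fits.append(FitResult(
            record_id=fr["record_id"], params=params,
            cf_initial=cb(fr["cf_initial"]), cf_final=cb(fr["cf_final"]),
            factors=fr["factors"],
        ))
    return fits


def run_pipeline(config: RunConfig, command: str) -> Path:
    """Execute one pipeline command; returns the run directory."""
    if command not in COMMANDS:
        raise ConfigError(f"unknown command {command!r}; expected one of {COMMANDS}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = _model_for(config)

    steps = ["synth", "fit", "trend", "predict", "validate"] if command == "all" else [command]
    for step in steps:
        getattr(_Steps, step)(config, out, model)
    manifest = {
        **_stamp(config), "command": command,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


class _Steps:
    @staticmethod
    def synth(config: RunConfig, out: Path, model) -> None:
        kw = dict(config.synth)
        drift_raw = kw.pop("drift", {})
        for key in ("times", "at_vco2", "activity", "sleep"):
            if key in kw:
                kw[key] = tuple(kw[key])
        design = StudyDesign(seed=config.seed, **kw)
        spec = DriftSpec(
            drifts={name: ParameterDrift(**law) for name, law in drift_raw.items()},
            seed=config.seed,
        )
        records, truth = generate_longitudinal_study(model, spec, design)
        write_records(records, out / "records.csv", out / "records.json")
        truth.to_json(out / "truth.json")

    @staticmethod
    def fit(config: RunConfig, out: Path, model) -> None:
        records = _load_records(config, out)
        fits = fit_longitudinal(
            model, records, settings=config.optimizer_settings(),
            selection_kwargs=config.selection,
        )
        _write_json(out / "fits.json", {"fits": [f.to_jsonable() for f in fits]}, config)

    @staticmethod
    def trend(config: RunConfig, out: Path, model) -> None:
        fits = _load_fits(config, out, model)
        outcomes = predict_next_parameters(fits, config=config.trend_config())
        trend_report(outcomes).to_csv(out / "trend_report.csv", index=False)

    @staticmethod
    def predict(config: RunConfig, out: Path, model) -> None:
        fits = _load_fits(config, out, model)
        outcomes = predict_next_parameters(fits, config=config.trend_config())
        predicted = predicted_parameter_set(fits, outcomes)
        _write_json(out / "predicted_params.json", {
            "predicted": predicted.to_dict(),
            "statuses": {o.name: o.status for o in outcomes},
        }, config)

    @staticmethod
    def validate(config: RunConfig, out: Path, model) -> None:
        records = _load_records(config, out)
        fits = _load_fits(config, out, model)
        if len(fits) < 3 or len(records) < 3:
            raise DependencyError("validation needs at least three fitted records")
        history, last_fit = fits[:-1], fits[-1]
        target = records[-1]
        horizon = target.time_years - records[-2].time_years
        cfg = replace(config.trend_config(), horizon_years=horizon)
        outcomes = predict_next_parameters(history, config=cfg)
        param_sets = {
            "time_specific": last_fit.params,
            "single_time": fits[0].params,
            "dynamic": predicted_parameter_set(history, outcomes),
        }
        stimuli = None
        if config.validation.get("at_from_preceding_record", True):
            from .synth import stimulus_grid
            from .model import StimulusLevel
            prev_at = records[-2].at_vco2
            if prev_at is not None:
                vo2, vco2 = stimulus_grid(prev_at, target.n_levels)
                stimuli = [StimulusLevel(o, c) for o, c in zip(vo2, vco2)]
        reports, comparison = compare_approaches(target, model, param_sets, stimuli=stimuli)
        validation_table(reports).to_csv(out / "validation.csv", index=False)
        _write_json(out / "validation.json", {
            "overall_pe": {k: r.overall_pe for k, r in reports.items()},
            "p_values": {f"{a}|{b}": p for (a, b), p in comparison.p_values.items()},
            "record_id": target.record_id,
        }, config)
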