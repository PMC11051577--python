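"""ARX trend models of the fitted parameters and gated one-step prediction.

Each parameter whose value the per-record optimization actually moves is
given a MISO ARX (autoregressive with exogenous inputs) model of its
time trend::

    A(q) P(n) = sum_i B_i(q) F_i(n) + e(n)

with A monic of order ``na``, every input polynomial B_i of order ``nb``
(all input delays zero), and the exogenous inputs F_i being elapsed time,
weekly physical activity, daily sleep hours and the anaerobic threshold.
Records are linearly interpolated onto a uniform sampling grid (``ts``
between 0.1 and 0.4 years) before estimation; coefficients come from
ordinary least squares on the regression form, and the model order and
sampling time are chosen by exhaustive search minimizing Akaike's
information criterion ``AIC = ln V + 2 d / N``.

Predicted values are accepted only when physiologically justifiable: the
model must reach 60% goodness of fit, the prediction may not flip sign, and
it may not move more than half the historically recorded range. Rejected or
unmodeled parameters fall back to the previous record's value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, RankError
from .optimization import FitResult
from .parameters import ParameterSet

TS_GRID = (0.1, 0.2, 0.3, 0.4)     # candidate sampling times, years
LOSS_FLOOR = 1e-12                 # AIC clamp for vanishing loss

STATUSES = ("accepted", "rejected_gof", "rejected_sign", "rejected_range", "not_modeled")


@dataclass(frozen=True)
class TrendConfig:
    """Settings for trend modeling and prediction gating."""

    ts_grid: tuple[float, ...] = TS_GRID
    na_max: int = 3
    nb_max: int = 3
    gof_threshold: float = 60.0        # minimum fit%, below which models are discarded
    range_fraction: float = 0.5        # allowed |change| as a fraction of recorded range
    significant_rel_change: float = 0.005  # relative change flagging a parameter as modified
    horizon_years: float = 1.0         # prediction distance beyond the last record


@dataclass
class ParameterTrajectory:
    """Fitted values of one parameter across records (first time = 0)."""

    name: str
    times: np.ndarray
    values: np.ndarray
    modified: np.ndarray  # bool per record: value moved by that record's fit

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.modified = np.asarray(self.modified, dtype=bool)
        if not (self.times.size == self.values.size == self.modified.size):
            raise ValueError("times, values and modified must have equal length")
        if self.times.size and self.times[0] != 0.0:
            raise ValueError("trajectory times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")


@dataclass
class FactorSeries:
    """Exogenous inputs per record: time, activity, sleep and AT."""

    times: np.ndarray           # years since first record
    activity: np.ndarray        # h/week
    sleep: np.ndarray           # h/day
    at_vco2: np.ndarray         # L/min

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.times, self.activity, self.sleep, self.at_vco2)]
        self.times, self.activity, self.sleep, self.at_vco2 = arrays
        if len({a.size for a in arrays}) != 1:
            raise ValueError("factor series must be aligned")
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("factor series must be finite")

    @classmethod
    def from_fit_results(cls, history: Sequence[FitResult]) -> "FactorSeries":
        t0 = history[0].factors["time_years"]
        return cls(
            times=[fr.factors["time_years"] - t0 for fr in history],
            activity=[fr.factors["activity_h_week"] for fr in history],
            sleep=[fr.factors["sleep_h_day"] for fr in history],
            at_vco2=[fr.factors["at_vco2"] for fr in history],
        )

    def input_matrix(self) -> np.ndarray:
        """Inputs as columns: time, activity, sleep, AT; shape ``(n, 4)``."""
        return np.column_stack([self.times, self.activity, self.sleep, self.at_vco2])


@dataclass
class ARXModel:
    """Estimated MISO ARX model for one parameter's time trend."""

    na: int
    nb: int                     # shared order of every input polynomial
    n_inputs: int
    coeffs_a: np.ndarray        # (na,) coefficients a_1..a_na (A monic)
    coeffs_b: np.ndarray        # (n_inputs, nb)
    ts: float                   # effective sampling time, years
    fit_pct: float
    aic: float
    loss_v: float
    n_samples: int              # regression samples N

    @property
    def d(self) -> int:
        return self.na + self.n_inputs * self.nb

    @property
    def delays(self) -> np.ndarray:
        return np.zeros(self.n_inputs, dtype=int)

    def one_step(self, y_hist: np.ndarray, u_hist: np.ndarray) -> float:
        """Predict y(n) from y(n-1..n-na) and u(n..n-nb+1).

        ``y_hist`` holds past outputs ending at n-1; ``u_hist`` holds inputs
        ending at the current instant n (delay zero includes u(n)).
        """
        val = 0.0
        for j in range(1, self.na + 1):
            val -= self.coeffs_a[j - 1] * y_hist[-j]
        for i in range(self.n_inputs):
            for l in range(self.nb):
                val += self.coeffs_b[i, l] * u_hist[-1 - l, i]
        return float(val)


def resample_uniform(
    traj: ParameterTrajectory, factors: FactorSeries, ts: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Linearly interpolate values and inputs onto a uniform time grid.

    ``ts`` must lie in [0.1, 0.4] years. The grid spacing is snapped to
    ``ts_eff = T / round(T / ts)`` so the grid is exactly uniform while both
    endpoints coincide with the original first and last records. Returns
    ``(t_grid, y_grid, u_grid, ts_eff)``.
    """
    if not 0.1 <= ts <= 0.4:
        raise ConfigError(f"sampling time {ts} years outside the [0.1, 0.4] range")
    if traj.times.size < 2:
        raise ConfigError("resampling needs at least two records")
    T = float(traj.times[-1])
    n_steps = max(1, round(T / ts))
    ts_eff = T / n_steps
    t_grid = np.linspace(0.0, T, n_steps + 1)
    y_grid = np.interp(t_grid, traj.times, traj.values)
    U = factors.input_matrix()
    u_grid = np.column_stack([
        np.interp(t_grid, factors.times, U[:, i]) for i in range(U.shape[1])
    ])
    return t_grid, y_grid, u_grid, ts_eff


def fit_arx(y: np.ndarray, U: np.ndarray | None, na: int, nb: int, ts: float = 1.0) -> ARXModel:
    """Least-squares ARX fit on uniformly sampled data.

    ``y`` is the output series; ``U`` (shape ``(n, n_inputs)``) the inputs, or
    None for a pure AR structure. ``na`` autoregressive lags, ``nb``
    coefficients per input at lags ``0..nb-1`` (delay zero). Raises
    :class:`RankError` when the regressor matrix is rank-deficient.

    ``loss_v`` is the mean squared one-step prediction error (the AIC loss);
    ``fit_pct`` is the normalized fit of the free-run *simulated* output,
    the quantity the justification gate thresholds.
    """
    y = np.asarray(y, dtype=float)
    n_inputs = 0 if U is None or nb == 0 else U.shape[1]
    d = na + n_inputs * nb
    if d == 0:
        raise ValueError("model must have at least one coefficient")
    p = max(na, nb - 1, 0)
    n_eff = y.size - p
    if n_eff <= d:
        raise RankError(f"effective sample count {n_eff} must exceed d={d}")
    cols = []
    for j in range(1, na + 1):
        cols.append(-y[p - j : p - j + n_eff])
    for i in range(n_inputs):
        for l in range(nb):
            cols.append(U[p - l : p - l + n_eff, i])
    phi = np.column_stack(cols)
    target = y[p:]
    if np.linalg.matrix_rank(phi) < d:
        raise RankError("singular regressor matrix")
    theta, *_ = np.linalg.lstsq(phi, target, rcond=None)
    pred = phi @ theta
    resid = target - pred
    loss_v = float(resid @ resid) / n_eff  # one-step loss enters the AIC

    # goodness of fit is judged on the free-run simulated output (initialized
    # from the first p samples, then fed its own predictions): one-step fits
    # look deceptively good on densely resampled series, while simulation
    # separates a real trend from noise
    y_sim = y.astype(float).copy()
    a_coef = theta[:na]
    b_coef = theta[na:]
    for n in range(p, y.size):
        val = 0.0
        for j in range(1, na + 1):
            val -= a_coef[j - 1] * y_sim[n - j]
        idx = 0
        for i in range(n_inputs):
            for l in range(nb):
                val += b_coef[idx] * U[n - l, i]
                idx += 1
        y_sim[n] = val
    sim_err = np.linalg.norm(target - y_sim[p:])
    denom = float(np.linalg.norm(target - target.mean()))
    if denom == 0.0:
        fit_pct = 100.0 if sim_err < 1e-12 else 0.0
    else:
        fit_pct = 100.0 * (1.0 - sim_err / denom)
    coeffs_a = theta[:na]
    coeffs_b = theta[na:].reshape(n_inputs, nb) if n_inputs else np.zeros((0, nb))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exact fits hit the AIC loss floor
        aic = aic_score(loss_v, d, n_eff)
    return ARXModel(
        na=na, nb=nb if n_inputs else 0, n_inputs=n_inputs,
        coeffs_a=coeffs_a, coeffs_b=coeffs_b, ts=ts,
        fit_pct=fit_pct, aic=aic, loss_v=loss_v, n_samples=n_eff,
    )


def aic_score(loss_v: float, d: int, n_samples: int) -> float:
    """Akaike's information criterion ``ln V + 2 d / N`` (loss floored at 1e-12)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if loss_v < 0:
        raise ValueError("loss_v must be nonnegative")
    if loss_v < LOSS_FLOOR:
        warnings.warn("loss below floor 1e-12; AIC clamped", stacklevel=2)
        loss_v = LOSS_FLOOR
    return float(np.log(loss_v) + 2.0 * d / n_samples)


def select_arx_model(
    traj: ParameterTrajectory,
    factors: FactorSeries,
    config: TrendConfig = TrendConfig(),
) -> ARXModel | None:
    """Exhaustive minimum-AIC search over sampling times and (na, nb) orders.

    Candidates must keep the coefficient count below the effective sample
    count; ties are broken toward fewer coefficients, then shorter sampling
    time. Returns None when no candidate is admissible.
    """
    best: tuple[float, int, float, ARXModel] | None = None
    for ts in config.ts_grid:
        _, y, U, ts_eff = resample_uniform(traj, factors, ts)
        for na in range(config.na_max + 1):
            for nb in range(config.nb_max + 1):
                if na + nb == 0:
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model = fit_arx(y, U if nb else None, na, nb, ts=ts_eff)
                except RankError:
                    continue
                key = (model.aic, model.d, ts)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (model.aic, model.d, ts, model)
    return best[3] if best else None


@dataclass
class PredictionOutcome:
    """Gated prediction of one parameter's value at the next record."""

    name: str
    status: str
    predicted_value: float | None = None
    fallback_value: float | None = None
    model: ARXModel | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def value(self) -> float:
        """The value to use downstream: prediction if accepted, else fallback."""
        if self.status == "accepted":
            return self.predicted_value
        return self.fallback_value


def parameter_trajectory(
    history: Sequence[FitResult], name: str, rel_change: float = 0.005
) -> ParameterTrajectory:
    """Trajectory of one parameter over the fit history with modified flags.

    A record's value counts as *modified* when it differs from the preceding
    record's value (or, for the first record, from its nominal) by more than
    ``rel_change`` relative.
    """
    t0 = history[0].factors["time_years"]
    times = np.array([fr.factors["time_years"] - t0 for fr in history])
    values = np.array([fr.params.value(name) for fr in history])
    refs = np.concatenate([[history[0].params[name].nominal], values[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(values - refs) / np.where(refs == 0, 1.0, np.abs(refs))
    return ParameterTrajectory(name=name, times=times, values=values, modified=rel > rel_change)


def _simulate_forward(
    model: ARXModel, y: np.ndarray, U: np.ndarray, horizon: float
) -> float:
    """Iterate one-step predictions out to the horizon, inputs held constant."""
    steps = max(1, round(horizon / model.ts))
    y_ext = list(y)
    U_ext = list(U)
    last_u = U[-1].copy()
    for s in range(steps):
        nxt = last_u.copy()
        nxt[0] = U_ext[-1][0] + model.ts  # time input keeps advancing
        U_ext.append(nxt)
        y_hist = np.array(y_ext[-max(model.na, 1):])
        u_hist = np.array(U_ext[-max(model.nb, 1):]) if model.n_inputs else np.zeros((1, 0))
        y_ext.append(model.one_step(y_hist, u_hist))
    return float(y_ext[-1])


def predict_next_parameters(
    history: Sequence[FitResult],
    factors: FactorSeries | None = None,
    config: TrendConfig = TrendConfig(),
    names: Sequence[str] | None = None,
) -> list[PredictionOutcome]:
    """Gated trend predictions for every optimized parameter.

    Parameters never modified twice at consecutive records are not modeled and
    keep the previous record's value. Future exogenous inputs are taken from
    the last record (the time input excepted, which advances by the horizon).
    """
    if len(history) < 2:
        raise ValueError("trend prediction needs at least two fit results")
    if factors is None:
        factors = FactorSeries.from_fit_results(history)
    last_params = history[-1].params
    if names is None:
        names = last_params.by_role("gain_threshold")

    outcomes: list[PredictionOutcome] = []
    for name in names:
        traj = parameter_trajectory(history, name, config.significant_rel_change)
        prev = float(traj.values[-1])
        consecutive = bool(np.any(traj.modified[:-1] & traj.modified[1:]))
        if not consecutive:
            outcomes.append(PredictionOutcome(name, "not_modeled", fallback_value=prev))
            continue
        model = select_arx_model(traj, factors, config)
        if model is None:
            outcomes.append(PredictionOutcome(name, "not_modeled", fallback_value=prev))
            continue
        _, y, U, _ = resample_uniform(traj, factors, model.ts)
        pred = _simulate_forward(model, y, U, config.horizon_years)

        if model.fit_pct < config.gof_threshold:
            status = "rejected_gof"
        elif np.sign(pred) != np.sign(prev) and prev != 0:
            status = "rejected_sign"
        else:
            span = float(traj.values.max() - traj.values.min())
            limit = config.range_fraction * (span if span > 0 else abs(prev))
            # tolerance keeps exact-boundary cases (linear drift) accepted
            exceeds = abs(pred - prev) - limit > 1e-9 * max(1.0, abs(prev))
            status = "rejected_range" if exceeds else "accepted"
        outcomes.append(PredictionOutcome(
            name, status, predicted_value=pred, fallback_value=prev, model=model,
        ))
    return outcomes


def predicted_parameter_set(
    history: Sequence[FitResult], outcomes: Sequence[PredictionOutcome]
) -> ParameterSet:
    """Parameter set for the next record: accepted predictions over the last fit.

    Values are clipped into each parameter's optimization bounds — a
    prediction outside the admissible physiological interval is not usable.
    """
    params = history[-1].params
    updates = {}
    for o in outcomes:
        p = params[o.name]
        updates[o.name] = float(np.clip(o.value, p.bound_low, p.bound_high))
    return params.with_values(updates)


def trend_report(outcomes: Sequence[PredictionOutcome]) -> pd.DataFrame:
    """Tabular per-parameter trend report (exportable as CSV)."""
    rows = []
    for o in outcomes:
        m = o.model
        rows.append({
            "parameter": o.name, "status": o.status,
            "ts": m.ts if m else np.nan, "na": m.na if m else np.nan,
            "nb": m.nb if m else np.nan,
            "fit_pct": m.fit_pct if m else np.nan,
            "aic": m.aic if m else np.nan,
            "predicted": o.predicted_value, "fallback": o.fallback_value,
            "used": o.value,
        })
    return pd.DataFrame(rows)
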