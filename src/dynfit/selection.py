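"""Classification and selection of the parameters to optimize.

Fitting every parameter of a physiological model to a handful of steady-state
observations is ill-posed, so the optimization is restricted to a reduced set
chosen in three steps:

1. *Role*: only gain/threshold parameters are eligible — their variation has a
   physiological meaning at steady state (time constants and initial values do
   not affect it; covariates are standardized from measurements).
2. *Identifiability + total sensitivity* (the **base set**): greedy forward
   subset selection that repeatedly adds the candidate with the highest
   error-weighted total sensitivity whose inclusion keeps the collinearity
   index of the selected, column-normalized sensitivity submatrix below a
   threshold (default 15). The collinearity index is ``1 / sigma_min``.
3. *Relative sensitivity* (the **specific sets**): for each output variable,
   the non-base parameter whose sensitivity is concentrated on that variable
   (dominance ratio over its effect on any other variable of at least 2 by
   default) is assigned to that variable's dedicated refinement stage.

Sensitivities are finite-difference relative sensitivities: the least-squares
slope of the normalized output change against the normalized parameter change
over five uniformly spaced variations within +/-5% of the current value,
evaluated at three stimulus levels (rest, midpoint, anaerobic threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SelectionError
from .model import EnvironmentConditions, PhysiologicalModel, StimulusLevel
from .parameters import ROLES, ParameterSet

DEFAULT_VARIATION_PCT = 5.0
DEFAULT_N_POINTS = 5
DEFAULT_TARGET_SIZE = 8
DEFAULT_COLLINEARITY_THRESHOLD = 15.0
DEFAULT_DOMINANCE_RATIO = 2.0


def classify_by_role(params: ParameterSet) -> dict[str, list[str]]:
    """Partition parameter names into the five functional role groups."""
    groups: dict[str, list[str]] = {role: [] for role in ROLES}
    for p in params:
        groups[p.role].append(p.name)
    return groups


@dataclass
class SensitivityMatrix:
    """Relative sensitivities of every (variable, stimulus) pair to each candidate.

    ``matrix[r, c]`` is the dimensionless relative sensitivity of row ``r``
    (a variable at one stimulus level) to candidate column ``c``;
    ``row_weights`` carry the absolute relative error of each row at the
    current parameter values, so that selection favours parameters acting
    where the model is currently wrong.
    """

    matrix: np.ndarray            # (n_rows, n_candidates)
    rows: list[tuple[str, int]]   # (variable, stimulus index)
    columns: list[str]            # candidate parameter names
    row_weights: np.ndarray       # (n_rows,), >= 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.row_weights = np.asarray(self.row_weights, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("sensitivity matrix entries must be finite")
        if np.any(self.row_weights < 0):
            raise ValueError("row weights must be nonnegative")

    def _weights(self) -> np.ndarray:
        # Normalized to unit mean; uniform when the model already matches the
        # data exactly (all weights zero).
        w = self.row_weights
        total = w.sum()
        if total <= 0:
            return np.ones_like(w)
        return w * (w.size / total)

    def total_sensitivity(self) -> pd.Series:
        """Error-weighted root-mean-square sensitivity per candidate."""
        w = self._weights()[:, None]
        ts = np.sqrt(np.mean(w * self.matrix**2, axis=0))
        return pd.Series(ts, index=self.columns)

    def per_variable(self) -> pd.DataFrame:
        """RMS sensitivity aggregated over stimulus levels, per variable."""
        variables = list(dict.fromkeys(v for v, _ in self.rows))
        out = np.zeros((len(variables), len(self.columns)))
        for i, var in enumerate(variables):
            mask = np.array([v == var for v, _ in self.rows])
            out[i] = np.sqrt(np.mean(self.matrix[mask] ** 2, axis=0))
        return pd.DataFrame(out, index=variables, columns=self.columns)


@dataclass
class SelectionResult:
    """Base and per-variable specific parameter sets plus diagnostics."""

    base_set: list[str]
    specific_sets: dict[str, list[str]]
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.diagnostics.to_csv(path, index=False)


def stimulus_levels_for_selection(
    at_vco2: float, rest_vco2: float = 0.3, rer: float = 0.9
) -> list[StimulusLevel]:
    """Rest, midpoint and AT stimulus levels on the VCO2 axis."""
    mid = 0.5 * (rest_vco2 + at_vco2)
    return [
        StimulusLevel(vo2=v / rer, vco2=v) for v in (rest_vco2, mid, at_vco2)
    ]


def build_sensitivity_matrix(
    model: PhysiologicalModel,
    params: ParameterSet,
    stimuli: Sequence[StimulusLevel],
    env: EnvironmentConditions,
    exp_data: np.ndarray | None = None,
    candidates: Sequence[str] | None = None,
    variation_pct: float = DEFAULT_VARIATION_PCT,
    n_points: int = DEFAULT_N_POINTS,
) -> SensitivityMatrix:
    """Finite-difference relative sensitivity matrix at the current parameters.

    ``exp_data`` (shape ``(n_variables, len(stimuli))``) provides the row
    weights as absolute relative errors of the current simulation; if omitted
    the weights are zero (pure-sensitivity ranking).
    """
    if candidates is None:
        candidates = params.by_role("gain_threshold")
    candidates = list(candidates)
    if not candidates:
        raise SelectionError("no eligible candidate parameters")

    variables = list(model.variable_names)
    base = model.simulate_grid(params, stimuli, env)  # (n_vars, n_stim)
    rows = [(v, k) for v in variables for k in range(len(stimuli))]
    fractions = np.linspace(-variation_pct, variation_pct, n_points) / 100.0

    n_rows = len(rows)
    S = np.zeros((n_rows, len(candidates)))
    for c, name in enumerate(candidates):
        p = params[name]
        theta0 = p.value
        dy = np.zeros((n_points, n_rows))
        # probes are clipped into the bounds (warm starts may sit on one);
        # the regression uses the fractions actually realized.
        realized = np.empty(n_points)
        for j, frac in enumerate(fractions):
            theta = float(np.clip(theta0 * (1.0 + frac), p.bound_low, p.bound_high))
            realized[j] = theta / theta0 - 1.0 if theta0 != 0 else 0.0
            if realized[j] == 0.0:
                continue
            out = model.simulate_grid(params.with_values({name: theta}), stimuli, env)
            dy[j] = ((out - base) / base).ravel()
        # Least-squares slope of (dy/y0) on (dtheta/theta0) through the origin.
        denom = float(realized @ realized)
        if denom == 0.0:
            continue
        S[:, c] = realized @ dy / denom

    if exp_data is None:
        weights = np.zeros(n_rows)
    else:
        exp = np.asarray(exp_data, dtype=float)
        if exp.shape != base.shape:
            raise ValueError(
                f"exp_data shape {exp.shape} does not match simulation {base.shape}"
            )
        weights = np.abs((exp - base) / exp).ravel()
    return SensitivityMatrix(matrix=S, rows=rows, columns=candidates, row_weights=weights)


def collinearity_index(submatrix: np.ndarray) -> float:
    """``1 / sigma_min`` of the column-normalized submatrix (inf if singular)."""
    norms = np.linalg.norm(submatrix, axis=0)
    if np.any(norms == 0):
        return np.inf
    sigma_min = np.linalg.svd(submatrix / norms, compute_uv=False)[-1]
    if sigma_min <= 0:
        return np.inf
    return float(1.0 / sigma_min)


def _select_base_with_diagnostics(
    S: SensitivityMatrix, target_size: int, collinearity_threshold: float
) -> tuple[list[str], dict[str, float]]:
    """Greedy identifiable subset of the highest-total-sensitivity parameters.

    At each step the remaining candidate with the highest total sensitivity
    whose inclusion keeps the collinearity index of the selected submatrix
    within the threshold is added; selection stops at ``target_size`` or when
    no candidate qualifies. Ties are broken by name order, so the result is
    independent of candidate ordering.
    """
    if target_size > len(S.columns):
        raise SelectionError(
            f"target_size {target_size} exceeds candidate count {len(S.columns)}"
        )
    if not np.any(S.matrix):
        raise SelectionError("all-zero sensitivity matrix: nothing is identifiable")
    ts = S.total_sensitivity()
    order = sorted(S.columns, key=lambda n: (-ts[n], n))
    w = np.sqrt(S._weights())[:, None]
    weighted = w * S.matrix

    selected: list[str] = []
    gammas: dict[str, float] = {}
    for _ in range(target_size):
        added = False
        for name in order:
            if name in selected or ts[name] <= 0:
                continue
            trial = selected + [name]
            cols = [S.columns.index(n) for n in trial]
            gamma = collinearity_index(weighted[:, cols])
            if gamma <= collinearity_threshold:
                selected.append(name)
                gammas[name] = gamma
                added = True
                break
        if not added:
            break
    if not selected:
        raise SelectionError("no identifiable candidate under the collinearity threshold")
    return selected, gammas


def select_base_set(
    S: SensitivityMatrix,
    target_size: int = DEFAULT_TARGET_SIZE,
    collinearity_threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
) -> list[str]:
    """Greedy identifiable subset (see :func:`_select_base_with_diagnostics`)."""
    return _select_base_with_diagnostics(S, target_size, collinearity_threshold)[0]


def select_specific_sets(
    S: SensitivityMatrix,
    base_set: Sequence[str],
    dominance_ratio: float = DEFAULT_DOMINANCE_RATIO,
) -> dict[str, list[str]]:
    """Per-variable refinement parameters with dominant relative sensitivity.

    For each output variable, the non-base candidate maximizing the ratio of
    its sensitivity to that variable over its largest sensitivity to any other
    variable is assigned, provided the ratio reaches ``dominance_ratio``.
    Variables may map to empty lists.
    """
    if not dominance_ratio > 1:
        raise ValueError("dominance_ratio must exceed 1")
    pv = S.per_variable()
    free = [n for n in S.columns if n not in set(base_set)]
    out: dict[str, list[str]] = {v: [] for v in pv.index}
    if not free:
        return out
    for var in pv.index:
        best_name, best_ratio = None, -np.inf
        for name in free:
            own = pv.at[var, name]
            if own <= 0:
                continue
            others = pv[name].drop(index=var)
            other_max = float(others.max()) if len(others) else 0.0
            ratio = np.inf if other_max == 0 else own / other_max
            if ratio > best_ratio or (ratio == best_ratio and best_name and name < best_name):
                best_name, best_ratio = name, ratio
        if best_name is not None and best_ratio >= dominance_ratio:
            out[var] = [best_name]
    return out


def select_parameters(
    model: PhysiologicalModel,
    params: ParameterSet,
    stimuli: Sequence[StimulusLevel],
    env: EnvironmentConditions,
    exp_data: np.ndarray | None = None,
    target_size: int = DEFAULT_TARGET_SIZE,
    collinearity_threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
    dominance_ratio: float = DEFAULT_DOMINANCE_RATIO,
) -> SelectionResult:
    """Full selection pipeline: roles -> sensitivity matrix -> base + specific sets."""
    S = build_sensitivity_matrix(model, params, stimuli, env, exp_data=exp_data)
    base, gammas = _select_base_with_diagnostics(S, target_size, collinearity_threshold)
    specific = select_specific_sets(S, base, dominance_ratio)
    ts = S.total_sensitivity()
    selected_for = {}
    for var, names in specific.items():
        for n in names:
            selected_for.setdefault(n, []).append(var)
    diag = pd.DataFrame({
        "parameter": S.columns,
        "total_sensitivity": [ts[n] for n in S.columns],
        "collinearity_at_inclusion": [gammas.get(n, np.nan) for n in S.columns],
        "selected_for": [
            "base" if n in base else ",".join(selected_for.get(n, [])) for n in S.columns
        ],
    })
    return SelectionResult(base_set=base, specific_sets=specific, diagnostics=diag)
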