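"""Parameter classification and sensitivity-based selection."""

import numpy as np
import pytest

from dynfit import (
    ParameterSet, SelectionError, StimulusLevel, build_sensitivity_matrix,
    classify_by_role, select_base_set, select_specific_sets,
)
from dynfit.parameters import ModelParameter
from dynfit.selection import SensitivityMatrix, collinearity_index

GAIN_THRESHOLD_NAMES = {
    "Gc", "Gp", "Gm", "kVT", "GHR", "GPM", "GPP", "Bc", "KpO2", "rI", "VTmax",
}


class LinearToyModel:
    """y_j = sum_i J_ji * theta_i with known Jacobian; one stimulus-independent map."""

    def __init__(self, jacobian, names):
        self.J = np.asarray(jacobian, dtype=float)
        self.names = list(names)
        self.variable_names = [f"y{j}" for j in range(self.J.shape[0])]

    def default_parameters(self):
        return ParameterSet(
            ModelParameter(name=n, nominal=1.0, role="gain_threshold") for n in self.names
        )

    def simulate_grid(self, params, stims, env):
        theta = params.values(self.names)
        y = self.J @ theta
        return np.tile(y[:, None], (1, len(stims)))


def test_roles_partition_the_parameter_set(nominal_params):
    groups = classify_by_role(nominal_params)
    assert set(groups["gain_threshold"]) == GAIN_THRESHOLD_NAMES
    all_names = [n for names in groups.values() for n in names]
    assert sorted(all_names) == sorted(nominal_params.names)


def test_roles_of_empty_set_are_five_empty_groups():
    groups = classify_by_role(ParameterSet([]))
    assert len(groups) == 5
    assert all(v == [] for v in groups.values())


def test_linear_map_has_unit_relative_sensitivity():
    toy = LinearToyModel([[2.0]], ["a"])
    params = toy.default_parameters()
    S = build_sensitivity_matrix(toy, params, [StimulusLevel(0.3, 0.3)], None,
                                 candidates=["a"])
    # y = a*x: relative output change equals relative parameter change exactly
    assert S.matrix == pytest.approx(np.ones_like(S.matrix), abs=1e-9)


def test_numeric_sensitivities_match_analytic_jacobian():
    J = np.array([[2.0, 0.5], [0.0, 3.0]])
    toy = LinearToyModel(J, ["a", "b"])
    params = toy.default_parameters()
    S = build_sensitivity_matrix(toy, params, [StimulusLevel(0.3, 0.3)], None)
    y0 = J @ np.ones(2)
    analytic = J / y0[:, None]  # relative sensitivity at theta = 1
    assert S.matrix[[0, 1], :] == pytest.approx(analytic, rel=1e-6)


def test_uninfluential_parameter_gives_zero_column(model, nominal_params, env):
    # tau_HR plays no role at steady state
    S = build_sensitivity_matrix(
        model, nominal_params, [StimulusLevel(0.4, 0.36)], env,
        candidates=["Gc", "tau_HR"],
    )
    assert np.all(S.matrix[:, 1] == 0.0)
    assert np.any(S.matrix[:, 0] != 0.0)


def test_zero_weights_when_data_equals_simulation(model, nominal_params, env):
    stims = [StimulusLevel(0.4, 0.36)]
    exp = model.simulate_grid(nominal_params, stims, env)
    S = build_sensitivity_matrix(model, nominal_params, stims, env, exp_data=exp)
    assert np.all(S.row_weights == 0.0)


def _matrix(cols, names):
    m = np.asarray(cols, dtype=float).T
    return SensitivityMatrix(
        matrix=m,
        rows=[("y", k) for k in range(m.shape[0])],
        columns=list(names),
        row_weights=np.zeros(m.shape[0]),
    )


class TestBaseSet:
    def test_orthogonal_columns_both_selected(self):
        S = _matrix([[1, 0, 0], [0, 1, 0]], ["a", "b"])
        assert select_base_set(S, target_size=2) == ["a", "b"]
        assert collinearity_index(S.matrix) == pytest.approx(1.0)

    def test_duplicated_column_only_one_selected(self):
        S = _matrix([[1, 1, 0], [1, 1, 0], [0, 0, 1]], ["a", "b", "c"])
        selected = select_base_set(S, target_size=2, collinearity_threshold=15)
        assert len([n for n in selected if n in ("a", "b")]) == 1
        assert "c" in selected

    def test_target_one_returns_highest_total_sensitivity(self):
        S = _matrix([[0.1, 0.1], [5.0, 5.0], [0.2, 0.0]], ["a", "b", "c"])
        assert select_base_set(S, target_size=1) == ["b"]

    def test_all_zero_matrix_raises(self):
        S = _matrix([[0, 0], [0, 0]], ["a", "b"])
        with pytest.raises(SelectionError):
            select_base_set(S, target_size=1)

    def test_permutation_invariance(self):
        cols = [[1.0, 0.2, 0], [0.3, 2.0, 0.1], [0, 0.5, 1.0]]
        names = ["a", "b", "c"]
        S1 = _matrix(cols, names)
        S2 = _matrix([cols[2], cols[0], cols[1]], [names[2], names[0], names[1]])
        assert set(select_base_set(S1, 2)) == set(select_base_set(S2, 2))


class TestSpecificSets:
    def test_exclusive_parameter_always_selected(self):
        S = SensitivityMatrix(
            matrix=np.array([[1.0], [0.0]]),
            rows=[("u", 0), ("v", 0)],
            columns=["p"],
            row_weights=np.zeros(2),
        )
        out = select_specific_sets(S, base_set=[], dominance_ratio=100.0)
        assert out["u"] == ["p"] and out["v"] == []

    def test_uniform_effects_select_nothing(self):
        S = SensitivityMatrix(
            matrix=np.ones((4, 2)),
            rows=[("u", 0), ("u", 1), ("v", 0), ("v", 1)],
            columns=["p", "q"],
            row_weights=np.zeros(4),
        )
        out = select_specific_sets(S, base_set=[], dominance_ratio=2.0)
        assert all(v == [] for v in out.values())

    def test_heart_rate_gain_assigned_to_hr(self, model, nominal_params, env):
        # GHR acts on heart rate only; with GHR outside the base set it must
        # be picked as hr's specific refinement parameter.
        stims = [StimulusLevel(v / 0.9, v) for v in (0.3, 0.75, 1.2)]
        S = build_sensitivity_matrix(model, nominal_params, stims, env)
        base = [n for n in GAIN_THRESHOLD_NAMES if n != "GHR"]
        out = select_specific_sets(S, base_set=base, dominance_ratio=2.0)
        assert out["hr"] == ["GHR"]

    def test_base_and_specific_sets_disjoint(self, model, nominal_params, env):
        stims = [StimulusLevel(v / 0.9, v) for v in (0.3, 0.75, 1.2)]
        S = build_sensitivity_matrix(model, nominal_params, stims, env)
        base = select_base_set(S, target_size=6)
        specific = select_specific_sets(S, base)
        chosen = {n for names in specific.values() for n in names}
        assert chosen.isdisjoint(base)
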