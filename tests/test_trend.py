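"""ARX trend models: resampling, least squares, AIC selection and gating."""

import numpy as np
import pytest

from dynfit import (
    ConfigError, FactorSeries, ParameterTrajectory, RankError, TrendConfig,
    aic_score, fit_arx, predict_next_parameters, resample_uniform, select_arx_model,
)
from dynfit.optimization import CostBreakdown, FitResult
from dynfit.parameters import ModelParameter, ParameterSet


def _traj(times, values):
    times = np.asarray(times, dtype=float)
    return ParameterTrajectory(
        "x", times - times[0], np.asarray(values, dtype=float),
        np.ones(len(values), dtype=bool),
    )


def _factors(times, activity=3.0, sleep=7.0, at=1.2):
    n = len(times)
    times = np.asarray(times, dtype=float)
    return FactorSeries(
        times - times[0], np.full(n, activity), np.full(n, sleep), np.full(n, at)
    )


class TestResample:
    def test_linear_midpoint(self):
        t, y, U, ts_eff = resample_uniform(_traj([0, 1], [1.0, 2.0]), _factors([0, 1]), 0.4)
        # ts snaps to 1/round(1/0.4) = 1/3 year... round(2.5) = 2 -> 0.5
        assert ts_eff == pytest.approx(0.5)
        assert y == pytest.approx([1.0, 1.5, 2.0])

    def test_constant_series_stays_constant(self):
        _, y, _, _ = resample_uniform(_traj([0, 2], [3.0, 3.0]), _factors([0, 2]), 0.25)
        assert y == pytest.approx(np.full_like(y, 3.0))

    def test_endpoints_preserved_exactly(self):
        traj = _traj([0, 0.7, 1.3], [1.0, 1.9, 0.4])
        t, y, _, _ = resample_uniform(traj, _factors([0, 0.7, 1.3]), 0.4)
        assert t[0] == 0.0 and t[-1] == pytest.approx(1.3)
        assert y[0] == 1.0 and y[-1] == pytest.approx(0.4)

    def test_out_of_range_sampling_time(self):
        with pytest.raises(ConfigError):
            resample_uniform(_traj([0, 1], [1.0, 2.0]), _factors([0, 1]), 0.05)


class TestFitARX:
    def test_noiseless_arx11_exact_recovery(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(-1, 1, 60)
        y = np.zeros(60)
        for n in range(1, 60):
            y[n] = 0.8 * y[n - 1] + 0.5 * u[n]
        model = fit_arx(y, u[:, None], na=1, nb=1)
        assert model.coeffs_a[0] == pytest.approx(-0.8, abs=1e-8)
        assert model.coeffs_b[0, 0] == pytest.approx(0.5, abs=1e-8)
        assert model.fit_pct > 99.99

    def test_constant_series_persistence_model(self):
        y = np.full(10, 2.5)
        model = fit_arx(y, None, na=1, nb=0)
        assert model.coeffs_a[0] == pytest.approx(-1.0)
        assert model.loss_v == pytest.approx(0.0, abs=1e-20)
        assert model.fit_pct == 100.0

    def test_loss_is_mean_squared_residual(self):
        rng = np.random.default_rng(7)
        y = np.cumsum(rng.normal(size=40))
        model = fit_arx(y, None, na=2, nb=0)
        # independent residual bookkeeping
        resid = []
        for n in range(2, 40):
            pred = -model.coeffs_a[0] * y[n - 1] - model.coeffs_a[1] * y[n - 2]
            resid.append(y[n] - pred)
        assert model.loss_v == pytest.approx(np.mean(np.square(resid)), abs=1e-12)
        assert model.n_samples == 38

    def test_singular_regressors_raise_rank_error(self):
        y = np.arange(10.0)
        U = np.ones((10, 2))  # two identical constant inputs
        with pytest.raises(RankError):
            fit_arx(y, U, na=0, nb=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_generator_coefficients_recovered_when_full_rank(self, seed):
        rng = np.random.default_rng(seed)
        a1 = rng.uniform(-0.9, 0.9)
        b = rng.uniform(-1, 1, size=2)
        u = rng.normal(size=(50, 2))
        y = np.zeros(50)
        for n in range(1, 50):
            y[n] = -a1 * y[n - 1] + u[n] @ b
        model = fit_arx(y, u, na=1, nb=1)
        assert model.coeffs_a[0] == pytest.approx(a1, abs=1e-8)
        assert model.coeffs_b[:, 0] == pytest.approx(b, abs=1e-8)


class TestAIC:
    def test_known_values(self):
        assert aic_score(1.0, 0, 5) == 0.0
        assert aic_score(np.e, 10, 10) == pytest.approx(3.0)
        assert aic_score(0.01, 2, 10) == pytest.approx(np.log(0.01) + 0.4)

    def test_monotone_in_complexity_and_loss(self):
        assert aic_score(0.5, 3, 20) > aic_score(0.5, 2, 20)
        assert aic_score(0.6, 2, 20) > aic_score(0.5, 2, 20)

    def test_zero_loss_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            val = aic_score(0.0, 1, 10)
        assert val == pytest.approx(np.log(1e-12) + 0.2)


class TestSelectARX:
    def test_linear_trajectory_hits_loss_floor(self):
        traj = _traj([0, 1, 2], [1.0, 1.2, 1.4])
        model = select_arx_model(traj, _factors([0, 1, 2]))
        assert model is not None
        assert model.loss_v < 1e-15

    def test_short_history_admits_only_one_coefficient(self):
        # two records, coarse grid: only na=1 fits below the sample count
        traj = _traj([0, 0.8], [1.0, 1.3])
        model = select_arx_model(traj, _factors([0, 0.8]),
                                 TrendConfig(ts_grid=(0.4,)))
        assert model is not None and model.d == 1

    def test_ties_resolve_to_smallest_d_then_ts(self):
        # constant trajectory: every admissible model nails it -> d=1 and the
        # shortest sampling time win
        traj = _traj([0, 1, 2], [2.0, 2.0, 2.0])
        model = select_arx_model(traj, _factors([0, 1, 2]))
        assert model.d == 1
        assert model.ts == pytest.approx(0.1)


def _history(values, name="Gc", times=None, bounds=(-10.0, 10.0)):
    """Minimal fit-history fixture around a single tracked parameter."""
    times = list(range(len(values))) if times is None else times
    cb = CostBreakdown(cf=0.0, per_variable={}, n_variables=0, n_levels=0)
    out = []
    for t, v in zip(times, values):
        ps = ParameterSet([ModelParameter(
            name=name, nominal=values[0], role="gain_threshold",
            bound_low=bounds[0], bound_high=bounds[1], value=v,
        )])
        out.append(FitResult(
            record_id=f"r{t}", params=ps, cf_initial=cb, cf_final=cb,
            factors={"time_years": float(t), "activity_h_week": 3.0,
                     "sleep_h_day": 7.0, "at_vco2": 1.2},
        ))
    return out


class TestPredictionGating:
    def test_constant_parameter_not_modeled(self):
        history = _history([1.0, 1.0, 1.0])
        (out,) = predict_next_parameters(history, names=["Gc"])
        assert out.status == "not_modeled"
        assert out.value == 1.0

    def test_linear_drift_extrapolates_exactly(self):
        history = _history([1.0, 1.2, 1.4])
        cfg = TrendConfig(horizon_years=1.0)
        (out,) = predict_next_parameters(history, config=cfg, names=["Gc"])
        assert out.status == "accepted"
        assert out.value == pytest.approx(1.6, abs=1e-6)

    def test_sign_flip_rejected_with_fallback(self):
        history = _history([1.2, 0.7, 0.2])
        (out,) = predict_next_parameters(history, names=["Gc"])
        assert out.status == "rejected_sign"
        assert out.value == 0.2

    def test_range_jump_rejected_with_fallback(self):
        history = _history([1.0, 1.3, 1.9])
        (out,) = predict_next_parameters(history, names=["Gc"])
        assert out.status == "rejected_range"
        assert out.value == 1.9

    def test_poor_fit_rejected_with_fallback(self):
        history = _history([1.0, 1.4, 0.8, 1.3])
        cfg = TrendConfig(ts_grid=(0.4,), na_max=1, nb_max=0)
        (out,) = predict_next_parameters(history, config=cfg, names=["Gc"])
        assert out.status == "rejected_gof"
        assert out.value == 1.3

    def test_every_parameter_gets_exactly_one_status(self, model):
        nominal = model.default_parameters()
        cb = CostBreakdown(cf=0.0, per_variable={}, n_variables=0, n_levels=0)
        history = []
        for t in range(3):
            ps = nominal.with_values({"GHR": 33.0 - t, "Gc": 1.2 + 0.05 * t})
            history.append(FitResult(
                record_id=f"r{t}", params=ps, cf_initial=cb, cf_final=cb,
                factors={"time_years": float(t), "activity_h_week": 3.0,
                         "sleep_h_day": 7.0, "at_vco2": 1.2},
            ))
        outcomes = predict_next_parameters(history)
        names = [o.name for o in outcomes]
        assert sorted(names) == sorted(nominal.by_role("gain_threshold"))
        assert all(o.status in ("accepted", "rejected_gof", "rejected_sign",
                                "rejected_range", "not_modeled") for o in outcomes)

    def test_prediction_is_deterministic(self):
        history = _history([1.0, 1.15, 1.4, 1.5])
        a = predict_next_parameters(history, names=["Gc"])
        b = predict_next_parameters(history, names=["Gc"])
        assert a[0].status == b[0].status
        assert a[0].value == b[0].value

    def test_empty_history_raises(self):
        with pytest.raises(ValueError):
            predict_next_parameters(_history([1.0]))
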