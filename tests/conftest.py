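import numpy as np
import pandas as pd
import pytest

from dynfit import (
    CardioRespSurrogate, EnvironmentConditions, LongitudinalRecord,
    StimulusLevel, SubjectAnthropometrics,
)
from dynfit.synth import stimulus_grid


@pytest.fixture(scope="session")
def model():
    return CardioRespSurrogate()


@pytest.fixture(scope="session")
def env():
    return EnvironmentConditions()


@pytest.fixture()
def nominal_params(model):
    return model.default_parameters()


@pytest.fixture(scope="session")
def make_record(model, env):
    """Factory for noiseless records simulated from given 'true' parameters."""

    def _make(true_params, at_vco2=1.2, record_id="R1", time_years=0.0,
              activity=3.0, sleep=7.0, height=170.0, weight=75.0, age=30.0):
        vo2, vco2 = stimulus_grid(at_vco2)
        stims = [StimulusLevel(o, c) for o, c in zip(vo2, vco2)]
        obs = model.simulate_grid(true_params, stims, env)
        return LongitudinalRecord(
            record_id=record_id,
            subject_id="S1",
            time_years=time_years,
            stimulus_vo2=vo2,
            stimulus_vco2=vco2,
            observations=pd.DataFrame(obs, index=list(model.variable_names)),
            anthro=SubjectAnthropometrics(height=height, weight=weight, age=age),
            env=env,
            activity_h_week=activity,
            sleep_h_day=sleep,
            at_vco2=at_vco2,
        )

    return _make


def bisect_ventilation(model, params, stim, env, lo=0.5, hi=300.0, iters=80):
    """Independent scalar bisection oracle on the ventilation residual."""
    f_lo = model.ventilation_residual(lo, params, stim, env)
    if f_lo >= 0:
        return lo
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if model.ventilation_residual(mid, params, stim, env) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
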