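"""Compact self-regulated steady-state cardiorespiratory model.

The model maps an exercise stimulus (O2 uptake ``vo2`` and CO2 output ``vco2``,
both L/min) to ten steady-state cardiorespiratory variables: minute ventilation
(ve), tidal volume (vt), breathing frequency (bf), inspiratory time (ti), heart
rate (hr), systolic/mean/diastolic arterial pressures (ps, pm, pd) and alveolar
O2/CO2 partial pressures (pao2, paco2).

Ventilation is the closed-loop state: alveolar gas tensions follow from the
alveolar ventilation through the gas-balance equations, and a chemoreflex +
metabolic controller returns the ventilatory demand for those tensions. The
steady state is the fixed point ``ve = controller(gas_balance(ve))``, solved by
damped iteration with adaptive damping (the loop gain of the CO2 feedback can
exceed the fixed-damping stability limit for extreme parameter draws).

This is a demonstration model: it exposes the same variable set, parameter
roles and calling contract as a full multi-compartmental cardiorespiratory
model, so that any model implementing :class:`PhysiologicalModel` can stand
behind the fitting machinery. Its parameter values are package-chosen for a
healthy adult at moderate altitude and are documented in
``data/surrogate_params.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .exceptions import ConvergenceError, InfeasibleStateError
from .parameters import ParameterSet, load_default_parameters

#: Saturated water vapor pressure at body temperature, mmHg.
P_H2O = 47.0
#: Lower floor for minute ventilation, L/min.
VE_FLOOR = 0.5
#: Upper cap for the ventilation iterate, L/min (well above any physiological value).
VE_CAP = 300.0

VARIABLE_NAMES = ("ve", "vt", "bf", "ti", "hr", "ps", "pm", "pd", "pao2", "paco2")


@dataclass(frozen=True)
class StimulusLevel:
    """Exercise intensity expressed through metabolic gas exchange rates."""

    vo2: float  # O2 uptake, L/min
    vco2: float  # CO2 output, L/min

    def __post_init__(self) -> None:
        if not (self.vo2 > 0 and self.vco2 > 0):
            raise ValueError(f"stimulus rates must be positive, got {self}")


@dataclass(frozen=True)
class EnvironmentConditions:
    """Inspired gas fractions (%, dry) and atmospheric pressure (mmHg)."""

    fio2: float = 21.0379
    fico2: float = 0.0421
    patm: float = 640.0

    def __post_init__(self) -> None:
        if not (0 < self.fio2 < 100):
            raise ValueError(f"fio2 must be in (0, 100), got {self.fio2}")
        if not (0 <= self.fico2 < 100):
            raise ValueError(f"fico2 must be in [0, 100), got {self.fico2}")
        if not self.patm > 0:
            raise ValueError(f"patm must be positive, got {self.patm}")

    @property
    def pio2(self) -> float:
        """Water-vapor-corrected inspired O2 partial pressure, mmHg."""
        return self.fio2 / 100.0 * (self.patm - P_H2O)

    @property
    def pico2(self) -> float:
        """Water-vapor-corrected inspired CO2 partial pressure, mmHg."""
        return self.fico2 / 100.0 * (self.patm - P_H2O)


@dataclass(frozen=True)
class SteadyStateOutput:
    """Steady-state values of the ten cardiorespiratory variables."""

    ve: float   # minute ventilation, L/min
    vt: float   # tidal volume, L
    bf: float   # breathing frequency, 1/min
    ti: float   # inspiratory time, s
    hr: float   # heart rate, bpm
    ps: float   # systolic pressure, mmHg
    pm: float   # mean pressure, mmHg
    pd: float   # diastolic pressure, mmHg
    pao2: float   # alveolar O2 partial pressure, mmHg
    paco2: float  # alveolar CO2 partial pressure, mmHg

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in VARIABLE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in VARIABLE_NAMES])


@runtime_checkable
class PhysiologicalModel(Protocol):
    """Contract a physiological model must satisfy to be fitted by this package.

    Any model exposing a role-annotated default parameter set, a steady-state
    simulator and the list of predicted variable names can replace the
    demonstration model, including full multi-compartmental cardiorespiratory
    models.
    """

    variable_names: Sequence[str]

    def default_parameters(self) -> ParameterSet: ...

    def simulate_steady_state(
        self, params: ParameterSet, stim: StimulusLevel, env: EnvironmentConditions
    ) -> SteadyStateOutput: ...

    def simulate_grid(
        self,
        params: ParameterSet,
        stims: Sequence[StimulusLevel],
        env: EnvironmentConditions,
    ) -> np.ndarray: ...


class CardioRespSurrogate:
    """Demonstration cardiorespiratory model (see module docstring)."""

    variable_names = VARIABLE_NAMES

    def __init__(self, tol: float = 1e-6, max_iter: int = 500):
        self.tol = tol
        self.max_iter = max_iter

    def default_parameters(self) -> ParameterSet:
        return load_default_parameters()

    # -- internals -----------------------------------------------------------
    @staticmethod
    def _vt_of_ve(ve: np.ndarray, p: dict[str, float]) -> np.ndarray:
        return np.clip(p["VTn"] + p["kVT"] * (ve - p["VEn"]), p["VTn"], p["VTmax"])

    @classmethod
    def _controller_of_ve(
        cls,
        ve: np.ndarray,
        p: dict[str, float],
        vo2: np.ndarray,
        vco2: np.ndarray,
        env: EnvironmentConditions,
    ) -> np.ndarray:
        """Ventilatory demand returned by the controller for gas tensions at ``ve``."""
        vt = cls._vt_of_ve(ve, p)
        if np.any(vt <= p["V0dead"]):
            raise InfeasibleStateError(
                f"tidal volume {vt.min():.3f} L does not exceed dead space {p['V0dead']:.3f} L"
            )
        va = ve * (1.0 - p["V0dead"] / vt)  # alveolar ventilation, L/min
        paco2 = env.pico2 + p["k_gas"] * vco2 / va
        pao2 = env.pio2 - p["k_gas"] * vo2 / va
        hypoxic = p["Gp"] * np.exp(np.minimum(-pao2 / p["KpO2"], 30.0))
        drive = p["Gc"] * (paco2 - p["Bc"]) + hypoxic + p["Gm"] * vco2
        return np.maximum(VE_FLOOR, drive)

    def _solve_ve(
        self, p: dict[str, float], vo2: np.ndarray, vco2: np.ndarray, env: EnvironmentConditions
    ) -> np.ndarray:
        """Vectorized bisection for the ventilation fixed point.

        The residual ``h(ve) = ve - controller(gas_balance(ve))`` is strictly
        increasing in ``ve`` (alveolar ventilation rises with ``ve``, so CO2
        drive falls), hence the root is unique and bracketed by the floor/cap
        pair; bisection converges unconditionally even where the chemoreflex
        loop gain would destabilize damped fixed-point iteration.
        """

        def h(ve: np.ndarray) -> np.ndarray:
            return ve - self._controller_of_ve(ve, p, vo2, vco2, env)

        lo = np.full_like(vo2, VE_FLOOR)
        hi = np.full_like(vo2, VE_CAP)
        # at the floor the controller output is itself floored, so h(lo) <= 0
        # always; h(hi) > 0 for any physiological parameter draw.
        h_hi = h(hi)
        if np.any(h_hi < 0):
            bad = int(np.argmax(h_hi < 0))
            raise ConvergenceError(
                f"ventilation demand exceeds {VE_CAP} L/min at stimulus "
                f"vo2={vo2.flat[bad]:.3f}, vco2={vco2.flat[bad]:.3f} L/min"
            )
        ve = 0.5 * (lo + hi)
        for _ in range(self.max_iter):
            resid = h(ve)
            if np.all(np.abs(resid) < self.tol):
                return ve
            neg = resid < 0
            lo = np.where(neg, ve, lo)
            hi = np.where(neg, hi, ve)
            ve = 0.5 * (lo + hi)
        resid = h(ve)
        bad = int(np.argmax(np.abs(resid)))
        raise ConvergenceError(
            f"ventilation fixed point did not converge at stimulus "
            f"vo2={vo2.flat[bad]:.3f}, vco2={vco2.flat[bad]:.3f} L/min "
            f"(residual {resid.flat[bad]:.2e} L/min)"
        )

    def _outputs(
        self, ve: np.ndarray, p: dict[str, float], vo2: np.ndarray, vco2: np.ndarray,
        env: EnvironmentConditions,
    ) -> np.ndarray:
        vt = self._vt_of_ve(ve, p)
        bf = ve / vt
        ti = 60.0 * p["rI"] / bf
        va = ve * (1.0 - p["V0dead"] / vt)
        paco2 = env.pico2 + p["k_gas"] * vco2 / va
        pao2 = env.pio2 - p["k_gas"] * vo2 / va
        hr = p["HR0"] + p["GHR"] * vo2
        pm = p["PM0"] + p["GPM"] * vo2
        pp = p["PP0"] + p["GPP"] * vo2
        pd = pm - pp / 3.0
        ps = pd + pp
        return np.stack([ve, vt, bf, ti, hr, ps, pm, pd, pao2, paco2])

    # -- public surface ------------------------------------------------------
    def simulate_grid(
        self,
        params: ParameterSet,
        stims: Sequence[StimulusLevel],
        env: EnvironmentConditions,
    ) -> np.ndarray:
        """Simulate all stimulus levels at once.

        Returns an array of shape ``(10, K)`` with rows ordered as
        :data:`VARIABLE_NAMES` and columns following ``stims``.
        """
        p = params.to_dict()
        vo2 = np.array([s.vo2 for s in stims], dtype=float)
        vco2 = np.array([s.vco2 for s in stims], dtype=float)
        ve = self._solve_ve(p, vo2, vco2, env)
        return self._outputs(ve, p, vo2, vco2, env)

    def simulate_steady_state(
        self, params: ParameterSet, stim: StimulusLevel, env: EnvironmentConditions
    ) -> SteadyStateOutput:
        """Solve the steady state at one stimulus level."""
        out = self.simulate_grid(params, [stim], env)
        return SteadyStateOutput(*(float(v) for v in out[:, 0]))

    def ventilation_residual(
        self,
        ve_candidate: float,
        params: ParameterSet,
        stim: StimulusLevel,
        env: EnvironmentConditions,
    ) -> float:
        """Fixed-point residual ``ve_candidate - controller(gas_balance(ve_candidate))``.

        Vanishes (to solver tolerance) at the steady-state ventilation; exposed
        so the solver can be checked against independent root finders.
        """
        if not ve_candidate > 0:
            raise ValueError(f"ve_candidate must be positive, got {ve_candidate}")
        p = params.to_dict()
        vo2 = np.array([stim.vo2])
        vco2 = np.array([stim.vco2])
        g = self._controller_of_ve(np.array([ve_candidate]), p, vo2, vco2, env)
        return float(ve_candidate - g[0])
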