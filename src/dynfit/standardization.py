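"""Measurement-derived parameter assignment ("standardization") before fitting.

Before any optimization, every parameter that can be tied directly to an
experimental measurement is set from the record: the environment (inspired gas
fractions, atmospheric pressure), the basal tidal volume VTn, the anaerobic
threshold AT, the total blood volume Vtot derived from body surface area, and
the unstressed blood volume group scaled in proportion to Vtot. This aligns
the simulation conditions with the measured ones and removes those parameters
from the optimization problem.

Total blood volume follows the BSA route::

    BSA  = sqrt(weight_kg * height_cm / 3600)        [m^2]
    Vtot = 1000 * (3.29 * BSA - 1.29)                [mL]

The anaerobic threshold is estimated noninvasively with the v-slope principle:
the VCO2-vs-VO2 relation is fitted with two least-squares line segments over
every admissible interior breakpoint, and AT is the VCO2 value at the
breakpoint of the split minimizing total squared error, provided the second
slope exceeds the first (CO2 output accelerates past the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSeriesError, MissingFieldError
from .model import EnvironmentConditions
from .parameters import ParameterSet
from .records import LongitudinalRecord, SubjectAnthropometrics

__all__ = [
    "SubjectAnthropometrics",
    "StandardizedParameters",
    "BreathSeries",
    "compute_bsa_vtot",
    "scale_volume_group",
    "estimate_at_vslope",
    "standardize_record",
    "VOLUME_GROUP",
]

#: Parameters whose values scale with total blood volume.
VOLUME_GROUP = ("Vu_ven", "Vu_art")

_MIN_SEGMENT = 3  # least points per v-slope segment
_SLOPE_EPS = 1e-9  # required strict slope increase at the breakpoint


@dataclass(frozen=True)
class StandardizedParameters:
    """Summary of the measurement-derived values applied to one record."""

    bsa: float            # body surface area, m^2
    vtot: float           # total blood volume, mL
    vtn: float            # basal tidal volume, L
    at_vco2: float        # anaerobic threshold as VCO2, L/min
    env: EnvironmentConditions
    volume_scale: float   # ratio applied to the unstressed-volume group

    def __post_init__(self) -> None:
        if not (self.bsa > 0 and self.vtot > 0 and self.volume_scale > 0):
            raise ValueError("bsa, vtot and volume_scale must be positive")
        if not self.at_vco2 >= 0.3:
            raise ValueError(f"at_vco2 must be >= 0.3 L/min, got {self.at_vco2}")


@dataclass(frozen=True)
class BreathSeries:
    """Paired VO2/VCO2 samples (L/min) ordered by increasing work rate."""

    vo2: np.ndarray
    vco2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vo2", np.asarray(self.vo2, dtype=float))
        object.__setattr__(self, "vco2", np.asarray(self.vco2, dtype=float))
        if self.vo2.shape != self.vco2.shape or self.vo2.ndim != 1:
            raise ValueError("vo2 and vco2 must be 1-D arrays of equal length")
        if self.vo2.size < 2 * _MIN_SEGMENT:
            raise ValueError(f"breath series needs >= {2 * _MIN_SEGMENT} samples")
        if not (np.all(self.vo2 > 0) and np.all(self.vco2 > 0)):
            raise ValueError("breath series samples must be positive")


def compute_bsa_vtot(anthro: SubjectAnthropometrics) -> tuple[float, float]:
    """Body surface area (m^2) and total blood volume (mL) from anthropometrics."""
    weight = anthro.require("weight")
    height = anthro.require("height")
    bsa = float(np.sqrt(weight * height / 3600.0))
    vtot = 1000.0 * (3.29 * bsa - 1.29)
    if vtot <= 0:
        raise ValueError(
            f"nonphysical anthropometrics: derived blood volume {vtot:.1f} mL <= 0"
        )
    return bsa, vtot


def scale_volume_group(
    params: ParameterSet,
    group: tuple[str, ...] | list[str],
    vtot_subject: float,
    vtot_nominal: float,
) -> ParameterSet:
    """Scale each grouped parameter by the subject/nominal blood-volume ratio.

    Each grouped parameter keeps its nominal proportion of total blood volume:
    ``value = nominal * vtot_subject / vtot_nominal``. Other parameters are
    untouched.
    """
    if not vtot_nominal > 0:
        raise ValueError("vtot_nominal must be positive")
    ratio = vtot_subject / vtot_nominal
    return params.with_values({name: params[name].nominal * ratio for name in group})


def _segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, sse)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def estimate_at_vslope(series: BreathSeries) -> float:
    """Anaerobic threshold (VCO2, L/min) by exhaustive two-segment v-slope fit.

    Candidate breakpoints are the observed VO2 samples with at least
    ``3`` points on each side (the breakpoint sample belongs to both
    segments). Splits whose second slope does not strictly exceed the first
    are rejected; if none remains the series is degenerate.
    """
    x, y = series.vo2, series.vco2
    n = x.size
    best: tuple[float, float] | None = None  # (sse, at_vco2)
    for i in range(_MIN_SEGMENT - 1, n - _MIN_SEGMENT + 1):
        s1, b1, sse1 = _segment_fit(x[: i + 1], y[: i + 1])
        s2, b2, sse2 = _segment_fit(x[i:], y[i:])
        if s2 - s1 <= _SLOPE_EPS * max(1.0, abs(s1)):
            continue
        sse = sse1 + sse2
        at = 0.5 * ((s1 * x[i] + b1) + (s2 * x[i] + b2))
        if best is None or sse < best[0]:
            best = (sse, at)
    if best is None:
        raise DegenerateSeriesError(
            "no interior breakpoint with a slope increase: series has no "
            "detectable anaerobic threshold"
        )
    return best[1]


def _resolve_at(record: LongitudinalRecord) -> float:
    # A directly supplied AT wins over the v-slope estimate.
    if record.at_vco2 is not None:
        return float(record.at_vco2)
    if record.breath_series is not None:
        return estimate_at_vslope(record.breath_series)
    raise MissingFieldError("at_vco2")


def standardize_record(
    record: LongitudinalRecord,
    params: ParameterSet,
    volume_group: tuple[str, ...] = VOLUME_GROUP,
) -> ParameterSet:
    """Assign all measurement-derived parameter values for one record.

    Sets the environment parameters verbatim, VTn from the tidal-volume
    measurement, AT (direct value or v-slope estimate), Vtot from the
    anthropometrics, and rescales the unstressed-volume group. All other
    parameters are left unchanged, so the operation is idempotent.
    """
    if record.anthro is None:
        raise MissingFieldError("anthropometrics")
    bsa, vtot = compute_bsa_vtot(record.anthro)
    updates = {
        "FiO2": record.env.fio2,
        "FiCO2": record.env.fico2,
        "Patm": record.env.patm,
        "VTn": record.resting_vtn(),
        "AT": _resolve_at(record),
        "Vtot": vtot,
    }
    out = params.with_values(updates)
    return scale_volume_group(out, volume_group, vtot, params["Vtot"].nominal)


def standardization_summary(
    record: LongitudinalRecord, params: ParameterSet
) -> StandardizedParameters:
    """The :class:`StandardizedParameters` that :func:`standardize_record` applies."""
    if record.anthro is None:
        raise MissingFieldError("anthropometrics")
    bsa, vtot = compute_bsa_vtot(record.anthro)
    return StandardizedParameters(
        bsa=bsa,
        vtot=vtot,
        vtn=record.resting_vtn(),
        at_vco2=_resolve_at(record),
        env=record.env,
        volume_scale=vtot / params["Vtot"].nominal,
    )
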