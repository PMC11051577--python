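"""Named model parameters with roles, nominal values and optimization bounds.

Physiological models group their parameters by functional role: time constants,
unit-conversion factors, covariates (subject- or environment-linked quantities),
initial values, and gains/thresholds. Only the gain/threshold group has a
physiologically meaningful effect on steady-state predictions and is therefore
eligible for optimization; covariates are standardized from measurements instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping

import numpy as np

from .exceptions import BoundsError

ROLES = (
    "time_constant",
    "conversion",
    "covariate",
    "initial_value",
    "gain_threshold",
)

#: Relative half-widths of the default optimization interval around the nominal
#: value: +/-30% for parameters tied to a direct physiological measure, +/-50%
#: for weighting parameters that are not.
GENERAL_BOUND_PCT = 30.0
UNLINKED_BOUND_PCT = 50.0

# Covariates and other non-optimized parameters get a deliberately loose
# interval so that values standardized from measurements never violate the
# bound invariant.
_WIDE_FACTOR = 10.0


def relative_bounds(nominal: float, pct: float) -> tuple[float, float]:
    """Sign-preserving relative interval ``nominal * (1 -/+ pct/100)``.

    For a negative nominal the interval is mirrored so that low < high always
    holds (e.g. nominal -2 at 30% -> (-2.6, -1.4)).
    """
    if nominal == 0.0:
        raise BoundsError("cannot derive relative bounds for a zero nominal value")
    lo = nominal * (1.0 - pct / 100.0)
    hi = nominal * (1.0 + pct / 100.0)
    return (min(lo, hi), max(lo, hi))


@dataclass
class ModelParameter:
    """One named model parameter: nominal reference, current value and bounds."""

    name: str
    nominal: float
    role: str
    value: float | None = None
    bound_low: float | None = None
    bound_high: float | None = None
    measure_linked: bool = False
    unit: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown parameter role {self.role!r} for {self.name!r}")
        if self.value is None:
            self.value = self.nominal
        if self.bound_low is None or self.bound_high is None:
            if self.role == "gain_threshold":
                pct = GENERAL_BOUND_PCT if self.measure_linked else UNLINKED_BOUND_PCT
                self.bound_low, self.bound_high = relative_bounds(self.nominal, pct)
            else:
                mag = abs(self.nominal) if self.nominal != 0.0 else 1.0
                self.bound_low = self.nominal - _WIDE_FACTOR * mag
                self.bound_high = self.nominal + _WIDE_FACTOR * mag
        self._check()

    def _check(self) -> None:
        if not self.bound_low < self.bound_high:
            raise BoundsError(
                f"{self.name}: bound_low {self.bound_low} must be < bound_high {self.bound_high}"
            )
        if not (self.bound_low <= self.value <= self.bound_high):
            raise BoundsError(
                f"{self.name}: value {self.value} outside bounds "
                f"[{self.bound_low}, {self.bound_high}]"
            )

    def with_value(self, value: float) -> "ModelParameter":
        return replace(self, value=float(value))


class ParameterSet:
    """Ordered, name-keyed collection of :class:`ModelParameter`.

    Lookup is total: indexing an unknown name raises ``KeyError`` naming it.
    """

    def __init__(self, params: Iterable[ModelParameter]):
        self._params: dict[str, ModelParameter] = {}
        for p in params:
            if p.name in self._params:
                raise ValueError(f"duplicate parameter name {p.name!r}")
            self._params[p.name] = p

    # -- mapping-ish surface -------------------------------------------------
    def __iter__(self) -> Iterator[ModelParameter]:
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __getitem__(self, name: str) -> ModelParameter:
        try:
            return self._params[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self._params)

    def value(self, name: str) -> float:
        return self[name].value

    def values(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = self.names if names is None else list(names)
        return np.array([self[n].value for n in names], dtype=float)

    def nominals(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = self.names if names is None else list(names)
        return np.array([self[n].nominal for n in names], dtype=float)

    def bounds(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = self.names if names is None else list(names)
        return np.array([(self[n].bound_low, self[n].bound_high) for n in names], dtype=float)

    def by_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return [p.name for p in self if p.role == role]

    # -- functional updates --------------------------------------------------
    def copy(self) -> "ParameterSet":
        return ParameterSet(replace(p) for p in self)

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        """Return a new set with the given values substituted (bounds checked)."""
        for name in updates:
            self[name]  # raise early on unknown names
        return ParameterSet(
            p.with_value(updates[p.name]) if p.name in updates else replace(p)
            for p in self
        )

    def to_dict(self) -> dict[str, float]:
        return {p.name: p.value for p in self}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self.names == other.names and all(
            self[n].value == other[n].value for n in self.names
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ParameterSet({len(self)} parameters: {', '.join(self.names[:6])}...)"


def load_default_parameters() -> ParameterSet:
    """Load the demonstration model's parameter table shipped as package data."""
    text = resources.files("dynfit.data").joinpath("surrogate_params.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    return ParameterSet(
        ModelParameter(
            name=r["name"],
            nominal=float(r["nominal"]),
            role=r["role"],
            measure_linked=r["measure_linked"] == "1",
            unit=r["unit"],
            description=r["description"],
        )
        for r in rows
    )
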