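"""Exception hierarchy for dynfit.

All errors raised by the library derive from :class:`DynfitError` so callers can
catch the whole family with one clause.
"""


class DynfitError(Exception):
    """Base class for all dynfit errors."""


class ConvergenceError(DynfitError):
    """Steady-state solver failed to converge for a stimulus level."""


class InfeasibleStateError(DynfitError):
    """Model state is physically infeasible (e.g. tidal volume below dead space)."""


class MissingFieldError(DynfitError):
    """A record lacks a measurement required by the requested operation."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"record is missing required field: {field!r}")


class DegenerateSeriesError(DynfitError):
    """A breath series admits no two-segment breakpoint with a slope increase."""


class SelectionError(DynfitError):
    """Parameter selection cannot proceed (e.g. all-zero sensitivity matrix)."""


class BoundsError(DynfitError):
    """Invalid optimization bounds."""


class ConfigError(DynfitError):
    """Invalid configuration value."""


class DependencyError(DynfitError):
    """A pipeline step is missing an upstream artifact."""


class RankError(DynfitError):
    """Singular regressor matrix in a least-squares model fit."""
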