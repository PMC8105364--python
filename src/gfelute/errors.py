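"""Exception hierarchy shared across the package.

All domain errors derive from :class:`EluteError` so callers can catch the
package's failures without touching builtin exceptions raised by bugs.
"""


class EluteError(Exception):
    """Base class for all gfelute domain errors."""


class InvalidParameterError(EluteError, ValueError):
    """A parameter violates its domain (negative rate, zero overtone, ...)."""


class InsufficientDataError(EluteError, ValueError):
    """Too few usable data points for the requested fit or summary."""


class NonPositiveConcentrationError(EluteError, ValueError):
    """A log transform was requested on a concentration <= 0."""


class SchemaError(EluteError, ValueError):
    """Malformed tabular input: missing column, non-monotone times, etc."""


class AggregationError(EluteError, ValueError):
    """Replicate aggregation failed (e.g. an infinite half-life present)."""


class InconsistentMassError(EluteError, ValueError):
    """A cumulative-release fraction exceeds 1 for the supplied M_infinity."""


class InfeasibleSpecError(EluteError, ValueError):
    """A synthetic-data spec is internally inconsistent (e.g. K*t^n > 1)."""
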