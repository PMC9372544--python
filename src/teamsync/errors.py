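"""Exception hierarchy.

All errors raised by this package derive from :class:`TeamsyncError`, so
callers can catch one type at an application boundary (the CLI maps them
to exit code 1).
"""


class TeamsyncError(Exception):
    """Base class for all package errors."""


class SchemaError(TeamsyncError):
    """A table does not conform to the documented CSV dialect (e.g. a
    missing or misnamed column)."""


class ValidationError(TeamsyncError):
    """A structurally well-formed table contains an invalid record; the
    message carries the offending row number where available."""


class ConfigError(TeamsyncError):
    """A simulation or run configuration violates its invariants."""


class UndefinedStatisticError(TeamsyncError):
    """A statistic is undefined for the given input (e.g. connectivity of
    a third with no recorded ball contact)."""


class InsufficientDataError(TeamsyncError):
    """A sample is too small for the requested procedure."""


class DegenerateVarianceError(InsufficientDataError):
    """A variance estimate is exactly zero, so a t-type statistic is
    undefined."""


class PairingError(TeamsyncError):
    """Simulation ground truth and analysis estimates cannot be paired
    (mismatched run identifiers)."""
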