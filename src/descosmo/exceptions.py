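"""Exception hierarchy for descosmo.

All package errors derive from :class:`DescosmoError` so callers can catch
one base class; the CLI maps subclasses onto distinct exit codes.
"""


class DescosmoError(Exception):
    """Base class for all descosmo errors."""


class ValidationError(DescosmoError, ValueError):
    """An input value violates a documented invariant."""


class ProfileParseError(DescosmoError, ValueError):
    """A σ-profile file is malformed; the message names the offending line."""


class SigmaRangeError(DescosmoError, ValueError):
    """A σ value lies outside the grid bounds."""


class GridMismatchError(DescosmoError, ValueError):
    """Two objects live on incompatible σ-grids."""


class DegenerateInputError(DescosmoError, ValueError):
    """Input is degenerate for the requested operation (e.g. zero total area)."""


class ConvergenceError(DescosmoError, RuntimeError):
    """An iterative solve failed to converge within its budget."""


class FixtureIntegrityError(DescosmoError, RuntimeError):
    """A packaged fixture file fails its checksum or completeness check."""


class InsufficientDataError(DescosmoError, ValueError):
    """Too few valid data points for the requested statistic."""


class UndefinedResultError(DescosmoError, ValueError):
    """The requested quantity is undefined for the given records
    (e.g. a fold ratio involving a below-LOQ measurement)."""
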