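"""Exception hierarchy shared across the package."""


class CycleSyncError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CycleSyncError, ValueError):
    """A model or noise parameter violates its constraints."""


class OutOfDomainError(CycleSyncError, ValueError):
    """A time argument falls outside the interval a function is defined on."""


class InvalidInputError(CycleSyncError, ValueError):
    """A sample, series, or table fails a structural precondition."""


class ResamplingCapError(CycleSyncError, RuntimeError):
    """Truncated-noise rejection sampling exceeded its retry cap."""


class FitFailureError(CycleSyncError, RuntimeError):
    """A least-squares fit failed to converge after every start.

    Carries the best attempt (if any) in ``best``.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class SchemaError(CycleSyncError, ValueError):
    """An input table is missing required columns or has malformed values."""
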