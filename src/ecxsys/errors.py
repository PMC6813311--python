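"""Exception hierarchy for the ecxsys package.

All package errors derive from :class:`EcxsysError` so callers can catch a
single base class.  Validation problems (bad input tables, out-of-domain
arguments) and fitting problems (non-convergence, degenerate data) are kept
distinct because the CLI maps them to different exit codes.
"""

from __future__ import annotations


class EcxsysError(Exception):
    """Base class for all ecxsys errors."""


class DomainError(EcxsysError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(EcxsysError, ValueError):
    """Input data violates a structural contract (schema, counts, control)."""


class InsufficientDesignError(ValidationError):
    """The concentration design is too sparse for the requested operation."""


class DesignMismatchError(ValidationError):
    """Two experiments that must share a concentration design do not."""


class DegenerateDataError(EcxsysError, ValueError):
    """Data carry no information for the requested fit (e.g. constant y)."""


class NonConvergenceError(EcxsysError, RuntimeError):
    """An optimizer failed to converge and the result cannot be used."""


class EffectNotReachedError(EcxsysError, RuntimeError):
    """A target effect level is not attained on the searched range."""

    def __init__(self, message: str, search_range: tuple[float, float] | None = None):
        super().__init__(message)
        self.search_range = search_range
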