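"""Exception types shared across the package."""

from __future__ import annotations


class AdCascadeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AdCascadeError):
    """A required column is missing from an input table."""


class TableParseError(AdCascadeError):
    """A cell could not be parsed; carries row/column context in the message."""


class ValidationError(AdCascadeError):
    """An input violates a declared invariant (duplicates, negative counts, ...)."""


class UnknownStratumError(AdCascadeError, KeyError):
    """A stratum (state, region, age band) is absent from a lookup table."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class UndefinedCostError(AdCascadeError, ZeroDivisionError):
    """The expected yield is zero, so a per-outcome cost is undefined.

    This signals "no detectable yield under these parameters", not infinity.
    """


class FittingError(AdCascadeError):
    """Curve fitting failed; ``best`` holds the best iterate when available."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class InfeasibleTargetError(AdCascadeError, ValueError):
    """A reach target at or above the curve's asymptote cannot be attained."""
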