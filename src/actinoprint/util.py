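"""Shared helpers: the package-wide rounding rule and small error types."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


class ActinoprintError(Exception):
    """Base class for package-specific errors."""


class ParameterError(ActinoprintError, ValueError):
    """An argument is outside its documented range."""


class FormatError(ActinoprintError, ValueError):
    """A file does not conform to its declared format."""


class ConfigError(ActinoprintError, ValueError):
    """A configuration object fails validation."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (half-up), not banker's rounding.

    All percentages the package reports go through this one rule so summary
    tables are consistent with each other.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """count/total as a percentage, rounded half-up to ``ndigits`` decimals."""
    if total == 0:
        raise ParameterError("percentage undefined for total == 0")
    return round_half_up(100.0 * count / total, ndigits)
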