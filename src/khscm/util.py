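"""Small shared numerics: report rounding and currency constants."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

#: Fixed study exchange rate, Kenyan shillings per euro.
KSH_PER_EUR = 90.66

#: Default annual inflation uplift applied to the earlier fiscal year.
DEFAULT_INFLATION = 0.05


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (report convention; Python's round() is banker's).

    >>> round_half_away(2.5)
    3.0
    >>> round_half_away(-2.5)
    -3.0
    >>> round_half_away(5.85, 1)
    5.9
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def round_to_nearest(value: float, base: float) -> float:
    """Round to the nearest multiple of ``base`` (half away from zero)."""
    if base <= 0:
        raise ValueError("base must be positive")
    return round_half_away(value / base) * base
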