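"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (10.5 -> 11, -10.5 -> -11).

    Python's built-in ``round`` uses banker's rounding, which does not match
    the half-away convention used for all displayed percentages and expected
    counts in this package.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percent of a zero denominator is undefined")
    return round_half_away(100.0 * numerator / denominator, ndigits)
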