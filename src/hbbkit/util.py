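"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["percent"]


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places (table convention).

    Python's built-in ``round`` is banker's rounding; cohort tables follow
    the usual print convention where e.g. 16.25 -> 16.3.
    """
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    q = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))
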