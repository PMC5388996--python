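"""Small shared numerics: decimal rounding matching printed report precision."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, dp: int = 0) -> float:
    """Round ``x`` to ``dp`` decimal places, halves away from zero.

    Printed census tables use conventional half-up rounding, not the
    banker's rounding of Python's built-in ``round``.
    """
    if dp < 0:
        raise ValueError("dp must be >= 0")
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, dp: int) -> float:
    """``100 * count / total`` rounded half-up to ``dp`` decimals."""
    if total == 0:
        raise ZeroDivisionError("total is zero")
    return round_half_up(100.0 * count / total, dp)
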