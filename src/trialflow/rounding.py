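"""Half-up decimal rounding — the printed-table convention.

Expected treatment counts are continuous; published tables print them
rounded half-up to one decimal and then form percentages from the rounded
counts.  Python's builtin ``round`` is banker's rounding (16.25 -> 16.2),
so the convention needs its own helper.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round1"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero upward."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round1(x: float) -> float:
    """One-decimal half-up rounding (the table convention)."""
    return round_half_up(x, 1)
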