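"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as in printed summary tables.

    Python's built-in ``round`` is banker's rounding; summary tables in this
    field conventionally round 0.005 up to 0.01.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(x: float) -> str:
    """Format a percentage to two decimals (half-up)."""
    return f"{round_half_up(x, 2):.2f}"
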