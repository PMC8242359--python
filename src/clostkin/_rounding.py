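"""Decimal rounding helpers for table-style reporting.

Python's built-in round() is banker's rounding; printed fermentation and
screening tables use conventional half-up, so reported values go through
these helpers. Raw floats are always kept alongside.
"""

from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int) -> float:
    """Round `x` to `ndigits` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int) -> float:
    """Drop digits beyond `ndigits` decimals without rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))
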