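"""Half-up decimal rounding for percentage display.

Python's built-in ``round`` uses banker's rounding; clinical summary tables
round half away from zero (15.75 -> 15.8), so percentages everywhere in the
package go through these helpers.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent"]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(proportion: float, ndigits: int = 1) -> float:
    """Express a proportion as a percentage, half-up rounded."""
    return round_half_up(100.0 * proportion, ndigits)
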