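"""Small shared helpers: half-up rounding and percentage formatting.

Percentages in all emitted tables are rounded half-up (not banker's
rounding) to match the convention of the summary tables they mirror.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round ``x`` to ``decimals`` places, ties away from zero upward."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent_of_total(count: int, total: int, decimals: int = 1) -> float:
    """100 * count / total, rounded half-up to ``decimals`` places.

    The division is carried out exactly (on rationals) before rounding so
    that printed-table arithmetic reproduces bit-for-bit.
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    frac = Fraction(100) * Fraction(int(count), int(total))
    quantum = Decimal(1).scaleb(-decimals)
    dec = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))
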