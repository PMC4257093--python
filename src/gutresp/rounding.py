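"""Fixed rounding convention for reported numbers.

All percentages and rounded figures in reports use round-half-up at the
requested precision, applied to the decimal representation of the value
(so 51.965 % at one decimal is 52.0, not 51.9).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round ``value`` half-up at ``ndigits`` decimals."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(
        Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    )


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up.

    A zero denominator yields 0.0 (empty partitions report 0 %).
    """
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)
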