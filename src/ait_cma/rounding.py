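"""Half-up rounding for reported Danish Kroner / Euro amounts.

All internal arithmetic is carried out unrounded; half-up rounding is applied
only at the reporting layer (tables, printed totals) and for the conventional
one-decimal maintenance-visit rate.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` half away from zero to ``ndigits`` decimal places.

    Python's builtin ``round`` uses banker's rounding; reported monetary
    amounts and the visits-per-year rate follow the commercial half-up rule
    (8.6667 -> 8.7, 26,858.47 -> 26,858).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
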