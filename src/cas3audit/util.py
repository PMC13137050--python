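"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent_1dp(numerator: int, denominator: int) -> float:
    """Exact ratio as a percentage, half-up rounded to one decimal place.

    Computed in decimal arithmetic so that e.g. 8/154 -> 5.2 and
    65/746 -> 8.7 without binary-float rounding artifacts.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
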