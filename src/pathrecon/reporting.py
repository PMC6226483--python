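"""Small reporting helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for reported
    integer percentages), unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage rounded half-up; 0 for an empty denominator."""
    if not denominator:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)
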