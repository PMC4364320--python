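"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, digits: int = 2) -> float:
    """Round half away from zero (the convention used in printed tables)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, digits: int = 2) -> float:
    """Exact-rational percentage, rounded half-up to ``digits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-digits)
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )
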