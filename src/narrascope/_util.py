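"""Small numeric helpers shared across the pipeline."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (half-up), not banker's rounding.

    Printed percentages in the source tables follow half-up convention
    (e.g. 60.18288% -> 60.18, 2.4529 -> 2.45), which ``round()`` would
    sometimes miss on exact .5 ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def share_pct(count: int, total: int) -> float:
    """Percentage 100*count/total, half-up to 2 decimals.

    Raises ValueError if total is zero or count is out of [0, total].
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    return round_half_up(100.0 * count / total, 2)
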