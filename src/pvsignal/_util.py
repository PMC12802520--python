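"""Small numeric helpers used across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed summary tables).

    Python's builtin ``round`` is banker's rounding; report tables round
    77.905 up to 77.91, so percentages go through this helper instead.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: float, total: float, ndigits: int = 2) -> float:
    """Percentage of ``count`` in ``total`` rounded half-up; 0.0 for empty totals."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


def derive_seed(seed: int, k: int) -> int:
    """Deterministic sub-seed for the k-th consumer of a master seed (< 2^31)."""
    return (seed * 1_000_003 + k) % (2**31)
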