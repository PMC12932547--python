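"""Set-level comparison of two differential screens and summary fractions."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import UndefinedStatisticError


@dataclass(frozen=True)
class MethodComparison:
    """Venn partition of two differential-genus sets.

    ``a_only`` are genera the second method did not detect; ``b_only``
    are new genera the second method rescued.
    """

    set_a: frozenset[str]
    set_b: frozenset[str]
    common: frozenset[str]
    a_only: frozenset[str]
    b_only: frozenset[str]


def compare_sets(a, b) -> MethodComparison:
    """Exact partition of two genus sets into common / a-only / b-only."""
    a, b = frozenset(a), frozenset(b)
    return MethodComparison(
        set_a=a,
        set_b=b,
        common=a & b,
        a_only=a - b,
        b_only=b - a,
    )


def upregulated_fraction(n_up: int, n_down: int, digits: int | None = 2) -> float:
    """Percent of differential genera that are upregulated: 100 * up / (up + down).

    Rounded half-up to ``digits`` decimals for display (``digits=None``
    returns the raw value). Both counts zero is undefined.
    """
    if n_up < 0 or n_down < 0:
        raise UndefinedStatisticError("counts must be non-negative")
    total = n_up + n_down
    if total == 0:
        raise UndefinedStatisticError("fraction undefined: no differential genera")
    raw = 100.0 * n_up / total
    if digits is None:
        return raw
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(raw)).quantize(q, rounding=ROUND_HALF_UP))
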