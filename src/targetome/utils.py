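"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
import warnings
from typing import Sequence


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (3.5 -> 4, -3.5 -> -4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def largest_remainder_counts(
    percentages: Sequence[float], n: int, warn: bool = True
) -> list[int]:
    """Integer counts summing to ``n`` that realize ``percentages`` (summing to 100).

    Floor each share, then hand out the remaining units by descending
    fractional remainder (ties -> earlier entry).  When a share is not an
    integer at the requested ``n`` a warning notes that largest-remainder
    rounding resolved it.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    total = sum(percentages)
    if abs(total - 100.0) > 1e-9:
        raise ValueError(f"percentages must sum to 100, got {total}")
    raw = [p * n / 100.0 for p in percentages]
    counts = [int(math.floor(v + 1e-9)) for v in raw]
    if warn and any(abs(v - round(v)) > 1e-9 for v in raw):
        warnings.warn(
            "quota percentages are not integral at n=%d; "
            "counts resolved by largest remainder" % n,
            stacklevel=2,
        )
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def counts_to_percent_triple(counts: Sequence[int]) -> list[int]:
    """Integer percentages of ``counts`` reconciled by largest remainder to sum 100."""
    n = sum(counts)
    if n == 0:
        raise ValueError("cannot form percentages of an empty count vector")
    raw = [100.0 * c / n for c in counts]
    pct = [int(math.floor(v + 1e-9)) for v in raw]
    remainder = 100 - sum(pct)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - pct[i]), i))
    for i in order[:remainder]:
        pct[i] += 1
    return pct
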