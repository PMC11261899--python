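"""Determination-breakdown statistics over record collections.

Deployments report submission campaigns as per-category counts and
integer percentages ("61 % no quality control issues, 10 % minor, …").
:func:`summarize_determinations` computes that breakdown for any collection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .records import RecordCollection


@dataclass(frozen=True)
class DeterminationBreakdown:
    """Per-determination counts and half-up-rounded integer percentages.

    With the ``per-category`` counting convention a record carrying several
    distinct determinations contributes to each of them, so counts can
    exceed ``total``; percentages are always relative to ``total`` records
    and, due to rounding, sum to 100 only up to ±(number of categories).
    No renormalization is applied.
    """

    total: int
    per_category: dict[str, tuple[int, int]]

    def counts(self) -> dict[str, int]:
        return {k: v[0] for k, v in self.per_category.items()}

    def percents(self) -> dict[str, int]:
        return {k: v[1] for k, v in self.per_category.items()}


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def summarize_determinations(
    collection: RecordCollection, convention: str = "per-category"
) -> DeterminationBreakdown:
    """Count determinations across a collection.

    ``convention='per-category'`` counts a record once per *distinct*
    determination it carries (duplicates within one record count once);
    ``'first'`` counts only each record's first determination. Labels are
    reported in canonical registry spelling where resolved, as-given
    otherwise; first-seen order is preserved.
    """
    if convention not in ("per-category", "first"):
        raise ValueError(f"unknown counting convention {convention!r}")
    counts: Counter = Counter()
    order: list[str] = []
    total = len(collection.records)
    for record in collection:
        refs = record.determinations
        if convention == "first":
            refs = refs[:1]
        seen_keys = set()
        for ref in refs:
            key = ref.key()
            if key in seen_keys:
                continue
            seen_keys.add(key)
            label = ref.term.label if ref.term is not None else ref.label
            if label not in counts:
                order.append(label)
            counts[label] += 1
    per_category = {
        label: (counts[label], _round_half_up(100.0 * counts[label] / total))
        for label in order
    }
    return DeterminationBreakdown(total=total, per_category=per_category)
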