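"""Descriptive landscape statistics: marginal counts, one-decimal
percentages, subclass frequency tables and dual-indication detection."""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from .candidate_registry import (
    Archetype,
    DEFAULT_ACTIVITY_CUTOFF,
    Indication,
    Phase,
    ProductType,
    Registry,
    is_active,
)
from .errors import UsageError

__all__ = [
    "percent",
    "LandscapeSummary",
    "SubclassTable",
    "summarize",
    "subclass_frequency",
    "dual_indication",
]


def percent(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-up to one decimal.

    Half-up (not banker's) rounding matches the reporting convention used
    throughout the summary tables.
    """
    if denominator <= 0:
        raise UsageError("percentage undefined: denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise UsageError(
            f"numerator must lie in [0, denominator], got "
            f"{numerator}/{denominator}"
        )
    exact = Decimal(numerator) * 100 / Decimal(denominator)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


#: category label -> (count, one-decimal percentage)
Breakdown = dict[str, tuple[int, float]]


@dataclass
class LandscapeSummary:
    total: int
    by_status: Breakdown = field(default_factory=dict)
    by_phase: Breakdown = field(default_factory=dict)
    by_product_type: Breakdown = field(default_factory=dict)
    by_archetype: Breakdown = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "by_status": self.by_status,
            "by_phase": self.by_phase,
            "by_product_type": self.by_product_type,
            "by_archetype": self.by_archetype,
        }


def _breakdown(counts: dict[str, int], total: int) -> Breakdown:
    return {label: (n, percent(n, total)) for label, n in counts.items()}


def summarize(
    registry: Registry, cutoff_year: int = DEFAULT_ACTIVITY_CUTOFF
) -> LandscapeSummary:
    """Marginal counts and percentages by status, phase, type and archetype.

    Deterministic and order-invariant; an empty registry yields total 0 and
    empty breakdowns.
    """
    total = len(registry)
    if total == 0:
        return LandscapeSummary(total=0)
    status_counts = {"active": 0, "inactive": 0}
    phase_counts = {p.value: 0 for p in Phase}
    type_counts = {t.value: 0 for t in ProductType}
    archetype_counts = {a.value: 0 for a in Archetype}
    for cand in registry:
        status_counts["active" if is_active(cand, cutoff_year) else "inactive"] += 1
        phase_counts[cand.phase.value] += 1
        type_counts[cand.product_type.value] += 1
        archetype_counts[cand.archetype.value] += 1
    return LandscapeSummary(
        total=total,
        by_status=_breakdown(status_counts, total),
        by_phase=_breakdown(phase_counts, total),
        by_product_type=_breakdown(type_counts, total),
        by_archetype=_breakdown(archetype_counts, total),
    )


@dataclass
class SubclassTable:
    """Subclass frequencies within one indication scope.

    Rows are ``(subclass, count, percentage)`` sorted by descending count,
    ties broken alphabetically.
    """

    scope: Indication
    total: int
    rows: list[tuple[str, int, float]]

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["subclass", "count", "percentage"])
            for row in self.rows:
                writer.writerow(row)


def subclass_frequency(registry: Registry, scope: Indication) -> SubclassTable:
    """Frequency of medicine subclasses among candidates in one scope.

    A candidate with indication ``both`` contributes to both the prevention
    and the management scope; percentages are taken over the scope total.
    """
    if scope not in (Indication.prevention, Indication.management):
        raise UsageError("scope must be prevention or management")
    in_scope = [
        c
        for c in registry
        if c.indication is scope or c.indication is Indication.both
    ]
    if not in_scope:
        return SubclassTable(scope=scope, total=0, rows=[])
    counts: dict[str, int] = {}
    for cand in in_scope:
        counts[cand.subclass] = counts.get(cand.subclass, 0) + 1
    total = len(in_scope)
    rows = [
        (subclass, n, percent(n, total))
        for subclass, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return SubclassTable(scope=scope, total=total, rows=rows)


def dual_indication(registry: Registry) -> set[str]:
    """Names of candidates evaluated for both prevention and management.

    Detects both explicit ``both`` indications and identical names recorded
    separately under each scope (as happens when per-scope tables are merged).
    """
    names = {c.name for c in registry if c.indication is Indication.both}
    prevention = {c.name for c in registry if c.indication is Indication.prevention}
    management = {c.name for c in registry if c.indication is Indication.management}
    return names | (prevention & management)
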