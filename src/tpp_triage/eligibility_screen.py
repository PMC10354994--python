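"""Six-criterion eligibility screen with flowchart attrition accounting.

Criteria are applied to clinical-phase candidates; a candidate is excluded
when any of its curated evidence flags is set.  When several criteria apply,
all are recorded and the lowest-numbered one is reported as primary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .candidate_registry import CLINICAL_PHASES, Candidate, Phase, Registry
from .errors import IntegrityError, UsageError

__all__ = [
    "CRITERIA",
    "CRITERION_IDS",
    "ScreenDecision",
    "FlowReport",
    "screen_candidate",
    "screen_registry",
]

#: Criterion id -> eligibility flag it reads.
CRITERIA: dict[str, str] = {
    "C1": "marketed_for_indication",
    "C2": "who_recommended_or_routine",
    "C3": "subgroup_recommended",
    "C4": "halted_negative_outcomes",
    "C5": "inferior_to_current",
    "C6": "other_labour_indication",
}

CRITERION_IDS: tuple[str, ...] = tuple(CRITERIA)


@dataclass(frozen=True)
class ScreenDecision:
    """Outcome of screening one candidate."""

    candidate_id: str
    excluded: bool
    criteria_met: tuple[str, ...]
    primary_criterion: str | None

    def __post_init__(self) -> None:
        if self.excluded != bool(self.criteria_met):
            raise IntegrityError("excluded must equal criteria_met non-empty")
        expected = self.criteria_met[0] if self.criteria_met else None
        if self.primary_criterion != expected:
            raise IntegrityError(
                "primary_criterion must be the lowest-numbered criterion met"
            )


@dataclass
class FlowReport:
    """Stage-attrition bookkeeping for one screening run."""

    n_total: int
    n_clinical: int
    n_excluded: int
    n_remaining: int
    per_criterion_counts: dict[str, int] = field(
        default_factory=lambda: {cid: 0 for cid in CRITERION_IDS}
    )

    def __post_init__(self) -> None:
        if self.n_remaining != self.n_clinical - self.n_excluded:
            raise IntegrityError("n_remaining must equal n_clinical - n_excluded")
        if sum(self.per_criterion_counts.values()) != self.n_excluded:
            raise IntegrityError("per-criterion counts must sum to n_excluded")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_clinical": self.n_clinical,
            "n_excluded": self.n_excluded,
            "n_remaining": self.n_remaining,
            "per_criterion_counts": dict(self.per_criterion_counts),
        }


def screen_candidate(candidate: Candidate) -> ScreenDecision:
    """Evaluate all six criteria for one candidate."""
    met = tuple(
        cid for cid, flag in CRITERIA.items() if getattr(candidate.flags, flag)
    )
    return ScreenDecision(
        candidate_id=candidate.id,
        excluded=bool(met),
        criteria_met=met,
        primary_criterion=met[0] if met else None,
    )


def screen_registry(
    registry: Registry,
    phases: frozenset[Phase] | set[Phase] = CLINICAL_PHASES,
) -> tuple[list[ScreenDecision], FlowReport]:
    """Screen every candidate in the selected phases.

    Returns per-candidate decisions plus a :class:`FlowReport` whose
    per-criterion counts attribute each excluded candidate to its primary
    criterion.  An empty selection yields an all-zero report.
    """
    if not phases:
        raise UsageError("phases must be non-empty")
    selected = [c for c in registry if c.phase in phases]
    decisions = [screen_candidate(c) for c in selected]
    per_criterion = {cid: 0 for cid in CRITERION_IDS}
    for decision in decisions:
        if decision.excluded:
            per_criterion[decision.primary_criterion] += 1
    n_excluded = sum(per_criterion.values())
    report = FlowReport(
        n_total=len(registry),
        n_clinical=len(selected),
        n_excluded=n_excluded,
        n_remaining=len(selected) - n_excluded,
        per_criterion_counts=per_criterion,
    )
    return decisions, report
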