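"""Weighted scoring of adjudicated rating sheets and phase-specific tiers.

Each rating level maps to an integer code, each parameter to a positive
weight (efficacy and safety carry greater weight than the rest), and the
weighted sum is compared, as a fraction of the maximum achievable score,
against per-phase thresholds to yield a high / medium / low potential tier.
The whole scheme is configurable; :func:`default_scheme` documents the
package defaults.  Boundary fractions belong to the upper tier.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .candidate_registry import Phase, RANKABLE_PHASES, Registry
from .eligibility_screen import screen_candidate
from .errors import ConfigError, UsageError
from .tpp_matching import (
    AdjudicationResult,
    Level,
    PARAMETERS,
    Parameter,
    RatingSheet,
    WEIGHTED_PARAMETERS,
    validate_sheet,
)

__all__ = [
    "Tier",
    "UnknownPolicy",
    "TierThresholds",
    "ScoringScheme",
    "RankResult",
    "RankBatch",
    "default_scheme",
    "score_sheet",
    "rank",
    "rank_registry",
    "scheme_to_yaml",
    "scheme_from_yaml",
    "write_ranks",
    "load_ranks",
]


class Tier(str, Enum):
    high = "high"
    medium = "medium"
    low = "low"


#: Total order on tiers (higher is better).
TIER_ORDER: dict[Tier, int] = {Tier.low: 0, Tier.medium: 1, Tier.high: 2}


class UnknownPolicy(str, Enum):
    score_zero = "score_zero"
    exclude_and_renormalize = "exclude_and_renormalize"


@dataclass(frozen=True)
class TierThresholds:
    """Tier cut points as fractions of the maximum achievable score."""

    high_cut: float
    medium_cut: float

    def __post_init__(self) -> None:
        if not 0.0 < self.medium_cut < self.high_cut <= 1.0:
            raise ConfigError(
                f"thresholds must satisfy 0 < medium_cut < high_cut <= 1, "
                f"got medium={self.medium_cut}, high={self.high_cut}"
            )


@dataclass
class ScoringScheme:
    """Level codes, parameter weights and per-phase tier thresholds."""

    level_codes: dict[Level, int]
    weights: dict[Parameter, float]
    thresholds: dict[Phase, TierThresholds]
    unknown_policy: UnknownPolicy = UnknownPolicy.score_zero

    def __post_init__(self) -> None:
        missing_levels = [lv.value for lv in Level if lv not in self.level_codes]
        if missing_levels:
            raise ConfigError(f"level_codes missing: {missing_levels}")
        codes = self.level_codes
        if any(codes[lv] < 0 for lv in Level):
            raise ConfigError("level codes must be non-negative")
        ladder = (Level.met_preferred, Level.met_minimum, Level.partial_minimum, Level.not_met)
        for better, worse in zip(ladder, ladder[1:]):
            if codes[better] < codes[worse]:
                raise ConfigError(
                    f"level codes must be non-increasing along the ordinal "
                    f"ladder ({better.value} < {worse.value})"
                )
        if codes[Level.unknown] > codes[Level.partial_minimum]:
            raise ConfigError("unknown may not score above partial_minimum")
        missing_params = [p.value for p in PARAMETERS if p not in self.weights]
        if missing_params:
            raise ConfigError(f"weights missing: {missing_params}")
        if any(self.weights[p] <= 0 for p in PARAMETERS):
            raise ConfigError("weights must be positive")
        unit_params = [p for p in PARAMETERS if p not in WEIGHTED_PARAMETERS]
        for heavy in WEIGHTED_PARAMETERS:
            if any(self.weights[heavy] <= self.weights[p] for p in unit_params):
                raise ConfigError(
                    f"weight of {heavy.value} must exceed every other "
                    f"parameter's weight"
                )
        for phase in (Phase.phase1, Phase.phase2, Phase.phase3):
            if phase not in self.thresholds:
                raise ConfigError(f"thresholds missing for {phase.value}")

    def max_achievable(self, parameters: Iterable[Parameter] = PARAMETERS) -> float:
        best = self.level_codes[Level.met_preferred]
        return sum(self.weights[p] * best for p in parameters)


def default_scheme() -> ScoringScheme:
    """The documented default scheme.

    Codes 3/2/1/0 down the ordinal ladder with unknown scoring 0; efficacy
    and safety weighted 2x; tier cuts at 70% (high) and 40% (medium) of the
    maximum achievable score for every rankable phase.  With these defaults
    the maximum achievable weighted score is ``3 * (2 + 2 + 7) = 33``.
    """
    return ScoringScheme(
        level_codes={
            Level.met_preferred: 3,
            Level.met_minimum: 2,
            Level.partial_minimum: 1,
            Level.not_met: 0,
            Level.unknown: 0,
        },
        weights={
            p: 2.0 if p in WEIGHTED_PARAMETERS else 1.0 for p in PARAMETERS
        },
        thresholds={
            phase: TierThresholds(high_cut=0.70, medium_cut=0.40)
            for phase in (Phase.phase1, Phase.phase2, Phase.phase3)
        },
        unknown_policy=UnknownPolicy.score_zero,
    )


def score_sheet(
    sheet: RatingSheet | AdjudicationResult,
    scheme: ScoringScheme,
) -> tuple[float, float, dict[Parameter, tuple[Level, int, float]]]:
    """Weighted score, maximum achievable score and per-parameter breakdown.

    Accepts either a consensus :class:`RatingSheet` or an
    :class:`AdjudicationResult`; the latter must be fully resolved.
    """
    if isinstance(sheet, AdjudicationResult):
        if not sheet.is_resolved:
            raise UsageError(
                f"adjudication for candidate {sheet.merged.candidate_id!r} has "
                f"unresolved disagreements: "
                f"{sorted(p.value for p in sheet.unresolved)}"
            )
        sheet = sheet.merged
    validate_sheet(sheet)
    if scheme.unknown_policy is UnknownPolicy.exclude_and_renormalize:
        scored = [p for p in PARAMETERS if sheet.level(p) is not Level.unknown]
        if not scored:
            raise UsageError(
                f"candidate {sheet.candidate_id!r}: all parameters unknown; "
                f"score undefined under exclude_and_renormalize"
            )
    else:
        scored = list(PARAMETERS)
    breakdown: dict[Parameter, tuple[Level, int, float]] = {}
    total = 0.0
    for parameter in scored:
        level = sheet.level(parameter)
        code = scheme.level_codes[level]
        contribution = scheme.weights[parameter] * code
        breakdown[parameter] = (level, code, contribution)
        total += contribution
    return total, scheme.max_achievable(scored), breakdown


def rank(score_fraction: float, phase: Phase, scheme: ScoringScheme) -> Tier:
    """Tier for a score fraction at a given phase (ties go to the upper tier)."""
    if phase not in RANKABLE_PHASES:
        raise UsageError(
            f"phase {phase.value!r} is not rankable; only Phase I-III "
            f"candidates are tiered"
        )
    if not 0.0 <= score_fraction <= 1.0:
        raise UsageError(f"score_fraction must lie in [0, 1], got {score_fraction}")
    cuts = scheme.thresholds[phase]
    if score_fraction >= cuts.high_cut:
        return Tier.high
    if score_fraction >= cuts.medium_cut:
        return Tier.medium
    return Tier.low


@dataclass(frozen=True)
class RankResult:
    candidate_id: str
    phase: Phase
    weighted_score: float
    max_achievable: float
    score_fraction: float
    tier: Tier
    breakdown: Mapping[Parameter, tuple[Level, int, float]] = field(
        default_factory=dict
    )


@dataclass
class RankBatch:
    """Rank results plus tier tally and per-candidate warnings."""

    results: list[RankResult]
    tally: dict[Tier, int]
    missing_sheets: list[str] = field(default_factory=list)


def rank_registry(
    registry: Registry,
    sheets: Mapping[str, RatingSheet] | Iterable[RatingSheet],
    scheme: ScoringScheme | None = None,
    apply_screen: bool = True,
) -> RankBatch:
    """Score and tier every rankable candidate with an adjudicated sheet.

    Candidates in Phase I-III (surviving the eligibility screen when
    ``apply_screen`` is set) are scored against ``scheme``; candidates
    lacking a sheet are reported in ``missing_sheets`` and excluded from
    the tally.
    """
    scheme = scheme or default_scheme()
    if not isinstance(sheets, Mapping):
        sheet_map: dict[str, RatingSheet] = {}
        for sheet in sheets:
            if sheet.candidate_id in sheet_map:
                raise UsageError(
                    f"multiple sheets supplied for candidate "
                    f"{sheet.candidate_id!r}; adjudicate to a consensus sheet first"
                )
            sheet_map[sheet.candidate_id] = sheet
    else:
        sheet_map = dict(sheets)
    results: list[RankResult] = []
    missing: list[str] = []
    tally = {tier: 0 for tier in Tier}
    for candidate in registry:
        if candidate.phase not in RANKABLE_PHASES:
            continue
        if apply_screen and screen_candidate(candidate).excluded:
            continue
        sheet = sheet_map.get(candidate.id)
        if sheet is None:
            missing.append(candidate.id)
            continue
        score, maximum, breakdown = score_sheet(sheet, scheme)
        fraction = score / maximum
        tier = rank(fraction, candidate.phase, scheme)
        results.append(
            RankResult(
                candidate_id=candidate.id,
                phase=candidate.phase,
                weighted_score=score,
                max_achievable=maximum,
                score_fraction=fraction,
                tier=tier,
                breakdown=breakdown,
            )
        )
        tally[tier] += 1
    return RankBatch(results=results, tally=tally, missing_sheets=missing)


# ---------------------------------------------------------------------------
# scheme config round-trip (YAML)


def scheme_to_yaml(scheme: ScoringScheme, path: str | Path) -> None:
    payload = {
        "level_codes": {lv.value: code for lv, code in scheme.level_codes.items()},
        "weights": {p.value: w for p, w in scheme.weights.items()},
        "thresholds": {
            phase.value: {"high_cut": t.high_cut, "medium_cut": t.medium_cut}
            for phase, t in scheme.thresholds.items()
        },
        "unknown_policy": scheme.unknown_policy.value,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def scheme_from_yaml(path: str | Path) -> ScoringScheme:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        return ScoringScheme(
            level_codes={Level(k): int(v) for k, v in payload["level_codes"].items()},
            weights={Parameter(k): float(v) for k, v in payload["weights"].items()},
            thresholds={
                Phase(k): TierThresholds(
                    high_cut=float(v["high_cut"]), medium_cut=float(v["medium_cut"])
                )
                for k, v in payload["thresholds"].items()
            },
            unknown_policy=UnknownPolicy(payload.get("unknown_policy", "score_zero")),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"invalid scheme config {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# rank table I/O

_RANK_COLUMNS = (
    "candidate_id",
    "phase",
    "weighted_score",
    "max_achievable",
    "score_fraction",
    "tier",
)


def write_ranks(results: Iterable[RankResult], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_RANK_COLUMNS)
        for res in results:
            writer.writerow(
                [
                    res.candidate_id,
                    res.phase.value,
                    res.weighted_score,
                    res.max_achievable,
                    res.score_fraction,
                    res.tier.value,
                ]
            )


def load_ranks(path: str | Path) -> list[RankResult]:
    results = []
    with Path(path).open(newline="", encoding="utf-8") as handle:
        for record in csv.DictReader(handle):
            results.append(
                RankResult(
                    candidate_id=record["candidate_id"],
                    phase=Phase(record["phase"]),
                    weighted_score=float(record["weighted_score"]),
                    max_achievable=float(record["max_achievable"]),
                    score_fraction=float(record["score_fraction"]),
                    tier=Tier(record["tier"]),
                )
            )
    return results
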