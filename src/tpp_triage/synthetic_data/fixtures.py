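"""Bundled reference fixtures for end-to-end testing without downloads.

Three fixtures are provided:

``flow``
    A 178-candidate registry whose marginal counts (activity status, phase,
    product type, archetype, clinical-screen attrition) equal the published
    pipeline-landscape totals.  Marginals are realised by deterministic
    assignment, so the equalities are exact; joint attributes beyond the
    published marginals are arbitrary but reproducible.

``preclinical_tables``
    The 92 screened-in preclinical candidates, with names, subclasses,
    archetypes and routes transcribed from the published per-scope summary
    tables (36 prevention-scope rows, 58 management-scope rows, two
    candidates in both scopes).  Product type and activity status are not
    printed per row and are assigned deterministically to match the
    published marginals (70 drugs / 13 dietary supplements / 9 biologics;
    28 active).

``clinical_ranks``
    The 44 screened-in clinical candidates with their final potential tiers
    (10 high / 7 medium / 27 low).  The 17 high- and medium-tier candidates
    are named as published; low-tier candidates are placeholders because
    their identities are not listed in the source summary.

Every fixture re-checks its published marginals at construction time and
raises :class:`IntegrityError` on transcription drift.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Union

from ..candidate_registry import (
    Archetype,
    Candidate,
    CLINICAL_PHASES,
    EligibilityFlags,
    Indication,
    Phase,
    ProductType,
    Registry,
    is_active,
)
from ..errors import IntegrityError, UsageError
from ..scoring_rank import Tier

__all__ = [
    "FIXTURE_NAMES",
    "ClinicalRankRow",
    "ClinicalRankFixture",
    "flow_registry",
    "preclinical_registry",
    "clinical_rank_fixture",
    "load_fixture",
]

FIXTURE_NAMES = ("flow", "preclinical_tables", "clinical_ranks")

_ACTIVE_YEAR = 2019
_INACTIVE_YEAR = 2016
_ACTIVITY_CUTOFF = 2018


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise IntegrityError(f"fixture drift: {message}")


# ---------------------------------------------------------------------------
# flow fixture

# (phase, count) in registry order; 107 preclinical + 71 clinical = 178.
_FLOW_PHASES = (
    (Phase.preclinical, 107),
    (Phase.phase1, 11),
    (Phase.phase2, 30),
    (Phase.phase3, 23),
    (Phase.phase4, 7),
)
_FLOW_TYPES = (
    (ProductType.drug, 132),
    (ProductType.biologic, 14),
    (ProductType.dietary_supplement, 32),
)
_FLOW_ARCHETYPES = ((Archetype.new_entity, 82), (Archetype.repurposed, 96))
_FLOW_ACTIVE = 68
# Primary-criterion attrition among the 71 clinical candidates (27 excluded).
# Only the total of 27 is published; the C1 (7 marketed) and C2 (11 routinely
# used off-label) counts follow the published prose, the remainder is an
# arbitrary deterministic split.
_FLOW_EXCLUSIONS = (
    ("marketed_for_indication", 7),
    ("who_recommended_or_routine", 11),
    ("subgroup_recommended", 3),
    ("halted_negative_outcomes", 3),
    ("inferior_to_current", 2),
    ("other_labour_indication", 1),
)


def _fill(assignments: tuple, total: int) -> list:
    values = []
    for value, count in assignments:
        values.extend([value] * count)
    if len(values) != total:
        raise IntegrityError(
            f"fixture drift: category counts sum to {len(values)}, not {total}"
        )
    return values


def flow_registry() -> Registry:
    """178-candidate registry matching the published pipeline marginals."""
    total = 178
    phases = _fill(_FLOW_PHASES, total)
    types = _fill(_FLOW_TYPES, total)
    archetypes = _fill(_FLOW_ARCHETYPES, total)
    clinical_flags: list[EligibilityFlags] = []
    for flag_name, count in _FLOW_EXCLUSIONS:
        clinical_flags.extend([EligibilityFlags(**{flag_name: True})] * count)
    clinical_flags.extend([EligibilityFlags()] * (71 - len(clinical_flags)))
    candidates = []
    clinical_index = 0
    for i in range(total):
        phase = phases[i]
        if phase in CLINICAL_PHASES:
            flags = clinical_flags[clinical_index]
            clinical_index += 1
        else:
            flags = EligibilityFlags()
        candidates.append(
            Candidate(
                id=f"FLOW{i:03d}",
                name=f"pipeline candidate {i + 1:03d}",
                indication=(
                    Indication.prevention if i % 2 == 0 else Indication.management
                ),
                phase=phase,
                product_type=types[i],
                archetype=archetypes[i],
                last_update_year=_ACTIVE_YEAR if i < _FLOW_ACTIVE else _INACTIVE_YEAR,
                subclass="Unspecified",
                flags=flags,
            )
        )
    registry = Registry(candidates)
    _check(len(registry) == 178, "flow total must be 178")
    _check(
        sum(is_active(c, _ACTIVITY_CUTOFF) for c in registry) == 68,
        "flow active count must be 68",
    )
    for phase, count in _FLOW_PHASES:
        _check(
            sum(c.phase is phase for c in registry) == count,
            f"flow {phase.value} count must be {count}",
        )
    for ptype, count in _FLOW_TYPES:
        _check(
            sum(c.product_type is ptype for c in registry) == count,
            f"flow {ptype.value} count must be {count}",
        )
    for archetype, count in _FLOW_ARCHETYPES:
        _check(
            sum(c.archetype is archetype for c in registry) == count,
            f"flow {archetype.value} count must be {count}",
        )
    clinical = [c for c in registry if c.phase in CLINICAL_PHASES]
    _check(len(clinical) == 71, "flow clinical count must be 71")
    _check(
        sum(c.flags.any() for c in clinical) == 27,
        "flow excluded-clinical count must be 27",
    )
    return registry


# ---------------------------------------------------------------------------
# preclinical tables fixture

_BIOLOGIC_NAMES = frozenset(
    {
        "Anti-Toll-like receptor 4 (TLR4) monoclonal antibody",
        "Etanercept",
        "Super-repressor (SR) IkB-alpha (exosome delivery)",
        "Synthetic TLR4",
        "Tocilizumab",
        "Exosome-based protein therapeutics",
        "Surfactant protein A",
        "Leptin",
        "Botulinum toxin A",
    }
)
_SUPPLEMENT_NAMES = frozenset(
    {
        "Melatonin",
        "Cucurbita moschata extract",
        "Gallic acid",
        "Honokial",
        "Nobiletin",
        "Resveratrol",
        "Ananas comosus, ethyl acetate fraction",
        "Pimpinella anisum extract",
        "Tannic acid",
        "Carvacrol",
        "Alpha-bisabolol",
        "Citral",
        "Paeoniflorin",
    }
)
_PRECLINICAL_ACTIVE = 28


def _read_data_csv(filename: str) -> list[dict[str, str]]:
    source = resources.files("tpp_triage.synthetic_data").joinpath(f"data/{filename}")
    with source.open(newline="", encoding="utf-8") as handle:
        return list(csv.DictReader(handle))


def preclinical_registry() -> Registry:
    """The 92 screened-in preclinical candidates from the per-scope tables.

    Candidates appearing in both scopes are merged into one record with
    indication ``both``; their archetype is taken from the management-scope
    row.  Note the merged registry holds 55 new / 37 repurposed candidates:
    the source tables disagree with the published archetype marginal
    (56 / 36) by one candidate, because resveratrol is listed as repurposed
    in one scope and new in the other.
    """
    rows = _read_data_csv("preclinical_tables.csv")
    _check(
        sum(r["scope"] == "prevention" for r in rows) == 36,
        "prevention scope must have 36 table rows",
    )
    _check(
        sum(r["scope"] == "management" for r in rows) == 58,
        "management scope must have 58 table rows",
    )
    merged: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for row in rows:
        name = row["name"]
        if name not in merged:
            merged[name] = dict(row)
            order.append(name)
        else:
            # second scope: merge to a dual-indication record, keeping the
            # management-scope archetype
            merged[name]["scope"] = Indication.both.value
            merged[name]["archetype"] = row["archetype"]
    candidates = []
    for i, name in enumerate(order):
        row = merged[name]
        if name in _BIOLOGIC_NAMES:
            ptype = ProductType.biologic
        elif name in _SUPPLEMENT_NAMES:
            ptype = ProductType.dietary_supplement
        else:
            ptype = ProductType.drug
        candidates.append(
            Candidate(
                id=f"PRE{i:03d}",
                name=name,
                indication=Indication(row["scope"]),
                phase=Phase.preclinical,
                product_type=ptype,
                archetype=Archetype(row["archetype"]),
                last_update_year=(
                    _ACTIVE_YEAR if i < _PRECLINICAL_ACTIVE else _INACTIVE_YEAR
                ),
                subclass=row["subclass"],
                route=row["route"],
            )
        )
    registry = Registry(candidates)
    _check(len(registry) == 92, "preclinical registry must hold 92 candidates")
    _check(
        sum(c.indication is Indication.both for c in registry) == 2,
        "exactly two dual-indication candidates expected",
    )
    _check(
        sum(c.archetype is Archetype.new_entity for c in registry) == 55,
        "55 new entities expected from the transcribed rows",
    )
    _check(
        sum(c.archetype is Archetype.repurposed for c in registry) == 37,
        "37 repurposed candidates expected from the transcribed rows",
    )
    _check(
        sum(c.product_type is ProductType.drug for c in registry) == 70,
        "70 drugs expected",
    )
    _check(
        sum(c.product_type is ProductType.dietary_supplement for c in registry) == 13,
        "13 dietary supplements expected",
    )
    _check(
        sum(c.product_type is ProductType.biologic for c in registry) == 9,
        "9 biologics expected",
    )
    _check(
        sum(is_active(c, _ACTIVITY_CUTOFF) for c in registry) == 28,
        "28 active preclinical candidates expected",
    )
    return registry


# ---------------------------------------------------------------------------
# clinical ranks fixture


@dataclass(frozen=True)
class ClinicalRankRow:
    name: str
    indication: Indication
    phase: Phase
    tier: Tier


@dataclass
class ClinicalRankFixture:
    """Final tier assignments for the 44 screened-in clinical candidates."""

    rows: list[ClinicalRankRow]

    def tally(self) -> dict[Tier, int]:
        counts = {tier: 0 for tier in Tier}
        for row in self.rows:
            counts[row.tier] += 1
        return counts


def clinical_rank_fixture() -> ClinicalRankFixture:
    rows = [
        ClinicalRankRow(
            name=r["name"],
            indication=Indication(r["indication"]),
            phase=Phase(r["phase"]),
            tier=Tier(r["tier"]),
        )
        for r in _read_data_csv("clinical_ranks.csv")
    ]
    fixture = ClinicalRankFixture(rows)
    _check(len(rows) == 44, "clinical ranks fixture must hold 44 candidates")
    tally = fixture.tally()
    _check(tally[Tier.high] == 10, "10 high-potential candidates expected")
    _check(tally[Tier.medium] == 7, "7 medium-potential candidates expected")
    _check(tally[Tier.low] == 27, "27 low-potential candidates expected")
    return fixture


def load_fixture(name: str) -> Union[Registry, ClinicalRankFixture]:
    """Dispatch on fixture name (see module docstring for the catalogue)."""
    if name == "flow":
        return flow_registry()
    if name == "preclinical_tables":
        return preclinical_registry()
    if name == "clinical_ranks":
        return clinical_rank_fixture()
    raise UsageError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
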