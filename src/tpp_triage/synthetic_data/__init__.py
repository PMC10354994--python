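"""Seeded generators for registries and dual-rater rating sheets, plus the
bundled reference fixtures (see :mod:`tpp_triage.synthetic_data.fixtures`)."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..candidate_registry import (
    Archetype,
    Candidate,
    CLINICAL_PHASES,
    DEFAULT_SNAPSHOT_YEAR,
    EligibilityFlags,
    FLAG_FIELDS,
    Indication,
    Phase,
    ProductType,
    RANKABLE_PHASES,
    Registry,
)
from ..errors import ConfigError
from ..tpp_matching import (
    Level,
    PARAMETERS,
    Parameter,
    RatingSheet,
    admissible_levels,
)
from .fixtures import (
    FIXTURE_NAMES,
    ClinicalRankFixture,
    ClinicalRankRow,
    clinical_rank_fixture,
    flow_registry,
    load_fixture,
    preclinical_registry,
)

__all__ = [
    "GeneratorConfig",
    "generate_registry",
    "generate_sheets",
    "FIXTURE_NAMES",
    "ClinicalRankFixture",
    "ClinicalRankRow",
    "clinical_rank_fixture",
    "flow_registry",
    "load_fixture",
    "preclinical_registry",
]

_TOL = 1e-9


def _default_phase_dist() -> dict[Phase, float]:
    return {
        Phase.preclinical: 0.60,
        Phase.phase1: 0.06,
        Phase.phase2: 0.17,
        Phase.phase3: 0.13,
        Phase.phase4: 0.04,
        Phase.marketed: 0.00,
    }


def _default_type_dist() -> dict[ProductType, float]:
    return {
        ProductType.drug: 0.74,
        ProductType.biologic: 0.08,
        ProductType.dietary_supplement: 0.18,
    }


def _default_archetype_dist() -> dict[Archetype, float]:
    return {Archetype.new_entity: 0.46, Archetype.repurposed: 0.54}


def _default_indication_dist() -> dict[Indication, float]:
    return {
        Indication.prevention: 0.40,
        Indication.management: 0.55,
        Indication.both: 0.05,
    }


def _default_flag_probs() -> dict[str, float]:
    return {name: 0.08 for name in FLAG_FIELDS}


@dataclass
class GeneratorConfig:
    """Marginal distributions and probabilities for the synthetic generators.

    ``level_dist`` optionally overrides the per-parameter rating-level
    distribution; parameters without an entry draw uniformly from their
    admissible levels.  ``agreement`` is the per-parameter probability that
    the second rater copies the first.
    """

    n_candidates: int = 100
    phase_dist: dict[Phase, float] = field(default_factory=_default_phase_dist)
    product_type_dist: dict[ProductType, float] = field(
        default_factory=_default_type_dist
    )
    archetype_dist: dict[Archetype, float] = field(
        default_factory=_default_archetype_dist
    )
    indication_dist: dict[Indication, float] = field(
        default_factory=_default_indication_dist
    )
    active_prob: float = 0.4
    flag_probs: dict[str, float] = field(default_factory=_default_flag_probs)
    level_dist: Mapping[Parameter, Mapping[Level, float]] = field(
        default_factory=dict
    )
    agreement: float = 0.8
    snapshot_year: int = DEFAULT_SNAPSHOT_YEAR
    activity_cutoff: int = 2018
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates < 0:
            raise ConfigError("n_candidates must be non-negative")
        for label, dist in (
            ("phase_dist", self.phase_dist),
            ("product_type_dist", self.product_type_dist),
            ("archetype_dist", self.archetype_dist),
            ("indication_dist", self.indication_dist),
        ):
            if any(p < 0 for p in dist.values()):
                raise ConfigError(f"{label}: probabilities must be non-negative")
            if abs(sum(dist.values()) - 1.0) > _TOL:
                raise ConfigError(f"{label}: probabilities must sum to 1")
        for label, prob in (
            ("active_prob", self.active_prob),
            ("agreement", self.agreement),
            *((f"flag_probs[{k}]", v) for k, v in self.flag_probs.items()),
        ):
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"{label} must lie in [0, 1], got {prob}")
        for parameter, dist in self.level_dist.items():
            admissible = admissible_levels(parameter)
            if any(level not in admissible for level in dist):
                raise ConfigError(
                    f"level_dist[{parameter.value}] contains inadmissible levels"
                )
            if abs(sum(dist.values()) - 1.0) > _TOL:
                raise ConfigError(
                    f"level_dist[{parameter.value}] must sum to 1"
                )


def _sample_categories(rng: np.random.Generator, dist: dict, size: int) -> list:
    values = list(dist.keys())
    probs = np.asarray([dist[v] for v in values], dtype=float)
    probs = probs / probs.sum()  # guard against 1e-9 drift
    idx = rng.choice(len(values), size=size, p=probs)
    return [values[i] for i in idx]


def generate_registry(config: GeneratorConfig) -> Registry:
    """Sample a registry of independent candidates from the marginals.

    Identical configs (including seed) produce identical registries.
    Eligibility flags are drawn only for clinical-phase candidates.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_candidates
    phases = _sample_categories(rng, config.phase_dist, n)
    types = _sample_categories(rng, config.product_type_dist, n)
    archetypes = _sample_categories(rng, config.archetype_dist, n)
    indications = _sample_categories(rng, config.indication_dist, n)
    active = rng.random(n) < config.active_prob
    candidates = []
    for i in range(n):
        if active[i]:
            year = int(
                rng.integers(config.activity_cutoff, config.snapshot_year + 1)
            )
        else:
            year = int(rng.integers(2000, config.activity_cutoff))
        if phases[i] in CLINICAL_PHASES:
            flags = EligibilityFlags(
                **{
                    name: bool(rng.random() < config.flag_probs.get(name, 0.0))
                    for name in FLAG_FIELDS
                }
            )
        else:
            flags = EligibilityFlags()
        candidates.append(
            Candidate(
                id=f"SYN{i:05d}",
                name=f"synthetic candidate {i:05d}",
                indication=indications[i],
                phase=phases[i],
                product_type=types[i],
                archetype=archetypes[i],
                last_update_year=year,
                subclass="Unspecified",
                flags=flags,
            )
        )
    return Registry(candidates, snapshot_year=config.snapshot_year)


def _sample_level(
    rng: np.random.Generator, config: GeneratorConfig, parameter: Parameter
) -> Level:
    dist = config.level_dist.get(parameter)
    if dist is None:
        levels = sorted(admissible_levels(parameter), key=lambda lv: lv.value)
        return levels[int(rng.integers(len(levels)))]
    levels = list(dist.keys())
    probs = np.asarray([dist[lv] for lv in levels], dtype=float)
    return levels[int(rng.choice(len(levels), p=probs / probs.sum()))]


def generate_sheets(
    registry: Registry,
    config: GeneratorConfig,
    phases: frozenset[Phase] = frozenset(RANKABLE_PHASES),
) -> list[tuple[RatingSheet, RatingSheet]]:
    """Paired independent rating sheets for each candidate in ``phases``.

    The second rater copies the first on each parameter with probability
    ``config.agreement``, otherwise draws uniformly from the other
    admissible levels.  Seeded independently of :func:`generate_registry`
    so the two can be composed freely.
    """
    rng = np.random.default_rng([config.seed, 7919])
    pairs: list[tuple[RatingSheet, RatingSheet]] = []
    for candidate in registry:
        if candidate.phase not in phases:
            continue
        levels_a: dict[Parameter, Level] = {}
        levels_b: dict[Parameter, Level] = {}
        for parameter in PARAMETERS:
            level_a = _sample_level(rng, config, parameter)
            levels_a[parameter] = level_a
            if rng.random() < config.agreement:
                levels_b[parameter] = level_a
            else:
                others = sorted(
                    admissible_levels(parameter) - {level_a},
                    key=lambda lv: lv.value,
                )
                levels_b[parameter] = others[int(rng.integers(len(others)))]
        pairs.append(
            (
                RatingSheet(candidate.id, "rater_a", levels_a),
                RatingSheet(candidate.id, "rater_b", levels_b),
            )
        )
    return pairs
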