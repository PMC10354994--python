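import pytest

from tpp_triage.candidate_registry import (
    Archetype,
    Candidate,
    EligibilityFlags,
    Indication,
    Phase,
    ProductType,
    Registry,
)
from tpp_triage.scoring_rank import default_scheme
from tpp_triage.tpp_matching import Level, PARAMETERS, Parameter, RatingSheet


def make_candidate(idx: int = 0, **overrides) -> Candidate:
    defaults = dict(
        id=f"CAND{idx:03d}",
        name=f"candidate {idx}",
        indication=Indication.prevention,
        phase=Phase.phase2,
        product_type=ProductType.drug,
        archetype=Archetype.repurposed,
        last_update_year=2019,
        subclass="Tocolytic",
        route="Oral",
        flags=EligibilityFlags(),
    )
    defaults.update(overrides)
    return Candidate(**defaults)


def make_sheet(
    candidate_id: str = "CAND000",
    rater_id: str = "rater_a",
    default_level: Level = Level.met_preferred,
    **overrides: Level,
) -> RatingSheet:
    """Full nine-parameter sheet; overrides are keyed by parameter name.

    The default level must be admissible on every scale (met_preferred and
    unknown are).
    """
    levels = {p: default_level for p in PARAMETERS}
    for name, level in overrides.items():
        levels[Parameter(name)] = level
    return RatingSheet(candidate_id, rater_id, levels)


@pytest.fixture
def scheme():
    return default_scheme()


@pytest.fixture
def small_registry():
    return Registry([make_candidate(i) for i in range(5)])
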