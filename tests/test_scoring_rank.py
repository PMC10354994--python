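import pytest
from hypothesis import given, settings, strategies as st

from tpp_triage.candidate_registry import Phase, Registry
from tpp_triage.errors import ConfigError, UsageError
from tpp_triage.scoring_rank import (
    ScoringScheme,
    Tier,
    TierThresholds,
    UnknownPolicy,
    default_scheme,
    rank,
    rank_registry,
    scheme_from_yaml,
    scheme_to_yaml,
    score_sheet,
)
from tpp_triage.tpp_matching import (
    ADMISSIBLE,
    Level,
    PARAMETERS,
    Parameter,
    SCALE_OF,
    adjudicate,
)

from .conftest import make_candidate, make_sheet

#: Worst admissible level per parameter (setting cannot be not_met).
WORST = {
    p: (Level.unknown if p is Parameter.setting else Level.not_met)
    for p in PARAMETERS
}


def minimal_sheet(candidate_id="CAND000"):
    return make_sheet(candidate_id, **{p.value: lv for p, lv in WORST.items()})


class TestDefaultScheme:
    def test_max_achievable_is_33(self, scheme):
        # hand sum: 3 * (2 + 2 + 7 * 1)
        assert scheme.max_achievable() == 33

    def test_invariants_hold_by_construction(self, scheme):
        assert isinstance(scheme, ScoringScheme)

    def test_efficacy_outweighs_unit_parameters(self, scheme):
        assert scheme.weights[Parameter.efficacy] > scheme.weights[Parameter.adherence]
        assert scheme.weights[Parameter.safety] > scheme.weights[Parameter.setting]


class TestSchemeValidation:
    def test_non_monotone_codes_rejected(self, scheme):
        codes = dict(scheme.level_codes)
        codes[Level.met_minimum] = 5
        with pytest.raises(ConfigError):
            ScoringScheme(codes, scheme.weights, scheme.thresholds)

    def test_unknown_above_partial_rejected(self, scheme):
        codes = dict(scheme.level_codes)
        codes[Level.unknown] = 2
        with pytest.raises(ConfigError):
            ScoringScheme(codes, scheme.weights, scheme.thresholds)

    def test_flat_weights_rejected(self, scheme):
        weights = {p: 1.0 for p in PARAMETERS}
        with pytest.raises(ConfigError, match="weight"):
            ScoringScheme(scheme.level_codes, weights, scheme.thresholds)

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            TierThresholds(high_cut=0.4, medium_cut=0.7)


class TestScoreSheet:
    def test_all_preferred_scores_maximum(self, scheme):
        score, maximum, breakdown = score_sheet(make_sheet(), scheme)
        assert (score, maximum) == (33, 33)
        assert breakdown[Parameter.efficacy] == (Level.met_preferred, 3, 6.0)

    def test_minimal_sheet_scores_zero(self, scheme):
        # the setting scale does not admit not_met, so the minimum-score
        # sheet uses setting=unknown (code 0) and not_met elsewhere
        score, maximum, _ = score_sheet(minimal_sheet(), scheme)
        assert (score, maximum) == (0, 33)

    def test_single_step_down_on_efficacy(self, scheme):
        score, maximum, _ = score_sheet(
            make_sheet(efficacy=Level.met_minimum), scheme
        )
        assert (score, maximum) == (31, 33)

    # oracle: brute-force over every single-parameter perturbation
    def test_all_single_parameter_perturbations(self, scheme):
        base = 33
        for parameter in PARAMETERS:
            for level in ADMISSIBLE[SCALE_OF[parameter]]:
                score, _, _ = score_sheet(
                    make_sheet(**{parameter.value: level}), scheme
                )
                expected = base - scheme.weights[parameter] * (
                    3 - scheme.level_codes[level]
                )
                assert score == expected

    def test_unknown_scores_zero_by_default(self, scheme):
        score, maximum, _ = score_sheet(make_sheet(efficacy=Level.unknown), scheme)
        assert (score, maximum) == (27, 33)

    def test_exclude_and_renormalize_drops_unknowns(self, scheme):
        scheme.unknown_policy = UnknownPolicy.exclude_and_renormalize
        score, maximum, breakdown = score_sheet(
            make_sheet(efficacy=Level.unknown), scheme
        )
        assert (score, maximum) == (27, 27)
        assert Parameter.efficacy not in breakdown

    def test_all_unknown_under_renormalize_is_degenerate(self, scheme):
        scheme.unknown_policy = UnknownPolicy.exclude_and_renormalize
        with pytest.raises(UsageError, match="unknown"):
            score_sheet(make_sheet(default_level=Level.unknown), scheme)

    def test_unresolved_adjudication_rejected(self, scheme):
        a = make_sheet(rater_id="a", safety=Level.not_met)
        b = make_sheet(rater_id="b")
        result = adjudicate(a, b)
        assert not result.is_resolved
        with pytest.raises(UsageError, match="unresolved"):
            score_sheet(result, scheme)

    def test_resolved_adjudication_scored(self, scheme):
        a = make_sheet(rater_id="a", safety=Level.not_met)
        b = make_sheet(rater_id="b")
        result = adjudicate(a, b, {Parameter.safety: Level.met_minimum})
        score, _, _ = score_sheet(result, scheme)
        assert score == 31


class TestRank:
    # oracle: boundary table under default cuts 0.70 / 0.40
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.39, Tier.low), (0.40, Tier.medium), (0.69, Tier.medium), (0.70, Tier.high)],
    )
    @pytest.mark.parametrize("phase", [Phase.phase1, Phase.phase2, Phase.phase3])
    def test_boundary_table(self, scheme, fraction, expected, phase):
        assert rank(fraction, phase, scheme) is expected

    def test_maximal_fraction_is_high(self, scheme):
        assert rank(1.0, Phase.phase2, scheme) is Tier.high

    @pytest.mark.parametrize(
        "phase", [Phase.preclinical, Phase.phase4, Phase.marketed]
    )
    def test_unrankable_phases_rejected(self, scheme, phase):
        with pytest.raises(UsageError, match="not rankable"):
            rank(0.5, phase, scheme)

    def test_fraction_out_of_range_rejected(self, scheme):
        with pytest.raises(UsageError):
            rank(1.2, Phase.phase2, scheme)


class TestRankRegistry:
    def test_two_candidate_tally(self, scheme):
        registry = Registry([make_candidate(0), make_candidate(1)])
        sheets = {
            "CAND000": make_sheet("CAND000"),
            "CAND001": minimal_sheet("CAND001"),
        }
        batch = rank_registry(registry, sheets, scheme)
        assert batch.tally == {Tier.high: 1, Tier.medium: 0, Tier.low: 1}

    def test_empty_inputs(self, scheme):
        batch = rank_registry(Registry([]), {}, scheme)
        assert batch.results == []
        assert batch.tally == {tier: 0 for tier in Tier}

    def test_missing_sheet_warned_not_tallied(self, scheme):
        registry = Registry([make_candidate(0), make_candidate(1)])
        batch = rank_registry(registry, {"CAND000": make_sheet("CAND000")}, scheme)
        assert batch.missing_sheets == ["CAND001"]
        assert sum(batch.tally.values()) == 1

    def test_unrankable_and_screened_out_candidates_skipped(self, scheme):
        from tpp_triage.candidate_registry import EligibilityFlags

        registry = Registry(
            [
                make_candidate(0, phase=Phase.preclinical),
                make_candidate(1, phase=Phase.phase4),
                make_candidate(
                    2, flags=EligibilityFlags(marketed_for_indication=True)
                ),
                make_candidate(3),
            ]
        )
        batch = rank_registry(registry, {"CAND003": make_sheet("CAND003")}, scheme)
        assert [r.candidate_id for r in batch.results] == ["CAND003"]
        assert batch.missing_sheets == []

    def test_duplicate_sheets_rejected(self, scheme):
        registry = Registry([make_candidate(0)])
        with pytest.raises(UsageError, match="multiple sheets"):
            rank_registry(
                registry,
                [make_sheet("CAND000", "a"), make_sheet("CAND000", "b")],
                scheme,
            )


# ---------------------------------------------------------------------------
# properties

_LEVEL_ORDER = [Level.not_met, Level.unknown, Level.partial_minimum, Level.met_minimum, Level.met_preferred]


def _improvements(parameter, level):
    """Admissible levels with a code-wise >= position than ``level``."""
    admissible = ADMISSIBLE[SCALE_OF[parameter]]
    idx = _LEVEL_ORDER.index(level)
    return [lv for lv in _LEVEL_ORDER[idx:] if lv in admissible]


@st.composite
def random_sheets(draw):
    levels = {
        p: draw(st.sampled_from(sorted(ADMISSIBLE[SCALE_OF[p]], key=lambda lv: lv.value)))
        for p in PARAMETERS
    }
    return make_sheet(**{p.value: lv for p, lv in levels.items()})


@settings(max_examples=80, deadline=None)
@given(
    sheet=random_sheets(),
    parameter=st.sampled_from(list(PARAMETERS)),
    data=st.data(),
)
def test_monotonicity_property(sheet, parameter, data):
    scheme = default_scheme()
    improved_level = data.draw(
        st.sampled_from(_improvements(parameter, sheet.level(parameter)))
    )
    improved = make_sheet(
        **{
            **{p.value: lv for p, lv in sheet.levels.items()},
            parameter.value: improved_level,
        }
    )
    base_score, maximum, _ = score_sheet(sheet, scheme)
    new_score, _, _ = score_sheet(improved, scheme)
    assert new_score >= base_score
    base_tier = rank(base_score / maximum, Phase.phase2, scheme)
    new_tier = rank(new_score / maximum, Phase.phase2, scheme)
    order = {Tier.low: 0, Tier.medium: 1, Tier.high: 2}
    assert order[new_tier] >= order[base_tier]


def test_weight_dominance(scheme):
    # dropping efficacy from preferred to not_met costs strictly more than
    # the same drop on any unit-weight parameter
    full, _, _ = score_sheet(make_sheet(), scheme)
    efficacy_drop = full - score_sheet(make_sheet(efficacy=Level.not_met), scheme)[0]
    for parameter in PARAMETERS:
        if parameter in (Parameter.efficacy, Parameter.safety):
            continue
        if Level.not_met not in ADMISSIBLE[SCALE_OF[parameter]]:
            continue
        other_drop = (
            full - score_sheet(make_sheet(**{parameter.value: Level.not_met}), scheme)[0]
        )
        assert efficacy_drop > other_drop


def test_tier_step_function(scheme):
    # exactly two breakpoints, tiers monotone in the fraction
    fractions = [i / 100 for i in range(101)]
    tiers = [rank(f, Phase.phase1, scheme) for f in fractions]
    order = {Tier.low: 0, Tier.medium: 1, Tier.high: 2}
    ranks_numeric = [order[t] for t in tiers]
    assert ranks_numeric == sorted(ranks_numeric)
    breakpoints = sum(
        1 for a, b in zip(ranks_numeric, ranks_numeric[1:]) if a != b
    )
    assert breakpoints == 2


@settings(max_examples=30, deadline=None)
@given(sheet=random_sheets())
def test_scheme_yaml_round_trip_property(tmp_path_factory, sheet):
    scheme = default_scheme()
    path = tmp_path_factory.mktemp("scheme") / "scheme.yaml"
    scheme_to_yaml(scheme, path)
    reloaded = scheme_from_yaml(path)
    assert score_sheet(sheet, reloaded) == score_sheet(sheet, scheme)
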