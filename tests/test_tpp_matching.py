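import itertools
import json

import pytest
from hypothesis import given, settings, strategies as st

from tpp_triage.errors import SchemaError, UsageError
from tpp_triage.tpp_matching import (
    ADMISSIBLE,
    CONSENSUS_RATER,
    Level,
    PARAMETERS,
    Parameter,
    RatingSheet,
    SCALE_OF,
    adjudicate,
    admissible_levels,
    agreement_rate,
    load_sheets,
    parse_level,
    validate_sheet,
    write_sheets,
)

from .conftest import make_sheet


class TestScales:
    def test_nine_parameters(self):
        assert len(PARAMETERS) == 9

    def test_scale_assignment(self):
        assert SCALE_OF[Parameter.setting].value == "setting3"
        assert SCALE_OF[Parameter.stability].value == "binary_unknown"
        assert SCALE_OF[Parameter.eml_listing].value == "binary_unknown"
        ordinal = [p for p in PARAMETERS if SCALE_OF[p].value == "ordinal5"]
        assert len(ordinal) == 6

    def test_aliases_map_to_canonical_levels(self):
        assert parse_level("both_settings", Parameter.setting) is Level.met_preferred
        assert parse_level("single_setting", Parameter.setting) is Level.partial_minimum
        assert parse_level("not_stated", Parameter.setting) is Level.unknown
        assert parse_level("met", Parameter.eml_listing) is Level.met_preferred

    def test_inadmissible_token_rejected(self):
        with pytest.raises(SchemaError, match="not admissible"):
            parse_level("met_minimum", Parameter.eml_listing)
        with pytest.raises(SchemaError, match="unknown level"):
            parse_level("excellent", Parameter.efficacy)


class TestValidateSheet:
    def test_maximal_sheet_valid(self):
        sheet = make_sheet()
        assert validate_sheet(sheet) is sheet

    def test_single_setting_sheet_valid(self):
        sheet = make_sheet(setting=Level.partial_minimum)
        assert validate_sheet(sheet) is sheet

    def test_inadmissible_level_named(self):
        sheet = make_sheet(eml_listing=Level.partial_minimum)
        with pytest.raises(SchemaError, match="eml_listing.*partial_minimum"):
            validate_sheet(sheet)

    def test_missing_parameter_named(self):
        levels = {p: Level.met_preferred for p in PARAMETERS if p is not Parameter.safety}
        with pytest.raises(SchemaError, match="safety"):
            validate_sheet(RatingSheet("c", "r", levels))


class TestAdjudicate:
    def test_identical_sheets_pass_through(self):
        a = make_sheet(rater_id="a")
        b = make_sheet(rater_id="b")
        result = adjudicate(a, b)
        assert result.merged.levels == a.levels
        assert result.merged.rater_id == CONSENSUS_RATER
        assert result.disagreements == ()
        assert result.resolved_by_third == frozenset()
        assert result.is_resolved

    def test_third_resolves_single_disagreement(self):
        a = make_sheet(rater_id="a", efficacy=Level.met_minimum)
        b = make_sheet(rater_id="b", efficacy=Level.partial_minimum)
        result = adjudicate(a, b, {Parameter.efficacy: Level.met_minimum})
        assert result.merged.level(Parameter.efficacy) is Level.met_minimum
        assert result.resolved_by_third == frozenset({Parameter.efficacy})
        assert result.is_resolved

    def test_uncovered_disagreement_flags_unresolved(self):
        a = make_sheet(rater_id="a", efficacy=Level.met_minimum, safety=Level.not_met)
        b = make_sheet(rater_id="b")
        result = adjudicate(a, b, {Parameter.efficacy: Level.met_minimum})
        assert not result.is_resolved
        assert result.unresolved == frozenset({Parameter.safety})

    def test_mismatched_candidate_rejected(self):
        with pytest.raises(UsageError):
            adjudicate(make_sheet("c1"), make_sheet("c2"))

    def test_inadmissible_third_level_rejected(self):
        a = make_sheet(rater_id="a", eml_listing=Level.met_preferred)
        b = make_sheet(rater_id="b", eml_listing=Level.not_met)
        with pytest.raises(SchemaError):
            adjudicate(a, b, {Parameter.eml_listing: Level.met_minimum})

    # oracle: per-parameter three-way truth table — merged level is a's when
    # a == b, otherwise the third rater's
    @pytest.mark.parametrize("parameter", [Parameter.efficacy, Parameter.setting])
    def test_three_way_truth_table(self, parameter):
        admissible = sorted(admissible_levels(parameter), key=lambda lv: lv.value)
        for la, lb, lc in itertools.product(admissible, repeat=3):
            a = make_sheet(rater_id="a", **{parameter.value: la})
            b = make_sheet(rater_id="b", **{parameter.value: lb})
            result = adjudicate(a, b, {parameter: lc})
            expected = la if la == lb else lc
            assert result.merged.level(parameter) is expected


class TestAgreementRate:
    def test_identity(self):
        assert agreement_rate(make_sheet(), make_sheet()) == 1.0

    def test_complete_disagreement(self):
        a = make_sheet(default_level=Level.met_preferred)
        b = make_sheet(default_level=Level.unknown)
        assert agreement_rate(a, b) == 0.0

    def test_three_of_nine_differ(self):
        b = make_sheet(
            efficacy=Level.met_minimum,
            safety=Level.met_minimum,
            adherence=Level.met_minimum,
        )
        assert agreement_rate(make_sheet(), b) == pytest.approx(6 / 9, abs=1e-9)

    def test_mismatched_candidate_rejected(self):
        with pytest.raises(UsageError):
            agreement_rate(make_sheet("c1"), make_sheet("c2"))


# ---------------------------------------------------------------------------
# properties


@st.composite
def sheets(draw, candidate_id="CAND000", rater_id="r"):
    levels = {
        p: draw(st.sampled_from(sorted(ADMISSIBLE[SCALE_OF[p]], key=lambda lv: lv.value)))
        for p in PARAMETERS
    }
    return RatingSheet(candidate_id, rater_id, levels)


@settings(max_examples=60, deadline=None)
@given(sheet=sheets())
def test_agreement_rate_identity_property(sheet):
    assert agreement_rate(sheet, sheet) == 1.0


@settings(max_examples=60, deadline=None)
@given(a=sheets(rater_id="a"), b=sheets(rater_id="b"), c=sheets(rater_id="c"))
def test_adjudication_symmetry_property(a, b, c):
    # with a third map total on disagreements, swapping raters changes nothing
    third = dict(c.levels)
    forward = adjudicate(a, b, third)
    backward = adjudicate(b, a, third)
    assert forward.merged.levels == backward.merged.levels
    assert forward.resolved_by_third == backward.resolved_by_third
    assert forward.is_resolved and backward.is_resolved


# ---------------------------------------------------------------------------
# serialisation


def test_csv_round_trip(tmp_path):
    sheets_list = [
        make_sheet("c1", "a"),
        make_sheet("c1", "b", setting=Level.partial_minimum, stability=Level.not_met),
        make_sheet("c2", "a", default_level=Level.unknown),
    ]
    path = tmp_path / "sheets.csv"
    write_sheets(sheets_list, path)
    assert load_sheets(path) == sheets_list


def test_csv_accepts_aliases(tmp_path):
    path = tmp_path / "sheets.csv"
    write_sheets([make_sheet("c1", "a")], path)
    text = path.read_text()
    # the canonical met_preferred token for setting may be written as its alias
    text = text.replace("met_preferred", "both_settings", 1)
    path.write_text(text)
    (sheet,) = load_sheets(path)
    assert sheet.level(Parameter.setting) is Level.met_preferred


def test_long_json_accepted(tmp_path):
    records = [
        {
            "candidate_id": "c1",
            "rater_id": "a",
            "parameter": p.value,
            "level": "met_preferred",
        }
        for p in PARAMETERS
    ]
    path = tmp_path / "sheets.json"
    path.write_text(json.dumps(records))
    (sheet,) = load_sheets(path)
    assert sheet == make_sheet("c1", "a")
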