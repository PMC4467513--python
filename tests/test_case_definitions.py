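"""Predicate evaluation semantics and the default definition set."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vacause.case_definitions import (
    AllOf,
    AnyOf,
    ConfigError,
    DurationInDays,
    ItemAtLeast,
    ItemEquals,
    NoneOf,
    dump_definitions,
    evaluate,
    load_definitions,
    predicate_from_dict,
    predicate_to_dict,
    validate_predicate,
)
from vacause.data_model import AgeStratum

from conftest import make_record


# ---------------------------------------------------------------------------
# Published behaviour anchors of the shipped definitions
# ---------------------------------------------------------------------------


class TestAidsDefinition:
    def test_fires_on_jaundice_alone(self, definitions):
        assert evaluate(definitions["aids"], make_record(jaundice=True))

    def test_fires_on_chronic_diarrhea_over_one_month(self, definitions):
        rec = make_record(diarrhea_present=True, diarrhea_duration_days=45)
        assert evaluate(definitions["aids"], rec)
        # 30 days is not "more than 1 month"
        rec30 = make_record(diarrhea_present=True, diarrhea_duration_days=30)
        assert not evaluate(definitions["aids"], rec30)

    def test_fires_on_any_single_wasting_sign(self, definitions):
        for sign in ("paleness", "hair_color_change", "leg_edema", "dry_scaly_skin"):
            assert evaluate(definitions["aids"], make_record(**{sign: True}))

    def test_cough_window_is_3_to_27_days(self, definitions):
        ok = make_record(cough=True, cough_duration_days=10, fever=True)
        assert evaluate(definitions["aids"], ok)
        too_long = make_record(cough=True, cough_duration_days=28, fever=True)
        assert not evaluate(definitions["aids"], too_long)
        too_short = make_record(cough=True, cough_duration_days=2, fever=True)
        assert not evaluate(definitions["aids"], too_short)

    def test_recent_tb_diagnosis_vetoes_respiratory_condition(self, definitions):
        rec = make_record(cough=True, cough_duration_days=10, fever=True,
                          tb_diagnosis_recent=True)
        assert not evaluate(definitions["aids"], rec)

    def test_false_when_all_five_condition_groups_absent(self, definitions):
        assert not evaluate(definitions["aids"], make_record())


class TestDiarrheaDefinition:
    def test_requires_six_or_more_stools_on_worst_day(self, definitions):
        few = make_record(diarrhea_present=True, stools_max_per_day=4)
        assert not evaluate(definitions["diarrhea"], few)
        many = make_record(diarrhea_present=True, stools_max_per_day=6)
        assert evaluate(definitions["diarrhea"], many)

    def test_stool_count_alone_is_not_diarrhea(self, definitions):
        assert not evaluate(definitions["diarrhea"], make_record(stools_max_per_day=9))


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------


class TestLoadDefinitions:
    def test_empty_config_equals_builtins(self, tmp_path, codebook, definitions):
        path = tmp_path / "defs.yaml"
        path.write_text("{}\n")
        assert load_definitions(path, codebook) == definitions

    def test_single_override_leaves_other_causes_unchanged(self, tmp_path, codebook, definitions):
        path = tmp_path / "defs.yaml"
        path.write_text(
            """
definitions:
  diarrhea:
    strata: [neonate_0_27d, child_1_59m]
    predicate:
      all_of:
        - item_equals: {item: diarrhea_present, value: true}
        - item_at_least: {item: stools_max_per_day, count: 4}
"""
        )
        defs = load_definitions(path, codebook)
        assert evaluate(defs["diarrhea"], make_record(diarrhea_present=True, stools_max_per_day=4))
        unchanged = {c: d for c, d in defs.items() if c != "diarrhea"}
        assert unchanged == {c: d for c, d in definitions.items() if c != "diarrhea"}

    def test_unknown_cause_label_rejected(self, tmp_path, codebook):
        path = tmp_path / "defs.yaml"
        path.write_text(
            """
definitions:
  dragonpox:
    strata: [child_1_59m]
    predicate: {item_equals: {item: fever, value: true}}
"""
        )
        with pytest.raises(ConfigError, match="dragonpox"):
            load_definitions(path, codebook)

    def test_unknown_item_rejected_with_location(self, codebook):
        pred = AllOf((ItemEquals("fever"), ItemEquals("not_an_item")))
        with pytest.raises(ConfigError, match=r"not_an_item"):
            validate_predicate(pred, codebook, "defs.test")

    def test_round_trip_is_lossless(self, tmp_path, codebook, definitions):
        out = tmp_path / "dump.yaml"
        dump_definitions(definitions, out)
        assert load_definitions(out, codebook) == definitions

    def test_duration_window_min_must_not_exceed_max(self):
        with pytest.raises(ConfigError, match="min"):
            DurationInDays(item="cough_duration_days", min_days=10, max_days=3)


# ---------------------------------------------------------------------------
# Property tests: evaluation semantics
# ---------------------------------------------------------------------------

ITEMS = ["i1", "i2", "i3", "d1", "c1"]


def leaf_strategy():
    return st.one_of(
        st.sampled_from(["i1", "i2", "i3"]).map(lambda i: ItemEquals(i, True)),
        st.tuples(st.just("c1"), st.integers(0, 8)).map(lambda t: ItemAtLeast(*t)),
        st.tuples(st.just("d1"), st.integers(0, 20), st.integers(0, 40)).map(
            lambda t: DurationInDays(t[0], min(t[1], t[2]), max(t[1], t[2]))
        ),
    )


def predicate_strategy():
    return st.recursive(
        leaf_strategy(),
        lambda children: st.one_of(
            st.lists(children, min_size=1, max_size=3).map(lambda c: AllOf(tuple(c))),
            st.lists(children, min_size=1, max_size=3).map(lambda c: AnyOf(tuple(c))),
            st.lists(children, min_size=1, max_size=3).map(lambda c: NoneOf(tuple(c))),
        ),
        max_leaves=12,
    )


def responses_strategy():
    return st.fixed_dictionaries(
        {},
        optional={
            "i1": st.booleans(),
            "i2": st.booleans(),
            "i3": st.booleans(),
            "d1": st.integers(0, 40),
            "c1": st.integers(0, 8),
        },
    )


def reference_interpreter(pred, responses):
    """Independent truth-table style evaluator used as an oracle."""
    if isinstance(pred, ItemEquals):
        return responses.get(pred.item, None) == pred.value
    if isinstance(pred, ItemAtLeast):
        v = responses.get(pred.item)
        return False if v is None else v >= pred.count
    if isinstance(pred, DurationInDays):
        v = responses.get(pred.item)
        if v is None:
            return False
        hi = float("inf") if pred.max_days is None else pred.max_days
        return pred.min_days <= v <= hi
    results = [reference_interpreter(c, responses) for c in pred.children]
    if isinstance(pred, AllOf):
        return sum(results) == len(results)
    if isinstance(pred, AnyOf):
        return sum(results) > 0
    if isinstance(pred, NoneOf):
        return sum(results) == 0
    raise TypeError(pred)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(pred=predicate_strategy(), responses=responses_strategy())
def test_evaluation_matches_reference_interpreter(pred, responses):
    assert pred.evaluate(responses) == reference_interpreter(pred, responses)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(pred=predicate_strategy(), responses=responses_strategy())
def test_absent_and_explicitly_missing_are_equivalent(pred, responses):
    before = pred.evaluate(responses)
    for item in ITEMS:
        if item not in responses:
            assert pred.evaluate({**responses, item: None}) == before


@settings(max_examples=200, deadline=None, derandomize=True)
@given(children=st.lists(predicate_strategy(), min_size=1, max_size=3),
       responses=responses_strategy())
def test_none_of_is_negated_any_of(children, responses):
    children = tuple(children)
    assert NoneOf(children).evaluate(responses) == (not AnyOf(children).evaluate(responses))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(pred=predicate_strategy())
def test_serialization_round_trip(pred):
    assert predicate_from_dict(predicate_to_dict(pred)) == pred


def test_definitions_cover_both_strata(definitions):
    neonatal = {c for c, d in definitions.items() if AgeStratum.NEONATE in d.applicable_strata}
    child = {c for c, d in definitions.items() if AgeStratum.CHILD in d.applicable_strata}
    assert "tetanus" in neonatal and "measles" in child
    assert "diarrhea" in neonatal & child
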