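"""First-hit hierarchy walk, multi-cause group handling, redistribution."""

import numpy as np
import pytest

from vacause.case_definitions import ConfigError, evaluate
from vacause.data_model import AgeStratum, VARecord
from vacause.hierarchy_engine import (
    CauseAssignment,
    Hierarchy,
    assign,
    assign_all,
    default_hierarchies,
    redistribute,
    validate_constraints,
)

from conftest import make_record


def neonatal_record(**responses):
    return make_record(age=5, **responses)


class TestAssign:
    def test_first_hit_wins_and_stops_evaluation(self, hierarchies, definitions):
        # meets both tetanus and pneumonia definitions; tetanus is earlier
        rec = neonatal_record(
            stopped_suckling=True, convulsions=True, cough=True, fast_breathing=True
        )
        result = assign(rec, hierarchies[AgeStratum.NEONATE], definitions)
        assert result.final_cause == "tetanus"
        assert result.provisional_causes == ("tetanus",)
        evaluated = [c for c, _ in result.rule_trace]
        assert "pneumonia" not in evaluated  # never evaluated after the hit

    def test_multi_cause_group_collects_all_firing_members(self, hierarchies, definitions):
        rec = make_record(
            diarrhea_present=True, stools_max_per_day=8,
            cough=True, fast_breathing=True,
        )
        result = assign(rec, hierarchies[AgeStratum.CHILD], definitions)
        assert set(result.provisional_causes) == {"diarrhea", "ari"}
        assert result.final_cause is None and result.pending

    def test_group_membership_skips_later_non_group_causes(self, hierarchies, definitions):
        # fires diarrhea (group) and would fire meningitis if evaluated
        rec = make_record(
            diarrhea_present=True, stools_max_per_day=8, fever=True, stiff_neck=True
        )
        result = assign(rec, hierarchies[AgeStratum.CHILD], definitions)
        assert result.provisional_causes == ("diarrhea",)
        assert result.final_cause == "diarrhea"
        assert "meningitis" not in [c for c, _ in result.rule_trace]

    def test_no_definition_fires_gives_unspecified(self, hierarchies, definitions):
        result = assign(make_record(), hierarchies[AgeStratum.CHILD], definitions)
        assert result.final_cause == "unspecified"
        assert result.provisional_causes == ("unspecified",)
        assert all(not fired for _, fired in result.rule_trace)

    def test_missing_definition_is_a_configuration_error(self, definitions):
        h = Hierarchy(stratum=AgeStratum.CHILD, ordered_causes=("malaria", "dragonpox"))
        with pytest.raises(ConfigError, match="dragonpox"):
            assign(make_record(), h, definitions)

    def test_stratum_mismatch_rejected(self, hierarchies, definitions):
        with pytest.raises(ValueError, match="hierarchy"):
            assign(neonatal_record(), hierarchies[AgeStratum.CHILD], definitions)


class TestDefaultHierarchies:
    def test_child_partial_order(self, hierarchies):
        h = hierarchies[AgeStratum.CHILD]
        assert h.index("ari") < h.index("meningitis") < h.index("malaria") < h.index("aids")

    def test_neonatal_hierarchy_excludes_malaria_and_aids(self, hierarchies):
        order = hierarchies[AgeStratum.NEONATE].ordered_causes
        assert "malaria" not in order and "aids" not in order

    def test_neonatal_sepsis_placed_after_diarrhea_and_ari_screens(self, hierarchies):
        h = hierarchies[AgeStratum.NEONATE]
        assert h.index("neonatal_sepsis") > h.index("diarrhea")
        assert h.index("neonatal_sepsis") > h.index("pneumonia")

    def test_multi_cause_group_is_child_only(self, hierarchies):
        assert hierarchies[AgeStratum.NEONATE].multi_cause_group == frozenset()
        assert hierarchies[AgeStratum.CHILD].multi_cause_group == {
            "measles", "diarrhea", "ari",
        }

    def test_validator_rejects_order_violations(self):
        bad = Hierarchy(
            stratum=AgeStratum.CHILD,
            ordered_causes=("aids", "malaria", "meningitis", "ari"),
        )
        with pytest.raises(ConfigError):
            validate_constraints(bad)
        bad_neo = Hierarchy(stratum=AgeStratum.NEONATE, ordered_causes=("malaria",))
        with pytest.raises(ConfigError):
            validate_constraints(bad_neo)


def _pending(rid, causes, stratum=AgeStratum.CHILD):
    return CauseAssignment(rid, stratum, tuple(causes), None)


def _final(rid, cause, stratum=AgeStratum.CHILD):
    return CauseAssignment(rid, stratum, (cause,), cause)


class TestRedistribute:
    def test_fractional_split_proportional_to_prior_csmf(self):
        # single-cause weighted CSMFs diarrhea:ari = 2:1
        assignments = [
            _final("a", "diarrhea"), _final("b", "diarrhea"), _final("c", "ari"),
            _pending("p", ["diarrhea", "ari"]),
        ]
        weights = {"a": 1.0, "b": 1.0, "c": 1.0, "p": 3.0}
        out = redistribute(assignments, weights, mode="fractional")
        resolved = {a.record_id: a for a in out}
        assert resolved["p"].fractions() == pytest.approx({"diarrhea": 2 / 3, "ari": 1 / 3})
        assert resolved["p"].final_cause == "diarrhea"  # larger share, for reporting

    def test_singleton_pending_resolves_to_itself(self):
        out = redistribute([_pending("p", ["measles"])], {"p": 1.0})
        assert out[0].final_cause == "measles"
        assert out[0].fractions() == {"measles": 1.0}

    def test_no_pending_is_identity(self):
        assignments = [_final("a", "malaria"), _final("b", "ari")]
        assert redistribute(assignments, {"a": 1.0, "b": 1.0}) == assignments

    def test_zero_prior_csmf_splits_equally(self):
        out = redistribute([_pending("p", ["measles", "ari"])], {"p": 2.0})
        assert out[0].fractions() == pytest.approx({"measles": 0.5, "ari": 0.5})

    def test_sample_mode_is_seeded_and_proportional(self):
        assignments = [_final(f"d{i}", "diarrhea") for i in range(9)] + [
            _final("a0", "ari"),
            _pending("p", ["diarrhea", "ari"]),
        ]
        weights = {a.record_id: 1.0 for a in assignments}
        first = redistribute(assignments, weights, seed=5, mode="sample")
        second = redistribute(assignments, weights, seed=5, mode="sample")
        assert [a.final_cause for a in first] == [a.final_cause for a in second]
        # across seeds the draw follows the 9:1 prior
        draws = [
            redistribute(assignments, weights, seed=s, mode="sample")[-1].final_cause
            for s in range(200)
        ]
        assert 0.8 < draws.count("diarrhea") / 200 <= 1.0

    def test_sampling_and_fractional_agree_in_expectation(self):
        rng = np.random.default_rng(0)
        assignments = [_final("a", "diarrhea"), _final("b", "ari"), _final("c", "ari")]
        pending = [_pending(f"p{i}", ["diarrhea", "ari"]) for i in range(300)]
        weights = {x.record_id: 1.0 for x in assignments + pending}
        frac = redistribute(assignments + pending, weights, mode="fractional")
        expected = sum(a.fractions().get("diarrhea", 0.0) for a in frac)
        sampled = redistribute(assignments + pending, weights, seed=17, mode="sample")
        got = sum(a.fractions().get("diarrhea", 0.0) for a in sampled)
        # binomial fluctuation around the fractional expectation
        assert abs(got - expected) < 3 * np.sqrt(300 * (1 / 3) * (2 / 3))


def test_assign_all_covers_both_strata(hierarchies, definitions):
    records = [
        neonatal_record(preterm_delivery=True, very_small_at_birth=True),
        make_record(record_id="r2", fever=True, convulsions=True),
    ]
    out = assign_all(records, hierarchies, definitions)
    assert [a.final_cause for a in out] == ["preterm_birth", "malaria"]
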