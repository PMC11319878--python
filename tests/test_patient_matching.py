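"""LOINC mapping, ULN conversion, criterion evaluation, funnel."""

from datetime import date

import numpy as np
import pytest

from elikb.knowledge_base import EAVRecord
from elikb.patient_matching import (
    MATCH,
    NO_MATCH,
    UNKNOWN,
    AmbiguousMapping,
    CriterionPredicate,
    LabMappingError,
    LabReference,
    LabResult,
    NoBoundError,
    PatientRecord,
    UnitError,
    evaluate_criterion,
    expand_medication_class,
    load_lab_references,
    map_loinc,
    run_funnel,
    to_lln,
    to_uln,
)
from elikb.patient_matching import ClassNotFound, MedicationClassTable, _stage_group

INDEX = date(2020, 1, 1)


def _lab(name="creatinine", value=1.0, unit="mg/dL"):
    return LabResult(name, value, unit, date(2019, 12, 1))


def _ref(loinc, rank=None, sample=None, unit="mg/dL", methodless=True):
    return LabReference(
        loinc, "creatinine", unit,
        low={"male": 0.6, "female": 0.5},
        high={"male": 1.2, "female": 1.1},
        popularity_rank=rank, sample_type=sample, methodless=methodless,
    )


class TestLoincMapping:
    def test_rule1_popularity_rank_wins(self):
        ref, rule = map_loinc(_lab(), [_ref("a", rank=2), _ref("b", rank=1)])
        assert (ref.loinc, rule) == ("b", 1)

    def test_rule2_serum_preferred_when_no_rank(self):
        ref, rule = map_loinc(_lab(), [_ref("a", sample="urine"), _ref("b", sample="serum")])
        assert (ref.loinc, rule) == ("b", 2)

    def test_rule3_gram_unit_preferred_over_molar(self):
        ref, rule = map_loinc(
            _lab(), [_ref("a", unit="umol/L"), _ref("b", unit="mg/dL")]
        )
        assert (ref.loinc, rule) == ("b", 3)

    def test_rule4_methodless_preferred(self):
        ref, rule = map_loinc(_lab(), [_ref("a", methodless=False), _ref("b")])
        assert (ref.loinc, rule) == ("b", 4)

    def test_identical_candidates_signal_ambiguity(self):
        with pytest.raises(AmbiguousMapping) as exc:
            map_loinc(_lab(), [_ref("a"), _ref("b")])
        assert {s.loinc for s in exc.value.survivors} == {"a", "b"}

    def test_no_candidate_signals_not_found(self):
        with pytest.raises(LabMappingError):
            map_loinc(LabResult("obscure assay", 1, "U/L", INDEX), [_ref("a")])

    def test_rule_cascade_is_a_refinement(self):
        """Each rule's survivor set is a non-empty subset of the previous
        one, and the cascade's winner comes from the final survivor set."""

        def step_sets(cands):
            sets = [set(c.loinc for c in cands)]
            cur = list(cands)
            ranked = [c for c in cur if c.popularity_rank is not None]
            if ranked:
                best = min(c.popularity_rank for c in ranked)
                cur = [c for c in ranked if c.popularity_rank == best]
            sets.append(set(c.loinc for c in cur))
            cur = [c for c in cur if c.sample_type in ("serum", "plasma")] or cur
            sets.append(set(c.loinc for c in cur))
            cur = [c for c in cur if "mol" not in c.unit.lower()] or cur
            sets.append(set(c.loinc for c in cur))
            cur = [c for c in cur if c.methodless] or cur
            sets.append(set(c.loinc for c in cur))
            return sets

        rng = np.random.default_rng(0)
        ranks = [None, 1, 2]
        samples = [None, "serum", "urine"]
        units = ["mg/dL", "umol/L"]
        for trial in range(50):
            cands = [
                _ref(
                    f"c{i}",
                    rank=ranks[rng.integers(3)],
                    sample=samples[rng.integers(3)],
                    unit=units[rng.integers(2)],
                    methodless=bool(rng.integers(2)),
                )
                for i in range(int(rng.integers(2, 6)))
            ]
            sets = step_sets(cands)
            for earlier, later in zip(sets, sets[1:]):
                assert later and later <= earlier
            try:
                ref, rule = map_loinc(_lab(), cands)
            except AmbiguousMapping as exc:
                assert {s.loinc for s in exc.survivors} == sets[-1]
                continue
            assert ref.loinc in sets[-1] and 0 <= rule <= 4


class TestUlnConversion:
    def test_alt_140_is_2_5_uln(self):
        refs = load_lab_references()
        alt_ref = next(r for r in refs if r.name == "ALT")
        lab = LabResult("ALT", 140.0, "U/L", INDEX)
        assert to_uln(lab, alt_ref, "male") == pytest.approx(2.5)

    def test_value_equal_to_uln_is_exactly_one(self):
        ref = _ref("a")
        assert to_uln(_lab(value=1.2), ref, "male") == 1.0

    def test_male_creatinine_example(self):
        assert to_uln(_lab(value=1.8), _ref("a"), "male") == pytest.approx(1.5)

    def test_homogeneity(self):
        ref = _ref("a")
        base = to_uln(_lab(value=0.9), ref, "female")
        for k in (0.5, 2.0, 3.7):
            assert to_uln(_lab(value=0.9 * k), ref, "female") == pytest.approx(k * base)

    def test_lln_uses_lower_bound(self):
        assert to_lln(_lab(value=0.6), _ref("a"), "male") == 1.0

    def test_incompatible_units_rejected(self):
        with pytest.raises(UnitError):
            to_uln(_lab(unit="umol/L"), _ref("a"), "male")

    def test_table_equivalent_units_accepted(self):
        ref = LabReference("a", "ANC", "10^3/uL", low={"male": 1.5}, high={"male": 8.0})
        lab = LabResult("ANC", 4.0, "K/microliter", INDEX)
        assert to_uln(lab, ref, "male") == pytest.approx(0.5)

    def test_missing_bound_signals(self):
        ref = LabReference("a", "direct bilirubin", "mg/dL", low={}, high={})
        with pytest.raises(NoBoundError):
            to_uln(_lab("direct bilirubin", 0.2), ref, "male")

    def test_unrecorded_sex_uses_midpoint(self):
        assert to_uln(_lab(value=1.15), _ref("a"), "unknown") == pytest.approx(1.0)


class TestMedicationClasses:
    def test_androgen_deprivation_therapy_members(self):
        drugs = [d for d, _ in expand_medication_class("androgen deprivation therapy")]
        assert drugs == ["leuprolide", "goserelin", "degarelix"]

    def test_proteasome_inhibitor_includes_bortezomib_code(self):
        assert ("bortezomib", "356733") in expand_medication_class("proteasome inhibitor")

    def test_unknown_class_signals_not_found(self):
        with pytest.raises(ClassNotFound):
            MedicationClassTable({}).members("LHRH agonist")


def _patient(**kw):
    defaults = dict(patient_id="p1", age=60.0, sex="male")
    defaults.update(kw)
    return PatientRecord(**defaults)


class TestEvaluateCriterion:
    def test_chf_exclusion_disqualifies_coded_patient(self, matcher):
        pred = CriterionPredicate(
            EAVRecord("comorbidity", "congestive heart failure", "yes"), section="exclusion"
        )
        p = _patient(diagnoses=[("I50.3", date(2018, 5, 1))])
        assert evaluate_criterion(p, pred, INDEX, matcher).verdict == NO_MATCH
        clean = _patient()
        assert evaluate_criterion(clean, pred, INDEX, matcher).verdict == MATCH

    def test_icd9_character_class_patterns_match(self, matcher):
        pred = CriterionPredicate(
            EAVRecord("comorbidity", "congestive heart failure", "yes"), section="exclusion"
        )
        p = _patient(diagnoses=[("428.31", date(2018, 5, 1))])
        assert evaluate_criterion(p, pred, INDEX, matcher).verdict == NO_MATCH
        near_miss = _patient(diagnoses=[("428.19", date(2018, 5, 1))])
        assert evaluate_criterion(near_miss, pred, INDEX, matcher).verdict == MATCH

    def test_ecog_inclusion(self, matcher):
        pred = CriterionPredicate(
            EAVRecord("vital", "ECOG", "0-1"), comparator="≤", threshold=1
        )
        assert evaluate_criterion(_patient(ecog=1), pred, INDEX, matcher).verdict == MATCH
        assert evaluate_criterion(_patient(ecog=3), pred, INDEX, matcher).verdict == NO_MATCH
        assert evaluate_criterion(_patient(), pred, INDEX, matcher).verdict == UNKNOWN

    def test_missing_lab_is_unknown(self, matcher):
        pred = CriterionPredicate(
            EAVRecord("laboratory_test", "ALT", "≤2.5x ULN"),
            comparator="≤", threshold=2.5, threshold_unit="xULN",
        )
        assert evaluate_criterion(_patient(), pred, INDEX, matcher).verdict == UNKNOWN

    def test_lab_uln_comparison_uses_most_recent_result(self, matcher):
        pred = CriterionPredicate(
            EAVRecord("laboratory_test", "ALT", "≤2.5x ULN"),
            comparator="≤", threshold=2.5, threshold_unit="xULN",
        )
        p = _patient(
            labs=[
                LabResult("ALT", 300.0, "U/L", date(2019, 1, 1)),
                LabResult("ALT", 56.0, "U/L", date(2019, 12, 1)),
            ]
        )
        res = evaluate_criterion(p, pred, INDEX, matcher)
        assert res.verdict == MATCH and "1" in res.evidence[0]

    def test_exception_rescues_excluded_match(self, matcher):
        pred2 = CriterionPredicate(
            EAVRecord("procedure", "organ transplantation", "yes"),
            section="exclusion",
            exceptions=["corneal transplant"],
        )
        p2 = _patient(
            procedures=[("organ transplantation", date(2015, 1, 1)), ("corneal transplant", date(2015, 1, 1))]
        )
        assert evaluate_criterion(p2, pred2, INDEX, matcher).verdict == MATCH

    def test_stage_prefix_matching(self):
        assert _stage_group("IIIA") == "III"
        assert _stage_group("IVB") == "IV"
        assert _stage_group("IIIB") != "I"


class TestFunnel:
    def test_zero_predicates_keeps_whole_cohort(self, matcher):
        cohort = [_patient(patient_id=f"p{i}") for i in range(5)]
        report = run_funnel(cohort, [], INDEX, matcher=matcher)
        assert report.final_eligible == 5

    def test_predicate_and_its_negation_empty_the_cohort(self, matcher):
        cohort = [_patient(patient_id=f"p{i}", ecog=i % 3) for i in range(6)]
        pred = CriterionPredicate(EAVRecord("vital", "ECOG", "≤1"), comparator="≤", threshold=1)
        anti = CriterionPredicate(EAVRecord("vital", "ECOG", ">1"), comparator=">", threshold=1)
        report = run_funnel(cohort, [pred, anti], INDEX, matcher=matcher)
        assert report.final_eligible == 0

    def test_counts_are_monotonically_nonincreasing(self, matcher):
        from elikb.synthetic import GeneratorConfig, default_funnel_predicates, gen_patient_cohort

        cohort, _ = gen_patient_cohort(GeneratorConfig(seed=9, n_patients=400))
        report = run_funnel(cohort, default_funnel_predicates(), INDEX, matcher=matcher)
        for step in report.steps:
            assert step.eligible_after <= step.eligible_before
        assert report.steps[0].eligible_before == 400

    def test_final_count_invariant_to_predicate_order(self, matcher):
        from elikb.synthetic import GeneratorConfig, default_funnel_predicates, gen_patient_cohort

        cohort, _ = gen_patient_cohort(GeneratorConfig(seed=10, n_patients=300))
        preds = default_funnel_predicates()
        fwd = run_funnel(cohort, preds, INDEX, matcher=matcher)
        rev = run_funnel(cohort, preds[::-1], INDEX, matcher=matcher)
        assert fwd.final_eligible == rev.final_eligible

    def test_counts_invariant_to_patient_order(self, matcher):
        from elikb.synthetic import GeneratorConfig, default_funnel_predicates, gen_patient_cohort

        cohort, _ = gen_patient_cohort(GeneratorConfig(seed=11, n_patients=200))
        preds = default_funnel_predicates()
        a = run_funnel(cohort, preds, INDEX, matcher=matcher)
        b = run_funnel(cohort[::-1], preds, INDEX, matcher=matcher)
        assert [(s.eligible_before, s.eligible_after) for s in a.steps] == [
            (s.eligible_before, s.eligible_after) for s in b.steps
        ]

    def test_funnel_matches_per_patient_oracle(self, matcher):
        """Funnel counts equal a naive one-patient-at-a-time filter."""
        from elikb.synthetic import GeneratorConfig, default_funnel_predicates, gen_patient_cohort

        cohort, truth = gen_patient_cohort(GeneratorConfig(seed=12, n_patients=500))
        preds = default_funnel_predicates()
        report = run_funnel(cohort, preds, INDEX, matcher=matcher)
        eligible = 0
        for p in cohort:
            if all(
                evaluate_criterion(p, pred, INDEX, matcher).verdict == MATCH
                for pred in preds
            ):
                eligible += 1
        assert report.final_eligible == eligible == truth.final_eligible

    def test_unknown_policy_rejected(self, matcher):
        with pytest.raises(ValueError):
            run_funnel([_patient()], [], INDEX, policy="optimistic", matcher=matcher)

    def test_ignore_unknown_policy_lets_unknowns_survive(self, matcher):
        pred = CriterionPredicate(EAVRecord("vital", "ECOG", "≤1"), comparator="≤", threshold=1)
        cohort = [_patient(patient_id="a"), _patient(patient_id="b", ecog=0)]
        conservative = run_funnel(cohort, [pred], INDEX, matcher=matcher)
        lenient = run_funnel(cohort, [pred], INDEX, policy="ignore_unknown", matcher=matcher)
        assert conservative.final_eligible == 1
        assert lenient.final_eligible == 2
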