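"""Synthetic-data generators: determinism, coverage, planted truth."""

from datetime import date

import pytest
from scipy import stats

from elikb.ontology import load_ontology, validate_annotation
from elikb.patient_matching import run_funnel
from elikb.synthetic import (
    GeneratorConfig,
    GeneratorConfigError,
    default_funnel_predicates,
    gen_criteria_corpus,
    gen_patient_cohort,
)


class TestCriteriaCorpus:
    def test_same_seed_yields_identical_bytes(self):
        a = gen_criteria_corpus(GeneratorConfig(seed=7, n_criteria=100))
        b = gen_criteria_corpus(GeneratorConfig(seed=7, n_criteria=100))
        assert a.to_jsonl() == b.to_jsonl()
        assert a.label_inventory == b.label_inventory

    def test_different_seeds_differ(self):
        a = gen_criteria_corpus(GeneratorConfig(seed=7, n_criteria=100))
        b = gen_criteria_corpus(GeneratorConfig(seed=8, n_criteria=100))
        assert a.to_jsonl() != b.to_jsonl()

    def test_restricting_templates_restricts_labels(self):
        corpus = gen_criteria_corpus(
            GeneratorConfig(seed=1, n_criteria=50, template_weights={"lab_value": 1.0})
        )
        groups = {lab.split("::")[0].removeprefix("B-") for lab in corpus.label_inventory}
        assert groups == {"laboratory_test", "value"}

    def test_unknown_template_id_is_config_error(self):
        with pytest.raises(GeneratorConfigError, match="unknown template"):
            gen_criteria_corpus(GeneratorConfig(template_weights={"nonexistent": 1.0}))

    def test_full_template_set_covers_every_label_at_n2000(self):
        corpus = gen_criteria_corpus(GeneratorConfig(seed=7, n_criteria=2000))
        ontology = load_ontology()
        groups_seen = {lab.split("::")[0] for lab in corpus.label_inventory}
        assert groups_seen == {g.name for g in ontology.groups}
        assert all(count >= 20 for count in corpus.label_inventory.values())
        relations_seen = {r.relation for c in corpus.criteria for r in c.relations}
        assert relations_seen == {r.name for r in ontology.relations}

    def test_gold_annotations_are_schema_valid(self, small_corpus, ontology):
        for crit in small_corpus:
            assert validate_annotation(crit, ontology).ok


class TestPatientCohort:
    def test_seed_determinism(self):
        cfg = GeneratorConfig(seed=4, n_patients=200)
        a, ta = gen_patient_cohort(cfg)
        b, tb = gen_patient_cohort(cfg)
        assert ta.expected_funnel == tb.expected_funnel
        assert [(p.patient_id, p.age, p.stage, p.ecog) for p in a] == [
            (p.patient_id, p.age, p.stage, p.ecog) for p in b
        ]

    def test_histology_prevalence_within_binomial_ci(self):
        n = 10_000
        cohort, _ = gen_patient_cohort(GeneratorConfig(seed=2, n_patients=n))
        k = sum(1 for p in cohort if p.histology == "nonsquamous")
        lo, hi = stats.binom.interval(0.99, n, 0.78)
        assert lo <= k <= hi

    def test_all_prevalences_one_makes_everyone_pass_histology(self):
        cohort, truth = gen_patient_cohort(
            GeneratorConfig(seed=3, n_patients=300, attribute_prevalences={"nonsquamous": 1.0}),
            default_funnel_predicates()[:1],
        )
        assert truth.expected_funnel == [(300, 300)]

    def test_impossible_lab_distribution_gives_zero_eligible(self):
        # ALT sampled entirely above 2.5x ULN (median far above, tiny spread)
        cohort, truth = gen_patient_cohort(
            GeneratorConfig(
                seed=3, n_patients=200,
                lab_value_distributions={"ALT": (5000.0, 0.01)},
            ),
            default_funnel_predicates()[3:4],  # ALT <= 2.5x ULN alone
        )
        assert truth.final_eligible == 0

    def test_unknown_prevalence_key_is_config_error(self):
        with pytest.raises(GeneratorConfigError, match="unknown attribute"):
            gen_patient_cohort(GeneratorConfig(attribute_prevalences={"wingspan": 0.5}))

    def test_unsamplable_predicate_is_config_error(self):
        from elikb.knowledge_base import EAVRecord
        from elikb.patient_matching import CriterionPredicate

        pred = CriterionPredicate(EAVRecord("procedure", "tattoo removal", "yes"))
        with pytest.raises(GeneratorConfigError, match="cannot sample"):
            gen_patient_cohort(GeneratorConfig(n_patients=5), [pred])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_funnel_reproduces_planted_counts(self, seed, matcher):
        cfg = GeneratorConfig(seed=seed, n_patients=800)
        cohort, truth = gen_patient_cohort(cfg)
        report = run_funnel(
            cohort, default_funnel_predicates(), cfg.index_date, matcher=matcher
        )
        assert [
            (s.eligible_before, s.eligible_after) for s in report.steps
        ] == truth.expected_funnel

    def test_missing_data_rates_produce_unknowns(self, matcher):
        cfg = GeneratorConfig(seed=5, n_patients=300, ecog_missing_rate=0.5)
        cohort, truth = gen_patient_cohort(cfg)
        assert any(p.ecog is None for p in cohort)
        report = run_funnel(
            cohort, default_funnel_predicates(), cfg.index_date, matcher=matcher
        )
        assert [
            (s.eligible_before, s.eligible_after) for s in report.steps
        ] == truth.expected_funnel
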