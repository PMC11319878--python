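"""EAV construction, hypernym expansion, prevalent values, code maps."""

import random

import pytest

from elikb.knowledge_base import (
    CodeNotFound,
    EAVRecord,
    HypernymNotFound,
    HypernymTable,
    NoDataError,
    build_eav,
    count_unique_eav,
    expand_hypernym,
    lookup_codes,
    prevalent_value,
    representative_value,
)
from elikb.ontology import AnnotatedCriterion, EntityMention, RelationMention


class TestBuildEav:
    def test_lab_with_value_modifier(self, ontology):
        crit = AnnotatedCriterion(
            "NCT1", "inclusion", "AST ≤2.5x ULN",
            [
                EntityMention("T1", 0, 3, "AST", "laboratory_test", "test"),
                EntityMention("T2", 4, 13, "≤2.5x ULN", "value", "value"),
            ],
            [RelationMention("has_value_limit", "T1", "T2")],
        )
        (rec,) = build_eav([crit], "nsclc", ontology)
        assert rec.entity_group == "laboratory_test"
        assert rec.attribute_name == "AST"
        assert rec.value == "≤ 2.5 xULN"
        assert rec.source_trials == ["NCT1"]

    def test_comorbidity_with_temporal_becomes_presence_plus_condition(self, ontology):
        crit = AnnotatedCriterion(
            "NCT2", "exclusion", "arrhythmia within 3 months",
            [
                EntityMention("T1", 0, 10, "arrhythmia", "comorbidity", "disease"),
                EntityMention("T2", 11, 26, "within 3 months", "temporal", ""),
            ],
            [RelationMention("has_temporal_limit", "T1", "T2")],
        )
        (rec,) = build_eav([crit], "nsclc", ontology)
        assert (rec.value, rec.condition) == ("yes", "within 3 months")

    def test_empty_input_gives_empty_kb(self, ontology):
        assert build_eav([], "nsclc", ontology) == []

    def test_duplicate_triples_merge_source_trials(self, ontology):
        def crit(tid):
            return AnnotatedCriterion(
                tid, "inclusion", "AST ≤2.5x ULN",
                [
                    EntityMention("T1", 0, 3, "AST", "laboratory_test", "test"),
                    EntityMention("T2", 4, 13, "≤2.5x ULN", "value", "value"),
                ],
                [RelationMention("has_value_limit", "T1", "T2")],
            )

        records = build_eav([crit("NCT1"), crit("NCT2")], "nsclc", ontology)
        assert len(records) == 1
        assert records[0].source_trials == ["NCT1", "NCT2"]

    def test_conflicting_value_links_flag_both(self, ontology):
        crit = AnnotatedCriterion(
            "NCT3", "inclusion", "AST ≤2.5x ULN or ≤5x ULN",
            [
                EntityMention("T1", 0, 3, "AST", "laboratory_test", "test"),
                EntityMention("T2", 4, 13, "≤2.5x ULN", "value", "value"),
                EntityMention("T3", 17, 24, "≤5x ULN", "value", "value"),
            ],
            [
                RelationMention("has_value_limit", "T1", "T2"),
                RelationMention("has_value_limit", "T1", "T3"),
            ],
        )
        records = build_eav([crit], "nsclc", ontology)
        assert len(records) == 2 and all(r.flagged for r in records)


class TestUniqueCounting:
    def test_identical_up_to_source_trials_count_once(self):
        a = EAVRecord("laboratory_test", "AST", "≤2.5x ULN", source_trials=["t1"])
        b = EAVRecord("laboratory_test", "AST", "≤2.5x ULN", source_trials=["t2"])
        assert count_unique_eav([a, b]) == 1

    def test_planted_distinct_triples_recovered_under_shuffling(self):
        rng = random.Random(5)
        base = [
            EAVRecord("laboratory_test", f"A{i}", f"v{i % 7}", f"c{i % 3}")
            for i in range(40)
        ]
        k = count_unique_eav(base)
        duplicated = base + [rng.choice(base) for _ in range(100)]
        rng.shuffle(duplicated)
        assert count_unique_eav(duplicated) == k == 40


class TestHypernyms:
    def test_normal_hepatic_function(self):
        exp = expand_hypernym("normal hepatic function")
        assert exp.hyponyms == [
            ("AST", "≤2.5x ULN"),
            ("ALT", "≤2.5x ULN"),
            ("Total bilirubin", "≤1.5x ULN"),
        ]

    def test_first_generation_egfr_inhibitor(self):
        exp = expand_hypernym("first-generation EGFR inhibitor")
        assert [h for h, _ in exp.hyponyms] == ["Gefitinib", "Erlotinib", "Vandetanib"]

    def test_tki_resistant_mutations_include_exon20_t790m(self):
        names = [h for h, _ in expand_hypernym("EGFR mutation resistant to TKI").hyponyms]
        assert "Exon 20 T790M" in names

    def test_lookup_is_case_insensitive(self):
        assert expand_hypernym("Normal Hepatic Function").hyponyms

    def test_second_malignancy_carries_exception_list(self):
        exp = expand_hypernym("second malignancy")
        (hyponym, value), = exp.hyponyms
        assert value == "Yes, with exceptions"
        assert "in situ cervical cancer" in exp.exceptions[hyponym]

    def test_unknown_hypernym_lists_nearest_names(self):
        with pytest.raises(HypernymNotFound) as exc:
            expand_hypernym("normal hepattic function")
        assert exc.value.suggestions

    def test_reverse_lookup_is_a_bijection(self):
        table = HypernymTable.load()
        seen = {}
        for row in table.rows:
            hyp, sub = table.reverse_lookup(row["hyponym"])
            assert (hyp, sub) == (row["hypernym"], row["subgroup"])
            assert seen.setdefault(row["hyponym"].lower(), (hyp, sub)) == (hyp, sub)


class TestPrevalentValue:
    def test_mode_of_planted_histogram(self):
        values = (
            [(2.5, "xULN", f"t{i}") for i in range(12)]
            + [(3.0, "xULN", f"u{i}") for i in range(4)]
            + [(1.5, "xULN", f"v{i}") for i in range(2)]
        )
        pv = prevalent_value("ALT", values)
        assert pv.value == 2.5
        assert pv.histogram == {1.5: 2, 2.5: 12, 3.0: 4}
        assert sum(pv.histogram.values()) == len(values)

    def test_single_value(self):
        pv = prevalent_value("ALT", [(2.0, "xULN", "t0")])
        assert pv.value == 2.0 and not pv.tied

    def test_tie_breaks_toward_stricter_threshold(self):
        # upper-bound multiples: smaller is stricter
        uln = prevalent_value("ALT", [(2.5, "xULN", "a"), (3.0, "xULN", "b")])
        assert uln.value == 2.5 and uln.tied
        # lower-bound counts: larger is stricter
        anc = prevalent_value("ANC", [(1000, "cells/uL", "a"), (1500, "cells/uL", "b")])
        assert anc.value == 1500 and anc.tied

    def test_empty_multiset_signals_no_data(self):
        with pytest.raises(NoDataError):
            prevalent_value("ALT", [])

    def test_bundled_default_anc_representative(self):
        pv = representative_value("ANC")
        assert (pv.value, pv.unit) == (1500.0, "cells/uL")


class TestCodeMaps:
    def test_chf_icd10(self):
        assert lookup_codes("congestive heart failure", "ICD-10") == ["I50.2", "I50.3", "I50.4"]

    def test_alt_loinc_with_normal_range(self):
        entry = lookup_codes("ALT", "LOINC")
        assert entry.code == "1742-6"
        assert (entry.low["male"], entry.high["male"]) == (7.0, 56.0)
        assert entry.unit == "U/L"

    def test_bortezomib_rxnorm(self):
        assert lookup_codes("bortezomib", "RxNorm") == "356733"

    def test_loinc_lookup_follows_synonym_rules(self):
        assert lookup_codes("SGPT", "LOINC").code == "1742-6"

    def test_unknown_concept_signals_not_found(self):
        with pytest.raises(CodeNotFound):
            lookup_codes("frobnication index", "LOINC")

    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError):
            lookup_codes("ALT", "SNOMED")
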