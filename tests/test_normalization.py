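"""Attribute normalization: rule tables, idempotence, curation."""

import pytest
from hypothesis import given, settings, strategies as st

from elikb.normalization import (
    ConceptDictionary,
    CurationOverrides,
    apply_curation,
    load_rules,
    normalize_comparator,
    normalize_temporal,
    normalize_term,
    normalize_unit,
    parse_value_expression,
)

RULES = load_rules()


class TestRuleTable:
    """Every bundled pattern maps to its canonical, for every rule class."""

    @pytest.mark.parametrize(
        "rule", [r for r in RULES.rules if r.rule_class == "synonym"], ids=lambda r: r.canonical
    )
    def test_synonym_patterns(self, rule):
        for pattern in rule.patterns:
            assert normalize_term(pattern, RULES).canonical_name == rule.canonical
            # case-insensitive and whitespace-stripped
            assert normalize_term(pattern.upper(), RULES).canonical_name == rule.canonical
            assert normalize_term(pattern.replace(" ", "  "), RULES).canonical_name == rule.canonical

    @pytest.mark.parametrize(
        "rule", [r for r in RULES.rules if r.rule_class == "comparator"], ids=lambda r: r.canonical
    )
    def test_comparator_patterns(self, rule):
        for pattern in rule.patterns:
            assert normalize_comparator(pattern, RULES) == rule.canonical
            assert normalize_comparator(pattern.upper(), RULES) == rule.canonical

    @pytest.mark.parametrize(
        "rule", [r for r in RULES.rules if r.rule_class == "temporal"], ids=lambda r: r.canonical
    )
    def test_temporal_patterns(self, rule):
        for pattern in rule.patterns:
            assert normalize_temporal(pattern, RULES) == (rule.canonical, True)

    def test_unit_patterns(self):
        (rule,) = [r for r in RULES.rules if r.rule_class == "unit"]
        for pattern in rule.patterns:
            assert normalize_unit(pattern, RULES) == ("10^3/uL", True)


class TestExamples:
    def test_sgpt_maps_to_alt(self):
        assert normalize_term("SGPT").canonical_name == "ALT"

    def test_er_positive_gets_cui(self):
        attr = normalize_term("ER+")
        assert attr.cui == "C0279754"
        assert attr.provenance == "dictionary"

    def test_canonical_is_fixed_point(self):
        assert normalize_term("ALT").canonical_name == "ALT"

    def test_unrecognized_comparator_signals_none(self):
        assert normalize_comparator("at most") is None

    def test_generalized_temporal_windows(self):
        assert normalize_temporal("within 10 days") == ("within 10 days", True)
        assert normalize_temporal("past 6 months") == ("within 6 months", True)
        assert normalize_temporal("within seven days") == ("within 1 week", True)
        out, ok = normalize_temporal("sometime recently")
        assert not ok

    def test_unknown_unit_passes_through_flagged(self):
        assert normalize_unit("mmol/L") == ("mmol/L", False)

    @pytest.mark.parametrize(
        ("text", "expected"),
        [
            ("≤2.5x ULN", ("≤", 2.5, "xULN")),
            ("greater than or equal to 1.5x ULN", ("≥", 1.5, "xULN")),
            ("≥ 100,000 cells/uL", ("≥", 100000.0, "cells/uL")),
            ("≥1500 K/microliter", ("≥", 1500.0, "10^3/uL")),
            ("no numbers here", (None, None, None)),
        ],
    )
    def test_value_expression_parsing(self, text, expected):
        assert parse_value_expression(text) == expected


class TestIdempotence:
    def test_every_bundled_pattern_is_idempotent(self):
        for rule in RULES.rules:
            if rule.rule_class in ("misc",):
                continue
            for pattern in rule.patterns:
                once = normalize_term(pattern, RULES)
                twice = normalize_term(once.canonical_name, RULES)
                assert twice.canonical_name == once.canonical_name

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet=st.characters(codec="utf-8", categories=("L", "N", "P", "Zs")), max_size=30))
    def test_normalization_is_idempotent_on_arbitrary_surfaces(self, surface):
        once = normalize_term(surface, RULES)
        twice = normalize_term(once.canonical_name, RULES)
        assert twice.canonical_name == once.canonical_name


class TestProvenanceAndCuration:
    def test_provenance_is_total_and_single(self):
        for surface in ("SGPT", "ER+", "blorp unknown thing"):
            attr = normalize_term(surface)
            assert attr.provenance in ("dictionary", "rule", "curation", "uncurated")

    def test_misspelling_resolved_only_by_override(self):
        attr = normalize_term("creatinine clearence")  # misspelled; no rule hit
        assert attr.uncurated
        fixed = apply_curation([attr], CurationOverrides({"creatinine clearence": "CrCl"}))
        assert fixed[0].canonical_name == "CrCl"
        assert fixed[0].provenance == "curation"

    def test_empty_override_file_is_identity(self):
        attrs = [normalize_term(s) for s in ("AST", "weirdness")]
        assert apply_curation(attrs, CurationOverrides()) == attrs

    def test_override_of_rule_resolved_surface_warns_but_applies(self):
        attr = normalize_term("SGOT")
        assert attr.provenance == "rule"
        with pytest.warns(UserWarning, match="conflicts"):
            out = apply_curation([attr], CurationOverrides({"SGOT": "AST enzyme"}))
        assert out[0].canonical_name == "AST enzyme"

    def test_dictionary_is_case_insensitive(self):
        d = ConceptDictionary({"Er+": ("Estrogen receptor positive", "C0279754")})
        assert d.lookup("er+") == ("Estrogen receptor positive", "C0279754")
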