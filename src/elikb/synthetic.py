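"""Synthetic study data: criteria corpora and patient cohorts.

Two generators make the whole pipeline testable without any download:

* :func:`gen_criteria_corpus` realizes eligibility-criterion sentences from
  hand-written templates covering every primary group, every modifier group
  and every relation type of the schema, with token-aligned gold mentions
  and relations constructed alongside the text.

* :func:`gen_patient_cohort` samples coded EHR-style patient records with
  *planted* eligibility: each patient's verdict for each criterion is
  derived at generation time directly from the sampled latent values, so
  expected funnel counts are known ground truth rather than re-derived
  through the matcher under test.

Both are fully seed-reproducible (identical seeds give byte-identical
output).  Default sizes mirror the study conditions the package emulates: a
246-sentence annotated corpus and a 2775-patient pilot cohort, with a
nonsquamous-histology prevalence of 0.78 and downstream prevalences shaped
so the default funnel attrition resembles the pilot scenario.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .knowledge_base import EAVRecord
from .lexicon import PhraseLexicon
from .ontology import AnnotatedCriterion, EntityMention, RelationMention
from .patient_matching import (
    MATCH,
    NO_MATCH,
    UNKNOWN,
    CriterionPredicate,
    LabResult,
    PatientRecord,
)


class GeneratorConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_criteria: int = 246
    n_patients: int = 2775
    index_date: date = date(2020, 1, 1)
    template_weights: dict[str, float] | None = None
    attribute_prevalences: dict[str, float] = field(default_factory=dict)
    lab_value_distributions: dict[str, tuple[float, float]] = field(default_factory=dict)
    lab_missing_rate: float = 0.0
    ecog_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for k, v in self.attribute_prevalences.items():
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"prevalence for {k!r} outside [0,1]")
        for rate in (self.lab_missing_rate, self.ecog_missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise GeneratorConfigError("missing-data rates must be in [0,1]")


# ===================================================== criteria templates

# a slot is (choices, label, role); choices are (surface, label_override)
# pairs or plain strings; label None means literal text.
_T = str  # readability alias


def _slot(choices, label=None, role=None):
    norm = []
    for c in choices:
        if isinstance(c, tuple):
            norm.append(c)
        else:
            norm.append((c, label))
    return (norm, role)


@dataclass
class Template:
    template_id: str
    section: str
    parts: list  # slots from _slot() or literal strings
    relations: list[tuple[str, str, str]] = field(default_factory=list)
    # (relation name, source role, target role)


_LAB_VALUES = ["≤ 2.5 x ULN", "≤ 1.5 x ULN", "≤ 3 x ULN", "≥ 1500 cells/uL", "≥ 9 g/dL"]

TEMPLATES: list[Template] = [
    Template(
        "age", "inclusion",
        [
            _slot(["Age"], "demographic::age", role="p"),
            _slot(["≥ 18 years", "≥ 20 years", "≤ 75 years"], "value::value", role="v"),
        ],
        [("has_value_limit", "p", "v")],
    ),
    Template(
        "gender", "inclusion",
        [
            _slot(["Male", "Female"], "demographic::gender", role="p"),
            "patients are eligible",
        ],
    ),
    Template(
        "lab_value", "inclusion",
        [
            _slot(
                ["AST", "ALT", "serum creatinine", "total bilirubin", "ANC", "platelet count", "hemoglobin"],
                "laboratory_test::test", role="p",
            ),
            _slot(_LAB_VALUES, "value::value", role="v"),
        ],
        [("has_value_limit", "p", "v")],
    ),
    Template(
        "lab_condition", "inclusion",
        [
            _slot(["platelet count", "hemoglobin"], "laboratory_test::test", role="p"),
            _slot(["≥ 100,000 cells/uL", "≥ 9 g/dL"], "value::value", role="v"),
            _slot(
                ["without transfusion support", "without growth factor support"],
                "condition::condition", role="c",
            ),
        ],
        [("has_value_limit", "p", "v"), ("has_condition", "p", "c")],
    ),
    Template(
        "ecog", "inclusion",
        [
            _slot(["ECOG performance status"], "vital::vital", role="p"),
            _slot(["≤ 2", "≤ 1", "0 - 1"], "value::value", role="v"),
        ],
        [("has_value_limit", "p", "v")],
    ),
    Template(
        "histology", "inclusion",
        [
            _slot(
                ["Histologically confirmed", "Cytologically confirmed"],
                "evidence::evidence", role="e",
            ),
            _slot(
                ["nonsquamous NSCLC", "squamous NSCLC", "adenocarcinoma"],
                "diagnosis::histology", role="p",
            ),
        ],
        [("need_evidence", "p", "e")],
    ),
    Template(
        "stage", "inclusion",
        [
            _slot(["Stage IIIB", "Stage IV", "Stage IIIA"], "diagnosis::stage", role="p"),
            "disease at enrollment",
        ],
    ),
    Template(
        "biomarker_neg", "exclusion",
        [
            _slot(["No"], "negation::negation", role="n"),
            _slot(
                ["EGFR T790M mutation", "ALK rearrangement", "HER2 amplification"],
                "biomarker::biomarker", role="p",
            ),
        ],
        [("has_negation", "p", "n")],
    ),
    Template(
        "biomarker_evidence", "inclusion",
        [
            _slot(["EGFR exon 19 deletion", "EGFR L858R mutation"], "biomarker::biomarker", role="p"),
            _slot(["documented by local testing", "confirmed by central laboratory"], "evidence::evidence", role="e"),
        ],
        [("need_evidence", "p", "e")],
    ),
    Template(
        "comorbidity_temporal", "exclusion",
        [
            _slot(
                ["Myocardial infarction", "Unstable angina", "Symptomatic bradycardia"],
                "comorbidity::disease", role="p",
            ),
            _slot(["within 6 months", "within 3 months", "within 28 days"], "temporal::temporal", role="t"),
        ],
        [("has_temporal_limit", "p", "t")],
    ),
    Template(
        "malignancy_exception", "exclusion",
        [
            _slot(["No"], "negation::negation", role="n"),
            _slot(["second malignancy", "active malignancy"], "comorbidity::disease", role="p"),
            "except",
            _slot(
                ["resected skin cancer", "in situ cervical cancer"],
                "exception::exception", role="x",
            ),
        ],
        [("has_negation", "p", "n"), ("has_exception", "p", "x")],
    ),
    Template(
        "neuropathy_grade", "exclusion",
        [
            _slot(["Peripheral neuropathy", "Sensory neuropathy"], "comorbidity::disease", role="p"),
            _slot(["grade ≥ 2", "grade ≥ 3"], "grade::grade", role="g"),
        ],
        [("has_grade_limit", "p", "g")],
    ),
    Template(
        "prior_lines", "inclusion",
        [
            _slot(["At least 2 prior lines", "At least 1 prior line"], "lines_of_therapy::lines_of_therapy", role="l"),
            "of",
            _slot(["platinum-based chemotherapy", "systemic chemotherapy"], "prior_therapy::chemotherapy", role="p"),
        ],
        [("has_line_of_therapy_limit", "p", "l")],
    ),
    Template(
        "prior_therapy_washout", "exclusion",
        [
            _slot(["No"], "negation::negation", role="n"),
            _slot(
                [
                    ("prior radiotherapy", "prior_therapy::radiotherapy"),
                    ("prior immunotherapy", "prior_therapy::immunotherapy"),
                ],
            ),
            _slot(["within 4 weeks", "within 2 weeks"], "temporal::temporal", role="t"),
        ],
        [("has_negation", "p", "n"), ("has_temporal_limit", "p", "t")],
    ),
    Template(
        "progression_on_tki", "inclusion",
        [
            _slot(["Disease progression", "Radiographic progression"], "disease_status::disease_status", role="s"),
            "following treatment with",
            _slot(["erlotinib", "gefitinib", "osimertinib"], "prior_therapy::targeted_therapy", role="p"),
        ],
        [("has_outcome", "p", "s")],
    ),
    Template(
        "medication_dose", "exclusion",
        [
            _slot(["Warfarin", "Prednisone"], "other_medication::medication", role="p"),
            "at a dose of",
            _slot(["> 5 mg daily", "> 10 mg daily"], "dose::dose", role="d"),
            _slot(["within 2 weeks", "within 3 weeks"], "temporal::temporal", role="t"),
        ],
        [("has_dose_limit", "p", "d"), ("has_temporal_limit", "p", "t")],
    ),
    Template(
        "procedure", "exclusion",
        [
            _slot(["Major surgery", "Organ transplantation"], "procedure::procedure", role="p"),
            _slot(["within 28 days", "within 4 weeks"], "temporal::temporal", role="t"),
        ],
        [("has_temporal_limit", "p", "t")],
    ),
    Template(
        "disease_status", "inclusion",
        [
            _slot(["Relapsed", "Refractory", "Measurable"], "disease_status::disease_status", role="p"),
            "disease is required",
        ],
    ),
    Template(
        "observation", "inclusion",
        [
            _slot(
                ["Willing to provide informed consent", "Able to swallow oral medication"],
                "other_observation::observation", role="p",
            ),
        ],
    ),
    Template(
        "medication_class", "exclusion",
        [
            _slot(["No"], "negation::negation", role="n"),
            _slot(
                ["current use of antibiotics", "LHRH agonist therapy"],
                "other_medication::medication", role="p",
            ),
        ],
        [("has_negation", "p", "n")],
    ),
]

# fix the roles of slots whose label varies by choice (prior_therapy_washout)
for _tpl in TEMPLATES:
    if _tpl.template_id == "prior_therapy_washout":
        _tpl.parts[1] = (_tpl.parts[1][0], "p")


def _realize(tpl: Template, rng: np.random.Generator, trial_id: str) -> AnnotatedCriterion:
    pieces: list[str] = []
    mentions: list[EntityMention] = []
    role_to_mid: dict[str, str] = {}
    pos = 0
    for part in tpl.parts:
        if isinstance(part, str):
            if pieces:
                pos += 1  # joining space
            pieces.append(part)
            pos += len(part)
            continue
        choices, role = part
        surface, label = choices[int(rng.integers(len(choices)))]
        if pieces:
            pos += 1
        start = pos
        pieces.append(surface)
        pos += len(surface)
        if label is not None:
            mid = f"T{len(mentions) + 1}"
            group, _, attribute = label.partition("::")
            mentions.append(EntityMention(mid, start, pos, surface, group, attribute))
            if role is not None:
                role_to_mid[role] = mid
    text = " ".join(pieces)
    relations = [
        RelationMention(rel, role_to_mid[src], role_to_mid[tgt])
        for rel, src, tgt in tpl.relations
        if src in role_to_mid and tgt in role_to_mid
    ]
    return AnnotatedCriterion(trial_id, tpl.section, text, mentions, relations)


@dataclass
class CriteriaCorpus:
    criteria: list[AnnotatedCriterion]
    label_inventory: Counter

    def to_jsonl(self) -> str:
        return "".join(
            json.dumps(
                {"trial_id": c.trial_id, "section": c.section, "text": c.text},
                ensure_ascii=False,
            )
            + "\n"
            for c in self.criteria
        )


def gen_criteria_corpus(config: GeneratorConfig) -> CriteriaCorpus:
    """Generate an annotated criteria corpus from the sentence templates."""
    rng = np.random.default_rng(config.seed)
    by_id = {t.template_id: t for t in TEMPLATES}
    if config.template_weights is not None:
        unknown = set(config.template_weights) - set(by_id)
        if unknown:
            raise GeneratorConfigError(f"unknown template ids: {sorted(unknown)}")
        ids = [t for t in by_id if config.template_weights.get(t, 0.0) > 0]
        weights = np.array([config.template_weights[t] for t in ids], dtype=float)
        if not ids:
            raise GeneratorConfigError("all template weights are zero")
        weights /= weights.sum()
    else:
        ids = list(by_id)
        weights = np.full(len(ids), 1.0 / len(ids))
    criteria: list[AnnotatedCriterion] = []
    inventory: Counter = Counter()
    for i in range(config.n_criteria):
        tpl = by_id[ids[int(rng.choice(len(ids), p=weights))]]
        crit = _realize(tpl, rng, f"SYN{i:05d}")
        inventory.update(m.label for m in crit.mentions)
        criteria.append(crit)
    return CriteriaCorpus(criteria, inventory)


def template_lexicon() -> PhraseLexicon:
    """The generator's own phrase lexicon (slot surface -> label)."""
    lex = PhraseLexicon()
    for tpl in TEMPLATES:
        for part in tpl.parts:
            if isinstance(part, str):
                continue
            for surface, label in part[0]:
                if label is not None:
                    lex.add(surface, label)
    return lex


def write_corpus(corpus: CriteriaCorpus, directory: str | Path) -> None:
    """Persist criteria JSONL plus gold standoff .txt/.ann pairs."""
    from .standoff import write_standoff_files

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "criteria.jsonl").write_text(corpus.to_jsonl(), encoding="utf-8")
    gold = d / "gold"
    gold.mkdir(exist_ok=True)
    for c in corpus.criteria:
        write_standoff_files(c, gold / f"{c.trial_id}.txt", gold / f"{c.trial_id}.ann")
    (d / "label_inventory.json").write_text(
        json.dumps(dict(sorted(corpus.label_inventory.items())), indent=1),
        encoding="utf-8",
    )


# ======================================================== patient cohorts

# upper limits of normal used by the generator's own truth computation
# (kept in-line so the ground truth does not route through the matcher)
_ULN = {
    "AST": {"male": 40.0, "female": 40.0},
    "ALT": {"male": 56.0, "female": 56.0},
    "Total bilirubin": {"male": 1.2, "female": 1.2},
    "Serum creatinine": {"male": 1.2, "female": 1.1},
}
_LAB_UNITS = {
    "AST": "U/L",
    "ALT": "U/L",
    "Total bilirubin": "mg/dL",
    "Serum creatinine": "mg/dL",
    "ANC": "cells/uL",
    "Platelets": "cells/uL",
    "Hemoglobin": "g/dL",
}
# (median, sigma) of the log-normal sampling distribution per analyte
_DEFAULT_LAB_DISTS = {
    "AST": (36.0, 0.75),
    "ALT": (50.0, 0.75),
    "Total bilirubin": (0.8, 0.5),
    "Serum creatinine": (0.95, 0.4),
    "ANC": (3500.0, 0.5),
    "Platelets": (250000.0, 0.4),
    "Hemoglobin": (13.0, 0.15),
}
_DEFAULT_PREVALENCES = {
    "nonsquamous": 0.78,
    "stage_iii_iv": 0.197,
    "congestive heart failure": 0.06,
    "acute myocardial infarction": 0.05,
    "arrhythmia": 0.08,
    "warfarin": 0.05,
    "PD-1 antibody": 0.10,
    "EGFR T790M": 0.08,
}
_ECOG_DIST = [0.18, 0.24, 0.11, 0.27, 0.15, 0.05]
_PRIOR_LINES_DIST = [0.30, 0.30, 0.20, 0.12, 0.08]
_STAGE_SUBSTAGES = {
    "I": ["IA", "IB"],
    "II": ["IIA", "IIB"],
    "III": ["IIIA", "IIIB"],
    "IV": ["IVA", "IVB"],
}
_COMORBIDITY_CODES = {
    "congestive heart failure": ["I50.2", "I50.3", "I50.4"],
    "acute myocardial infarction": ["I21"],
    "arrhythmia": ["I49"],
}
_MED_CODES = {"warfarin": ["900032"], "PD-1 antibody": ["900033", "900034"]}


@dataclass
class GroundTruth:
    verdicts: dict[str, dict[str, str]]  # patient_id -> predicate label -> verdict
    expected_funnel: list[tuple[int, int]]  # (before, after) per predicate
    predicate_labels: list[str]

    @property
    def final_eligible(self) -> int:
        return self.expected_funnel[-1][1] if self.expected_funnel else len(self.verdicts)


def default_funnel_predicates() -> list[CriterionPredicate]:
    """The default simulated trial design: nonsquamous histology, stage
    III/IV, AST and ALT at most 2.5x ULN, ECOG at most 1."""
    return [
        CriterionPredicate(
            EAVRecord("diagnosis", "histology", "nonsquamous"), categories=["nonsquamous"]
        ),
        CriterionPredicate(
            EAVRecord("diagnosis", "stage", "III/IV"), categories=["III", "IV"]
        ),
        CriterionPredicate(
            EAVRecord("laboratory_test", "AST", "≤2.5x ULN"),
            comparator="≤", threshold=2.5, threshold_unit="xULN",
        ),
        CriterionPredicate(
            EAVRecord("laboratory_test", "ALT", "≤2.5x ULN"),
            comparator="≤", threshold=2.5, threshold_unit="xULN",
        ),
        CriterionPredicate(
            EAVRecord("vital", "ECOG", "≤1"), comparator="≤", threshold=1,
        ),
    ]


def _truth_verdict(
    predicate: CriterionPredicate,
    latent: dict,
) -> str:
    """Ground-truth verdict from latent sampled values (generator-side)."""
    group = predicate.eav.entity_group
    attr = predicate.eav.attribute_name
    cmp_fns = {
        "≤": lambda v, t: v <= t,
        "≥": lambda v, t: v >= t,
        "<": lambda v, t: v < t,
        ">": lambda v, t: v > t,
        "=": lambda v, t: v == t,
    }
    if group == "diagnosis" and attr == "histology":
        present = latent["histology"] in {c.lower() for c in predicate.categories}
    elif group == "diagnosis" and attr == "stage":
        present = latent["stage_group"] in set(predicate.categories)
    elif group == "laboratory_test":
        value = latent["labs"].get(attr)
        if value is None:
            return UNKNOWN
        if predicate.threshold_unit == "xULN":
            value = value / _ULN[attr][latent["sex"]]
        present = cmp_fns[predicate.comparator](value, predicate.threshold)
    elif group == "vital":
        if latent["ecog"] is None:
            return UNKNOWN
        present = cmp_fns[predicate.comparator](latent["ecog"], predicate.threshold)
    elif group == "demographic" and attr.lower() == "age":
        present = cmp_fns[predicate.comparator](latent["age"], predicate.threshold)
    elif group == "prior_therapy" and attr.lower() in ("prior lot", "lines", "lot"):
        present = cmp_fns[predicate.comparator](latent["prior_lines"], predicate.threshold)
    elif group == "comorbidity":
        present = attr in latent["comorbidities"]
    elif group in ("other_medication",):
        present = attr in latent["medications"]
    elif group == "biomarker":
        status = latent["biomarkers"].get(attr)
        if status is None:
            return UNKNOWN
        present = status == "positive"
    else:
        raise GeneratorConfigError(
            f"generator cannot sample predicate on {group}::{attr}"
        )
    if predicate.excludes:
        if present and any(
            _e in latent.get("exception_concepts", set()) for _e in predicate.exceptions
        ):
            return MATCH
        return NO_MATCH if present else MATCH
    return MATCH if present else NO_MATCH


def gen_patient_cohort(
    config: GeneratorConfig,
    predicates: list[CriterionPredicate] | None = None,
) -> tuple[list[PatientRecord], GroundTruth]:
    """Sample a coded patient cohort with planted per-predicate verdicts.

    Every patient's verdict per predicate is recorded at generation time by
    direct comparison of the sampled latent values against the predicate
    (no matcher involved); expected funnel counts are then accumulated
    under the conservative unknown-is-ineligible policy.
    """
    predicates = predicates if predicates is not None else default_funnel_predicates()
    prev = dict(_DEFAULT_PREVALENCES)
    for k, v in config.attribute_prevalences.items():
        if k not in prev:
            raise GeneratorConfigError(f"unknown attribute {k!r} in prevalence map")
        prev[k] = v
    dists = dict(_DEFAULT_LAB_DISTS)
    for k, v in config.lab_value_distributions.items():
        if k not in dists:
            raise GeneratorConfigError(f"unknown analyte {k!r} in lab distributions")
        dists[k] = v
    rng = np.random.default_rng(config.seed)
    index = config.index_date
    cohort: list[PatientRecord] = []
    verdicts: dict[str, dict[str, str]] = {}
    labels = [p.label for p in predicates]
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        sex = "female" if rng.random() < 0.5 else "male"
        age = float(np.clip(rng.normal(66.0, 10.0), 18.0, 90.0).round(1))
        nonsq = rng.random() < prev["nonsquamous"]
        histology = "nonsquamous" if nonsq else "squamous"
        if rng.random() < prev["stage_iii_iv"]:
            group = "III" if rng.random() < 0.5 else "IV"
        else:
            group = "I" if rng.random() < 0.65 else "II"
        stage = _STAGE_SUBSTAGES[group][int(rng.integers(2))]
        labs: dict[str, float] = {}
        lab_results: list[LabResult] = []
        for analyte, (median, sigma) in dists.items():
            if rng.random() < config.lab_missing_rate:
                continue
            value = float(np.round(median * np.exp(sigma * rng.standard_normal()), 2))
            labs[analyte] = value
            lab_results.append(
                LabResult(
                    analyte,
                    value,
                    _LAB_UNITS[analyte],
                    index - timedelta(days=int(rng.integers(1, 90))),
                    sample_type="serum",
                )
            )
        ecog = None if rng.random() < config.ecog_missing_rate else int(
            rng.choice(6, p=_ECOG_DIST)
        )
        prior_lines = int(rng.choice(len(_PRIOR_LINES_DIST), p=_PRIOR_LINES_DIST))
        comorbidities: set[str] = set()
        diagnoses: list[tuple[str, date]] = []
        for concept, codes in _COMORBIDITY_CODES.items():
            if rng.random() < prev[concept]:
                comorbidities.add(concept)
                diagnoses.append(
                    (
                        codes[int(rng.integers(len(codes)))],
                        index - timedelta(days=int(rng.integers(30, 2000))),
                    )
                )
        medications: set[str] = set()
        med_rows: list[tuple[str, date, date]] = []
        for concept, codes in _MED_CODES.items():
            if rng.random() < prev[concept]:
                medications.add(concept)
                start = index - timedelta(days=int(rng.integers(10, 400)))
                med_rows.append((codes[int(rng.integers(len(codes)))], start, index))
        biomarkers: dict[str, str] = {}
        bm_rows: list[tuple[str, str]] = []
        if rng.random() < 0.7:  # tested at all
            status = "positive" if rng.random() < prev["EGFR T790M"] else "negative"
            biomarkers["EGFR T790M"] = status
            bm_rows.append(("EGFR T790M", status))
        latent = {
            "sex": sex,
            "age": age,
            "histology": histology,
            "stage_group": group,
            "labs": labs,
            "ecog": ecog,
            "prior_lines": prior_lines,
            "comorbidities": comorbidities,
            "medications": medications,
            "biomarkers": biomarkers,
        }
        verdicts[pid] = {
            lab: _truth_verdict(p, latent) for lab, p in zip(labels, predicates)
        }
        cohort.append(
            PatientRecord(
                pid,
                age,
                sex,
                diagnoses=diagnoses,
                histology=histology,
                stage=stage,
                biomarkers=bm_rows,
                labs=lab_results,
                medications=med_rows,
                ecog=ecog,
                prior_lines=prior_lines,
            )
        )
    expected: list[tuple[int, int]] = []
    alive = set(verdicts)
    for lab in labels:
        before = len(alive)
        alive = {pid for pid in alive if verdicts[pid][lab] == MATCH}
        expected.append((before, len(alive)))
    return cohort, GroundTruth(verdicts, expected, labels)
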