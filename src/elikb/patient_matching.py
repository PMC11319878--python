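"""Rule-based patient matching and the sequential eligibility funnel.

Coded EHR-style patient records are matched against computable criterion
predicates (exported from the EAV knowledge base).  Laboratory criteria
expressed as multiples of the upper/lower limit of normal (ULN/LLN) are
evaluated by mapping the patient's local test to a LOINC reference via a
four-rule cascade and dividing the absolute value by the sex-specific
normal-range bound.  Evaluation is three-valued — ``match`` /
``no_match`` / ``unknown`` — and the funnel applies criteria
conjunctively in order, reporting surviving patient counts per step.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

from .knowledge_base import CodeMap, EAVRecord, _data
from .normalization import _key, normalize_term, normalize_unit

logger = logging.getLogger(__name__)

MATCH, NO_MATCH, UNKNOWN = "match", "no_match", "unknown"


# ------------------------------------------------------------------- types


@dataclass
class LabResult:
    local_name: str
    value: float
    unit: str
    date: date
    sample_type: str | None = None  # serum | plasma | blood | other
    method_stated: bool = False

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("lab unit must be non-empty")
        if self.value != self.value or self.value in (float("inf"), float("-inf")):
            raise ValueError("lab value must be finite")


@dataclass
class LabReference:
    loinc: str
    name: str
    unit: str
    low: dict[str, float | None] = field(default_factory=dict)
    high: dict[str, float | None] = field(default_factory=dict)
    popularity_rank: int | None = None
    sample_type: str | None = None
    methodless: bool = True

    def __post_init__(self) -> None:
        for sex in self.low:
            lo, hi = self.low.get(sex), self.high.get(sex)
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"{self.name}: low must be < high")


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    sex: str = "unknown"
    diagnoses: list[tuple[str, date]] = field(default_factory=list)
    histology: str = ""
    stage: str = ""
    biomarkers: list[tuple[str, str]] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    medications: list[tuple[str, date, date]] = field(default_factory=list)
    ecog: int | None = None
    prior_lines: int = 0
    procedures: list[tuple[str, date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ecog is not None and not 0 <= self.ecog <= 5:
            raise ValueError("ecog must be in [0, 5]")
        if self.prior_lines < 0:
            raise ValueError("prior_lines must be >= 0")
        for _, start, end in self.medications:
            if start and end and end < start:
                raise ValueError("medication end date before start date")


@dataclass
class CriterionPredicate:
    """One computable criterion.

    ``comparator``/``threshold``/``threshold_unit`` serve quantitative
    predicates; ``categories`` serves categorical ones (histology terms,
    stage groups, biomarker names, drug classes).  ``section`` is the
    criterion's origin; an exclusion-section predicate (or a negated one)
    makes the *presence* of the condition disqualifying, with
    ``exceptions`` able to rescue an otherwise-excluding match.
    """

    eav: EAVRecord
    comparator: str | None = None
    threshold: float | None = None
    threshold_unit: str | None = None
    categories: list[str] = field(default_factory=list)
    temporal_window: str | None = None
    negated: bool = False
    exceptions: list[str] = field(default_factory=list)
    section: str = "inclusion"

    def __post_init__(self) -> None:
        if self.comparator is not None and self.threshold is None:
            raise ValueError("quantitative predicate needs a threshold")

    @property
    def label(self) -> str:
        parts = [self.eav.entity_group, self.eav.attribute_name]
        if self.comparator is not None:
            parts.append(f"{self.comparator}{self.threshold:g}{self.threshold_unit or ''}")
        elif self.categories:
            parts.append("/".join(self.categories))
        else:
            parts.append(self.eav.value)
        if self.section == "exclusion" or self.negated:
            parts.insert(0, "NOT")
        return " ".join(parts)

    @property
    def excludes(self) -> bool:
        return (self.section == "exclusion") != self.negated  # xor

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CriterionPredicate":
        d = dict(d)
        d["eav"] = EAVRecord(**d["eav"])
        return cls(**d)


@dataclass
class MatchResult:
    patient_id: str
    predicate: str
    verdict: str  # match | no_match | unknown
    evidence: list[str] = field(default_factory=list)


@dataclass
class FunnelStep:
    criterion: str
    eligible_before: int
    eligible_after: int
    verdicts: dict[str, int] = field(default_factory=dict)


@dataclass
class FunnelReport:
    steps: list[FunnelStep]
    policy: str
    index_date: date
    cohort_size: int

    @property
    def final_eligible(self) -> int:
        return self.steps[-1].eligible_after if self.steps else self.cohort_size

    def to_json(self) -> str:
        return json.dumps(
            {
                "policy": self.policy,
                "index_date": self.index_date.isoformat(),
                "cohort_size": self.cohort_size,
                "steps": [
                    {
                        "criterion": s.criterion,
                        "before": s.eligible_before,
                        "after": s.eligible_after,
                        "verdicts": s.verdicts,
                    }
                    for s in self.steps
                ],
                "final_eligible": self.final_eligible,
            },
            indent=1,
        )


# ------------------------------------------------------------ LOINC mapping


class LabMappingError(LookupError):
    pass


class AmbiguousMapping(LabMappingError):
    def __init__(self, name: str, survivors: list[LabReference]):
        self.survivors = survivors
        super().__init__(
            f"{name!r} still ambiguous after all rules: "
            + ", ".join(s.loinc for s in survivors)
        )


def load_lab_references(path: str | Path | None = None) -> list[LabReference]:
    p = Path(path) if path is not None else _data("loinc_references.csv")
    refs: list[LabReference] = []
    with open(p, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            def num(x):
                return float(x) if x not in ("", None) else None

            refs.append(
                LabReference(
                    loinc=row["loinc"],
                    name=row["concept"],
                    unit=row["unit"],
                    low={"male": num(row["low_male"]), "female": num(row["low_female"])},
                    high={"male": num(row["high_male"]), "female": num(row["high_female"])},
                    popularity_rank=int(row["popularity_rank"]) if row["popularity_rank"] else None,
                    sample_type=row["sample_type"] or None,
                    methodless=row["methodless"].lower() in ("true", "1", "yes"),
                )
            )
    return refs


def _is_gram_unit(unit: str) -> bool:
    u = unit.lower()
    return "mol" not in u and bool(re.search(r"(^|[^a-z])[munpk]?g([^a-z]|$)", u))


def map_loinc(
    lab: LabResult, dictionary: list[LabReference]
) -> tuple[LabReference, int]:
    """Map a local laboratory test to one LOINC reference.

    Candidates are the dictionary entries whose name matches the local name
    after synonym normalization.  Four rules apply in order until a unique
    candidate remains — (1) best popularity rank, (2) serum/plasma sample,
    (3) gram-based unit preferred over molar, (4) methodless entry — each
    refining (never enlarging) the candidate set.  Returns the winning
    reference and the number of the rule that resolved it (0 when the name
    alone was unique).
    """
    if not dictionary:
        raise LabMappingError("empty LOINC dictionary")
    target = _key(normalize_term(lab.local_name).canonical_name)
    cands = [
        r
        for r in dictionary
        if _key(normalize_term(r.name).canonical_name) == target
    ]
    if not cands:
        raise LabMappingError(f"no LOINC candidate for {lab.local_name!r}")
    if len(cands) == 1:
        return cands[0], 0
    rules = [
        lambda cs: (
            [c for c in cs if c.popularity_rank == min(x.popularity_rank for x in cs if x.popularity_rank is not None)]
            if any(x.popularity_rank is not None for x in cs)
            else cs
        ),
        lambda cs: [c for c in cs if c.sample_type in ("serum", "plasma")] or cs,
        lambda cs: [c for c in cs if _is_gram_unit(c.unit)] or cs,
        lambda cs: [c for c in cs if c.methodless] or cs,
    ]
    for rule_no, rule in enumerate(rules, start=1):
        cands = rule(cands)
        if len(cands) == 1:
            return cands[0], rule_no
    raise AmbiguousMapping(lab.local_name, cands)


# --------------------------------------------------------- ULN conversion


class UnitError(ValueError):
    pass


class NoBoundError(ValueError):
    """The reference lacks the needed normal-range bound."""


def _resolve_sex(ref_bounds: dict[str, float | None], sex: str) -> float | None:
    if sex in ref_bounds:
        return ref_bounds[sex]
    vals = [v for v in ref_bounds.values() if v is not None]
    if not vals:
        return None
    logger.warning("patient sex %r unrecorded; using male/female midpoint", sex)
    return sum(vals) / len(vals)


def _compatible_units(a: str, b: str) -> bool:
    ca, _ = normalize_unit(a)
    cb, _ = normalize_unit(b)
    return _key(ca) == _key(cb)


def to_uln(lab: LabResult, ref: LabReference, sex: str = "unknown") -> float:
    """Absolute value -> multiple of the upper limit of normal."""
    if not _compatible_units(lab.unit, ref.unit):
        raise UnitError(f"incompatible units {lab.unit!r} vs {ref.unit!r}")
    bound = _resolve_sex(ref.high, sex)
    if bound is None:
        raise NoBoundError(f"{ref.name}: no upper limit of normal")
    return lab.value / bound


def to_lln(lab: LabResult, ref: LabReference, sex: str = "unknown") -> float:
    """Absolute value -> multiple of the lower limit of normal."""
    if not _compatible_units(lab.unit, ref.unit):
        raise UnitError(f"incompatible units {lab.unit!r} vs {ref.unit!r}")
    bound = _resolve_sex(ref.low, sex)
    if bound is None:
        raise NoBoundError(f"{ref.name}: no lower limit of normal")
    return lab.value / bound


# ----------------------------------------------------- medication classes


class ClassNotFound(KeyError):
    pass


class MedicationClassTable:
    def __init__(self, members: dict[str, list[str]]):
        self._members = {_key(k): v for k, v in members.items()}

    @classmethod
    def load(cls, path: str | Path | None = None) -> "MedicationClassTable":
        p = Path(path) if path is not None else _data("medication_classes.csv")
        members: dict[str, list[str]] = {}
        with open(p, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                members.setdefault(row["class"], []).append(row["drug"])
        return cls(members)

    def members(self, class_concept: str) -> list[str]:
        hit = self._members.get(_key(class_concept))
        if hit is None:
            raise ClassNotFound(f"unknown medication class {class_concept!r}")
        return list(hit)


def expand_medication_class(
    class_concept: str,
    classes: MedicationClassTable | None = None,
    code_map: CodeMap | None = None,
) -> list[tuple[str, str]]:
    """Member drugs of a medication class with their RxNorm codes."""
    classes = classes or MedicationClassTable.load()
    code_map = code_map or CodeMap.load()
    out = []
    for drug in classes.members(class_concept):
        try:
            code = code_map.lookup(drug, "RxNorm")
        except KeyError:
            code = None
        out.append((drug, code))
    return out


# -------------------------------------------------------------- evaluation


_WINDOW_RE = re.compile(r"within\s*(\d+)\s*(day|week|month|year)s?")

_WINDOW_DAYS = {"day": 1, "week": 7, "month": 30, "year": 365}


def window_to_days(window: str) -> int | None:
    m = _WINDOW_RE.search(window.lower())
    if not m:
        return None
    return int(m.group(1)) * _WINDOW_DAYS[m.group(2)]


def _icd_matches(patient_code: str, pattern: str) -> bool:
    """ICD pattern match: character classes (ICD-9 style) are honored,
    plain codes match as prefixes at a dot or code boundary."""
    pc = patient_code.upper().strip()
    pat = pattern.upper().strip()
    if "[" in pat:
        # escape regex metacharacters outside character classes, keep the
        # classes themselves (incl. ranges) intact
        out: list[str] = []
        in_class = False
        for ch in pat:
            if ch == "[":
                in_class = True
                out.append(ch)
            elif ch == "]":
                in_class = False
                out.append(ch)
            elif in_class:
                out.append(ch)
            else:
                out.append(re.escape(ch))
        return re.fullmatch("".join(out), pc) is not None
    return pc == pat or pc.startswith(pat + ".") or (pc.startswith(pat) and "." in pat)


def _stage_group(stage: str) -> str:
    m = re.match(r"([IVX]+)", stage.upper().strip())
    return m.group(1) if m else stage.upper().strip()


class MatchConfigError(ValueError):
    pass


class CriterionMatcher:
    """Evaluates predicates against patients using the bundled code maps."""

    def __init__(
        self,
        lab_references: list[LabReference] | None = None,
        code_map: CodeMap | None = None,
        classes: MedicationClassTable | None = None,
    ):
        self.lab_references = lab_references or load_lab_references()
        self.code_map = code_map or CodeMap.load()
        self.classes = classes or MedicationClassTable.load()

    # -- helpers

    def _compare(self, value: float, predicate: CriterionPredicate) -> bool:
        t = predicate.threshold
        return {
            "≤": value <= t,
            "≥": value >= t,
            "<": value < t,
            ">": value > t,
            "=": value == t,
        }[predicate.comparator]

    def _recent_lab(
        self, patient: PatientRecord, analyte: str, predicate: CriterionPredicate, index_date: date
    ) -> LabResult | None:
        earliest = None
        if predicate.temporal_window:
            days = window_to_days(predicate.temporal_window)
            if days is not None:
                earliest = index_date - timedelta(days=days)
        target = _key(normalize_term(analyte).canonical_name)
        hits = [
            lab
            for lab in patient.labs
            if _key(normalize_term(lab.local_name).canonical_name) == target
            and lab.date <= index_date
            and (earliest is None or lab.date >= earliest)
        ]
        return max(hits, key=lambda lab: lab.date) if hits else None

    def _in_window(self, when: date, predicate: CriterionPredicate, index_date: date) -> bool:
        if when > index_date:
            return False
        if predicate.temporal_window:
            days = window_to_days(predicate.temporal_window)
            if days is not None:
                return when >= index_date - timedelta(days=days)
        return True

    # -- per-group positive checks: does the asserted condition hold?

    def _positive_verdict(
        self, patient: PatientRecord, p: CriterionPredicate, index_date: date, evidence: list[str]
    ) -> str:
        group = p.eav.entity_group
        attr = p.eav.attribute_name
        if group == "demographic":
            if _key(attr) == "age":
                if p.comparator is None:
                    return UNKNOWN
                evidence.append(f"age={patient.age:g}")
                return MATCH if self._compare(patient.age, p) else NO_MATCH
            # gender / sex criterion
            if not patient.sex or patient.sex == "unknown":
                return UNKNOWN
            evidence.append(f"sex={patient.sex}")
            wanted = [_key(c) for c in p.categories] or [_key(p.eav.value)]
            return MATCH if _key(patient.sex) in wanted else NO_MATCH
        if group == "laboratory_test":
            lab = self._recent_lab(patient, attr, p, index_date)
            if lab is None or p.comparator is None:
                return UNKNOWN
            unit = (p.threshold_unit or "").strip()
            if unit in ("xULN", "xLLN"):
                ref, _rule = map_loinc(lab, self.lab_references)
                mult = to_uln(lab, ref, patient.sex) if unit == "xULN" else to_lln(lab, ref, patient.sex)
                evidence.append(f"{attr}={lab.value:g}{lab.unit} -> {mult:.3g}{unit}")
                return MATCH if self._compare(mult, p) else NO_MATCH
            if unit and not _compatible_units(lab.unit, unit):
                raise UnitError(f"lab {attr}: {lab.unit!r} vs criterion {unit!r}")
            evidence.append(f"{attr}={lab.value:g}{lab.unit}")
            return MATCH if self._compare(lab.value, p) else NO_MATCH
        if group == "vital":
            if patient.ecog is None:
                return UNKNOWN
            evidence.append(f"ecog={patient.ecog}")
            if p.comparator is not None:
                return MATCH if self._compare(patient.ecog, p) else NO_MATCH
            return MATCH if str(patient.ecog) in p.categories else NO_MATCH
        if group == "diagnosis":
            if _key(attr) == "histology":
                if not patient.histology:
                    return UNKNOWN
                evidence.append(f"histology={patient.histology}")
                wanted = [_key(c) for c in p.categories] or [_key(p.eav.value)]
                return MATCH if _key(patient.histology) in wanted else NO_MATCH
            if _key(attr) == "stage":
                if not patient.stage:
                    return UNKNOWN
                evidence.append(f"stage={patient.stage}")
                groups = [g.upper() for g in p.categories] or [p.eav.value.upper()]
                return MATCH if _stage_group(patient.stage) in groups else NO_MATCH
            return UNKNOWN
        if group == "comorbidity":
            try:
                patterns = self.code_map.lookup(attr, "ICD-10") + self.code_map.lookup(attr, "ICD-9")
            except KeyError as exc:
                raise MatchConfigError(str(exc)) from exc
            for code, when in patient.diagnoses:
                if self._in_window(when, p, index_date) and any(
                    _icd_matches(code, pat) for pat in patterns
                ):
                    evidence.append(f"diagnosis {code} matches {attr}")
                    return MATCH
            return NO_MATCH  # coded diagnoses: absence of code = absence
        if group in ("other_medication", "prior_therapy"):
            if group == "prior_therapy" and _key(attr) in ("priorlot", "lines", "priorlines", "lot"):
                if p.comparator is None:
                    return UNKNOWN
                evidence.append(f"prior_lines={patient.prior_lines}")
                return MATCH if self._compare(patient.prior_lines, p) else NO_MATCH
            codes: set[str] = set()
            try:
                for _drug, code in expand_medication_class(attr, self.classes, self.code_map):
                    if code:
                        codes.add(code)
            except ClassNotFound:
                try:
                    codes.add(self.code_map.lookup(attr, "RxNorm"))
                except KeyError as exc:
                    raise MatchConfigError(str(exc)) from exc
            for code, start, end in patient.medications:
                if code in codes and (start is None or start <= index_date):
                    if p.temporal_window:
                        days = window_to_days(p.temporal_window)
                        if days is not None and end is not None and end < index_date - timedelta(days=days):
                            continue
                    evidence.append(f"medication {code} matches {attr}")
                    return MATCH
            return NO_MATCH
        if group == "biomarker":
            for marker, status in patient.biomarkers:
                if _key(marker) == _key(attr):
                    evidence.append(f"biomarker {marker}={status}")
                    return MATCH if _key(status) in ("positive", "yes", "detected") else NO_MATCH
            return UNKNOWN  # untested biomarker
        if group == "procedure":
            for concept, when in patient.procedures:
                if _key(concept) == _key(attr) and self._in_window(when, p, index_date):
                    evidence.append(f"procedure {concept} on {when}")
                    return MATCH
            return NO_MATCH
        return UNKNOWN

    def _matches_exception(self, patient: PatientRecord, p: CriterionPredicate) -> bool:
        ex_keys = {_key(e) for e in p.exceptions}
        if not ex_keys:
            return False
        pool = (
            [c for c, _ in patient.diagnoses]
            + [c for c, _ in patient.procedures]
            + [patient.histology]
            + [m for m, _ in patient.biomarkers]
        )
        return any(_key(x) in ex_keys for x in pool if x)

    def evaluate(
        self, patient: PatientRecord, predicate: CriterionPredicate, index_date: date
    ) -> MatchResult:
        """Three-valued evaluation of one predicate for one patient.

        Exclusion-section (or negated) predicates disqualify on presence of
        the condition, unless an exception concept rescues the patient.
        Absent evidence yields ``unknown``.
        """
        evidence: list[str] = []
        raw = self._positive_verdict(patient, predicate, index_date, evidence)
        if predicate.excludes:
            if raw == MATCH:
                if self._matches_exception(patient, predicate):
                    evidence.append("exception applies")
                    verdict = MATCH
                else:
                    verdict = NO_MATCH
            elif raw == NO_MATCH:
                verdict = MATCH
            else:
                verdict = UNKNOWN
        else:
            verdict = raw
        return MatchResult(patient.patient_id, predicate.label, verdict, evidence)


def evaluate_criterion(
    patient: PatientRecord,
    predicate: CriterionPredicate,
    index_date: date,
    matcher: CriterionMatcher | None = None,
) -> MatchResult:
    return (matcher or _default_matcher()).evaluate(patient, predicate, index_date)


def run_funnel(
    cohort: list[PatientRecord],
    predicates: list[CriterionPredicate],
    index_date: date,
    policy: str = "conservative",
    matcher: CriterionMatcher | None = None,
) -> FunnelReport:
    """Sequential conjunctive eligibility funnel.

    ``policy='conservative'`` treats ``unknown`` as not eligible;
    ``policy='ignore_unknown'`` lets unknowns survive the step.  Counts are
    invariant to patient order, and the final count to predicate order.
    """
    if policy not in ("conservative", "ignore_unknown"):
        raise ValueError(f"unknown policy {policy!r}")
    matcher = matcher or _default_matcher()
    eligible = list(cohort)
    steps: list[FunnelStep] = []
    for p in predicates:
        verdicts = {MATCH: 0, NO_MATCH: 0, UNKNOWN: 0}
        survivors: list[PatientRecord] = []
        for patient in eligible:
            res = matcher.evaluate(patient, p, index_date)
            verdicts[res.verdict] += 1
            if res.verdict == MATCH or (res.verdict == UNKNOWN and policy == "ignore_unknown"):
                survivors.append(patient)
        steps.append(FunnelStep(p.label, len(eligible), len(survivors), verdicts))
        eligible = survivors
    return FunnelReport(steps, policy, index_date, len(cohort))


# ------------------------------------------------------------- cohort IO


def write_cohort(directory: str | Path, cohort: list[PatientRecord]) -> None:
    """Write a cohort as the documented CSV table set."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    def w(name: str, header: list[str], rows: list[list]) -> None:
        with open(d / name, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            writer.writerows(rows)

    w("patients.csv", ["patient_id", "age", "sex"], [[p.patient_id, f"{p.age:g}", p.sex] for p in cohort])
    w(
        "diagnoses.csv",
        ["patient_id", "icd_code", "date"],
        [[p.patient_id, c, dt.isoformat()] for p in cohort for c, dt in p.diagnoses],
    )
    w(
        "labs.csv",
        ["patient_id", "local_name", "value", "unit", "sample_type", "date"],
        [
            [p.patient_id, lab.local_name, f"{lab.value:g}", lab.unit, lab.sample_type or "", lab.date.isoformat()]
            for p in cohort
            for lab in p.labs
        ],
    )
    w(
        "medications.csv",
        ["patient_id", "rxnorm_code", "start_date", "end_date"],
        [
            [p.patient_id, c, s.isoformat() if s else "", e.isoformat() if e else ""]
            for p in cohort
            for c, s, e in p.medications
        ],
    )
    w(
        "vitals.csv",
        ["patient_id", "ecog", "prior_lines"],
        [[p.patient_id, "" if p.ecog is None else p.ecog, p.prior_lines] for p in cohort],
    )
    w(
        "staging.csv",
        ["patient_id", "histology", "stage", "biomarker", "status"],
        [
            [p.patient_id, p.histology, p.stage, m, s]
            for p in cohort
            for m, s in (p.biomarkers or [("", "")])
        ],
    )


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    d = Path(directory)

    def rows(name: str) -> list[dict]:
        path = d / name
        if not path.exists():
            return []
        with open(path, newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))

    patients: dict[str, PatientRecord] = {}
    for r in rows("patients.csv"):
        patients[r["patient_id"]] = PatientRecord(r["patient_id"], float(r["age"]), r["sex"] or "unknown")
    for r in rows("vitals.csv"):
        p = patients[r["patient_id"]]
        p.ecog = int(r["ecog"]) if r["ecog"] != "" else None
        p.prior_lines = int(r["prior_lines"] or 0)
    for r in rows("staging.csv"):
        p = patients[r["patient_id"]]
        p.histology = r["histology"]
        p.stage = r["stage"]
        if r["biomarker"]:
            p.biomarkers.append((r["biomarker"], r["status"]))
    for r in rows("diagnoses.csv"):
        patients[r["patient_id"]].diagnoses.append((r["icd_code"], date.fromisoformat(r["date"])))
    for r in rows("labs.csv"):
        patients[r["patient_id"]].labs.append(
            LabResult(
                r["local_name"],
                float(r["value"]),
                r["unit"],
                date.fromisoformat(r["date"]),
                r["sample_type"] or None,
            )
        )
    for r in rows("medications.csv"):
        patients[r["patient_id"]].medications.append(
            (
                r["rxnorm_code"],
                date.fromisoformat(r["start_date"]) if r["start_date"] else None,
                date.fromisoformat(r["end_date"]) if r["end_date"] else None,
            )
        )
    return list(patients.values())


def load_predicates(path: str | Path) -> list[CriterionPredicate]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [CriterionPredicate.from_dict(d) for d in data]


def save_predicates(predicates: list[CriterionPredicate], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([p.to_dict() for p in predicates], indent=1), encoding="utf-8"
    )


_MATCHER: CriterionMatcher | None = None


def _default_matcher() -> CriterionMatcher:
    global _MATCHER
    if _MATCHER is None:
        _MATCHER = CriterionMatcher()
    return _MATCHER
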