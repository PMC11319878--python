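"""Entity-Attribute-Value knowledge base construction and lookup tables.

Normalized, relation-linked annotations are folded into EAV records — one
per (primary mention, linked modifiers) — whose identity is the
``(entity_group, attribute_name, value, condition)`` quadruple.  Hypernym
concepts ("adequate organ function", "cardiovascular disease", ...) expand
into their hyponym/value lists; representative laboratory thresholds are
the modal value across trials; and ICD / LOINC / RxNorm code maps make the
records computable against coded patient data.
"""

from __future__ import annotations

import csv
import difflib
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .normalization import (
    ConceptDictionary,
    RuleSet,
    _key,
    normalize_temporal,
    normalize_term,
    parse_value_expression,
)
from .ontology import AnnotatedCriterion, Ontology, load_ontology


def _data(name: str) -> Path:
    return Path(str(resources.files("elikb").joinpath(f"data/{name}")))


# --------------------------------------------------------------------- EAV


@dataclass
class EAVRecord:
    entity_group: str
    attribute_name: str
    value: str
    condition: str = ""
    disease: str = ""
    section: str = "inclusion"
    source_trials: list[str] = field(default_factory=list)
    flagged: bool = False  # conflicting duplicate value links

    @property
    def identity(self) -> tuple[str, str, str, str]:
        return (self.entity_group, self.attribute_name, self.value, self.condition)


_VALUE_LIKE = {"value", "lines_of_therapy", "dose", "grade"}
_CONDITION_LIKE = {"temporal", "condition", "exception", "evidence"}


def build_eav(
    criteria: list[AnnotatedCriterion],
    disease: str,
    ontology: Ontology | None = None,
    rules: RuleSet | None = None,
    dictionary: ConceptDictionary | None = None,
) -> list[EAVRecord]:
    """Fold annotated+linked criteria into merged EAV records.

    Primary mentions with a linked value modifier take that normalized
    value; primaries without one are presence assertions (``yes``, or
    ``no`` under a linked negation).  Temporal/condition/exception
    modifiers land in the condition field.  Duplicate identities merge
    with unioned source trials; a primary with two conflicting value links
    yields both records flagged.
    """
    ontology = ontology or load_ontology()
    records: dict[tuple, EAVRecord] = {}
    for crit in criteria:
        by_id = {m.mention_id: m for m in crit.mentions}
        links: dict[str, list] = {}
        for rel in crit.relations:
            links.setdefault(rel.source, []).append(rel)
        for m in crit.mentions:
            g = ontology.group(m.group)
            if g is None or g.category != "primary":
                continue
            attr = normalize_term(m.surface, rules, dictionary).canonical_name
            values: list[str] = []
            conditions: list[str] = []
            negated = False
            for rel in links.get(m.mention_id, []):
                tgt = by_id.get(rel.target)
                if tgt is None:
                    continue
                tg = ontology.group(tgt.group)
                if tg is None:
                    continue
                if tgt.group == "negation":
                    negated = True
                elif tgt.group in _VALUE_LIKE:
                    values.append(_normalize_value_text(tgt.surface, rules))
                elif tgt.group in _CONDITION_LIKE:
                    win, ok = normalize_temporal(tgt.surface, rules)
                    conditions.append(win if ok else tgt.surface)
            condition = "; ".join(conditions)
            if not values:
                values = ["no" if negated else "yes"]
            flagged = len(set(values)) > 1
            for val in values:
                rec_key = (m.group, attr, val, condition, disease, crit.section)
                rec = records.get(rec_key)
                if rec is None:
                    rec = EAVRecord(
                        m.group, attr, val, condition, disease, crit.section, [], flagged
                    )
                    records[rec_key] = rec
                rec.flagged = rec.flagged or flagged
                if crit.trial_id not in rec.source_trials:
                    rec.source_trials.append(crit.trial_id)
    return list(records.values())


def _normalize_value_text(surface: str, rules: RuleSet | None) -> str:
    comparator, value, unit = parse_value_expression(surface, rules)
    if value is None:
        return surface.strip()
    num = f"{value:g}"
    parts = [comparator or "", num, unit or ""]
    return " ".join(p for p in parts if p)


def count_unique_eav(records: list[EAVRecord]) -> int:
    """Number of unique EAV identities; order- and duplication-invariant."""
    return len({r.identity for r in records})


def write_eav_tsv(records: list[EAVRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "entity_group\tattribute_name\tvalue\tcondition\tdisease\tsection\tsource_trials\n"
        )
        for r in sorted(records, key=lambda r: (r.entity_group, r.attribute_name, r.value)):
            fh.write(
                f"{r.entity_group}\t{r.attribute_name}\t{r.value}\t{r.condition}\t"
                f"{r.disease}\t{r.section}\t{';'.join(r.source_trials)}\n"
            )


# --------------------------------------------------------- hypernym tables


class HypernymNotFound(KeyError):
    def __init__(self, name: str, suggestions: list[str]):
        self.suggestions = suggestions
        hint = f"; nearest: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"unknown hypernym {name!r}{hint}")


@dataclass
class HypernymExpansion:
    hypernym: str
    subgroup: str | None
    hyponyms: list[tuple[str, str]]  # (concept, value)
    exceptions: dict[str, list[str]] = field(default_factory=dict)


class HypernymTable:
    """The hypernym -> (subgroup ->) hyponym/value expansion tables."""

    def __init__(self, rows: list[dict]):
        self.rows = rows
        self._names: set[str] = set()
        for r in rows:
            self._names.add(r["hypernym"])
            if r["subgroup"]:
                self._names.add(r["subgroup"])

    @classmethod
    def load(cls, path: str | Path | None = None) -> "HypernymTable":
        p = Path(path) if path is not None else _data("hypernym_expansions.csv")
        with open(p, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls(rows)

    def expand(self, name: str) -> HypernymExpansion:
        """Full hyponym/value list for a hypernym or subgroup concept."""
        key = _key(name)
        as_top = [r for r in self.rows if _key(r["hypernym"]) == key]
        as_sub = [r for r in self.rows if _key(r["subgroup"]) == key]
        if as_top:
            rows, hypernym, subgroup = as_top, as_top[0]["hypernym"], None
        elif as_sub:
            rows, hypernym, subgroup = as_sub, as_sub[0]["hypernym"], as_sub[0]["subgroup"]
        else:
            suggestions = difflib.get_close_matches(name, sorted(self._names), n=3, cutoff=0.5)
            raise HypernymNotFound(name, suggestions)
        exceptions = {
            r["hyponym"]: r["exceptions"].split(";")
            for r in rows
            if r.get("exceptions")
        }
        return HypernymExpansion(
            hypernym, subgroup, [(r["hyponym"], r["value"]) for r in rows], exceptions
        )

    def reverse_lookup(self, hyponym: str) -> tuple[str, str]:
        """Map a hyponym back to its unique (hypernym, subgroup)."""
        key = _key(hyponym)
        hits = [r for r in self.rows if _key(r["hyponym"]) == key]
        if not hits:
            raise HypernymNotFound(hyponym, [])
        if len({(r["hypernym"], r["subgroup"]) for r in hits}) > 1:
            raise ValueError(f"hyponym {hyponym!r} maps to multiple hypernyms")
        return hits[0]["hypernym"], hits[0]["subgroup"]


def expand_hypernym(name: str, table: HypernymTable | None = None) -> HypernymExpansion:
    return (table or _default_hypernyms()).expand(name)


# ----------------------------------------------------- representative values


class NoDataError(ValueError):
    """No trial values were supplied for the analyte."""


@dataclass
class PrevalentValue:
    value: float
    unit: str
    histogram: dict[float, int]  # value -> number of contributing trials
    tied: bool = False


# lower-bound thresholds (counts, concentrations, clearance): larger is
# stricter; upper-bound multiples of ULN: smaller is stricter.
_LOWER_BOUND_UNITS = {"cells/ul", "g/dl", "mg/dl", "ng/dl", "ml/min", "10^3/ul"}


def prevalent_value(
    lab_test: str, trial_values: list[tuple[float, str, str]]
) -> PrevalentValue:
    """Modal threshold for an analyte across trials, with its histogram.

    ``trial_values`` is a multiset of ``(value, unit, trial_id)`` already on
    a common unit.  Ties break toward the stricter threshold — the smaller
    multiple-of-ULN, or the larger cell-count/concentration bound — and are
    reported via ``tied``.
    """
    if not trial_values:
        raise NoDataError(f"no trial values for {lab_test!r}")
    units = {u for _, u, _ in trial_values}
    if len(units) > 1:
        raise ValueError(f"values for {lab_test!r} mix units {sorted(units)}")
    unit = next(iter(units))
    hist = Counter()
    for value, _, _trial in trial_values:
        hist[value] += 1
    top = max(hist.values())
    modes = sorted(v for v, c in hist.items() if c == top)
    stricter_is_larger = unit.lower() in _LOWER_BOUND_UNITS
    pick = modes[-1] if stricter_is_larger else modes[0]
    return PrevalentValue(pick, unit, dict(sorted(hist.items())), tied=len(modes) > 1)


def representative_value(analyte: str, path: str | Path | None = None) -> PrevalentValue:
    """Prevalent value of an analyte from the bundled default histograms.

    The bundled histograms are synthetic defaults shaped like published
    trial-count distributions (mode at the field-typical threshold); swap in
    your own table for a real corpus.
    """
    p = Path(path) if path is not None else _data("lab_value_histograms.csv")
    values: list[tuple[float, str, str]] = []
    with open(p, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            if _key(row["analyte"]) != _key(analyte):
                continue
            for k in range(int(row["trial_count"])):
                values.append((float(row["value"]), row["unit"], f"t{i}_{k}"))
    return prevalent_value(analyte, values)


# ----------------------------------------------------------------- code maps


class CodeNotFound(KeyError):
    def __init__(self, concept: str, system: str, suggestions: list[str]):
        self.suggestions = suggestions
        hint = f"; nearest: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"no {system} codes for {concept!r}{hint}")


@dataclass
class LoincEntry:
    code: str
    unit: str
    low: dict[str, float | None]  # sex -> lower limit of normal
    high: dict[str, float | None]  # sex -> upper limit of normal


class CodeMap:
    """Bundled ICD-9/10, LOINC (+ normal ranges) and RxNorm code tables."""

    def __init__(
        self,
        icd: dict[str, dict[str, list[str]]],
        loinc: dict[str, LoincEntry],
        rxnorm: dict[str, str],
    ):
        self._icd = icd
        self._loinc = loinc
        self._rxnorm = rxnorm

    @classmethod
    def load(
        cls,
        icd_path: str | Path | None = None,
        loinc_path: str | Path | None = None,
        rxnorm_path: str | Path | None = None,
    ) -> "CodeMap":
        icd: dict[str, dict[str, list[str]]] = {}
        with open(Path(icd_path) if icd_path else _data("icd_codes.csv"), newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                icd[_key(row["concept"])] = {
                    "ICD-10": row["icd10"].split(";"),
                    "ICD-9": row["icd9"].split(";"),
                }
        loinc: dict[str, LoincEntry] = {}
        with open(Path(loinc_path) if loinc_path else _data("loinc_references.csv"), newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                def num(x):
                    return float(x) if x not in ("", None) else None

                entry = LoincEntry(
                    row["loinc"],
                    row["unit"],
                    {"male": num(row["low_male"]), "female": num(row["low_female"])},
                    {"male": num(row["high_male"]), "female": num(row["high_female"])},
                )
                for sex in ("male", "female"):
                    lo, hi = entry.low[sex], entry.high[sex]
                    if lo is not None and hi is not None and not lo < hi:
                        raise ValueError(f"{row['concept']}: normal range low >= high")
                loinc[_key(row["concept"])] = entry
        rxnorm: dict[str, str] = {}
        with open(Path(rxnorm_path) if rxnorm_path else _data("rxnorm_codes.csv"), newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                rxnorm[_key(row["drug"])] = row["code"]
        return cls(icd, loinc, rxnorm)

    def lookup(self, concept: str, system: str):
        """Codes for a normalized concept in one coding system.

        For LOINC the :class:`LoincEntry` (code plus normal range) is
        returned; for ICD systems a list of code patterns; for RxNorm the
        code string.
        """
        key = _key(concept)
        if system in ("ICD-10", "ICD-9"):
            table, universe = self._icd, self._icd.keys()
            if key in table:
                return table[key][system]
        elif system == "LOINC":
            universe = self._loinc.keys()
            hit = self._loinc.get(key)
            if hit is None:  # try the synonym rules (e.g. SGPT -> ALT)
                hit = self._loinc.get(_key(normalize_term(concept).canonical_name))
            if hit is not None:
                return hit
        elif system == "RxNorm":
            universe = self._rxnorm.keys()
            if key in self._rxnorm:
                return self._rxnorm[key]
        else:
            raise ValueError(f"unknown coding system {system!r}")
        suggestions = difflib.get_close_matches(key, sorted(universe), n=3, cutoff=0.5)
        raise CodeNotFound(concept, system, suggestions)


def lookup_codes(concept: str, system: str, code_map: CodeMap | None = None):
    return (code_map or _default_codes()).lookup(concept, system)


_DEFAULT_HYPERNYMS: HypernymTable | None = None
_DEFAULT_CODES: CodeMap | None = None


def _default_hypernyms() -> HypernymTable:
    global _DEFAULT_HYPERNYMS
    if _DEFAULT_HYPERNYMS is None:
        _DEFAULT_HYPERNYMS = HypernymTable.load()
    return _DEFAULT_HYPERNYMS


def _default_codes() -> CodeMap:
    global _DEFAULT_CODES
    if _DEFAULT_CODES is None:
        _DEFAULT_CODES = CodeMap.load()
    return _DEFAULT_CODES
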