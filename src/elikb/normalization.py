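"""Attribute normalization: dictionary (CUI) mapping, rule engine, curation.

Normalization is a 3-step cascade:

1. concept-dictionary lookup assigning a canonical concept and its concept
   unique identifier (CUI) — a small curated bundle ships with the package
   and a full terminology can be dropped in;
2. the rule engine: synonym, comparator, temporal and unit rules plus the
   miscellaneous rules (case-insensitive matching, whitespace stripping)
   that apply to every pattern;
3. manual-curation overrides (a two-column surface,canonical CSV) that win
   over rule output.

Surfaces no step resolves pass through flagged ``uncurated``.  The full
pipeline is idempotent, and every output carries exactly one provenance
label (``dictionary`` | ``rule`` | ``curation`` | ``uncurated``).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

COMPARATORS = ("≤", "≥", "<", ">", "=")

_NUMBER_WORDS = {
    w: i + 1
    for i, w in enumerate(
        "one two three four five six seven eight nine ten eleven twelve".split()
    )
}


def _key(surface: str) -> str:
    """Apply the miscellaneous rules: case-fold and remove all whitespace."""
    return re.sub(r"\s+", "", surface).casefold()


@dataclass(frozen=True)
class NormalizationRule:
    rule_class: str  # synonym | comparator | temporal | unit | misc
    canonical: str
    patterns: tuple[str, ...]


class RuleSet:
    """The normalization-rule table, indexed per rule class."""

    def __init__(self, rules: list[NormalizationRule]):
        self.rules = rules
        self._by_class: dict[str, dict[str, str]] = {}
        for r in rules:
            table = self._by_class.setdefault(r.rule_class, {})
            for pat in r.patterns:
                table.setdefault(_key(pat), r.canonical)  # first (table order) wins

    def lookup(self, rule_class: str, surface: str) -> str | None:
        return self._by_class.get(rule_class, {}).get(_key(surface))


def load_rules(path: str | Path | None = None) -> RuleSet:
    p = (
        Path(path)
        if path is not None
        else Path(str(resources.files("elikb").joinpath("data/normalization_rules.tsv")))
    )
    rules: list[NormalizationRule] = []
    for raw in p.read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        rule_class, canonical, *rest = raw.split("\t")
        patterns = tuple(rest[0].split("|")) if rest else ()
        rules.append(NormalizationRule(rule_class, canonical, patterns))
    return RuleSet(rules)


class ConceptDictionary:
    """Surface form -> (canonical concept, CUI), case/space-insensitive."""

    def __init__(self, entries: dict[str, tuple[str, str]] | None = None):
        self._entries: dict[str, tuple[str, str]] = {}
        for surface, (canonical, cui) in (entries or {}).items():
            self.add(surface, canonical, cui)

    def add(self, surface: str, canonical: str, cui: str) -> None:
        self._entries[_key(surface)] = (canonical, cui)

    def lookup(self, surface: str) -> tuple[str, str] | None:
        return self._entries.get(_key(surface))

    def __len__(self) -> int:
        return len(self._entries)


def load_concept_dictionary(path: str | Path | None = None) -> ConceptDictionary:
    p = (
        Path(path)
        if path is not None
        else Path(str(resources.files("elikb").joinpath("data/concept_dictionary.csv")))
    )
    d = ConceptDictionary()
    with open(p, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            d.add(row["surface"], row["canonical"], row["cui"])
    return d


@dataclass
class NormalizedAttribute:
    surface: str
    canonical_name: str
    cui: str | None = None
    comparator: str | None = None
    value: float | None = None
    unit: str | None = None
    temporal: str | None = None
    provenance: str = "uncurated"  # dictionary | rule | curation | uncurated

    def __post_init__(self) -> None:
        if self.comparator is not None and self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")

    @property
    def uncurated(self) -> bool:
        return self.provenance == "uncurated"


def normalize_term(
    surface: str,
    rules: RuleSet | None = None,
    dictionary: ConceptDictionary | None = None,
) -> NormalizedAttribute:
    """Map a surface form to its canonical attribute name.

    Dictionary hits carry the CUI; otherwise the longest-matching synonym
    rule applies; unresolved surfaces pass through flagged ``uncurated``.
    Idempotent: canonicals map to themselves.
    """
    rules = rules if rules is not None else _default_rules()
    dictionary = dictionary if dictionary is not None else _default_dictionary()
    stripped = surface.strip()
    hit = dictionary.lookup(stripped)
    if hit is not None:
        canonical, cui = hit
        return NormalizedAttribute(stripped, canonical, cui=cui, provenance="dictionary")
    canonical = rules.lookup("synonym", stripped)
    if canonical is not None:
        return NormalizedAttribute(stripped, canonical, provenance="rule")
    return NormalizedAttribute(stripped, stripped, provenance="uncurated")


def normalize_comparator(surface: str, rules: RuleSet | None = None) -> str | None:
    """Canonicalize a comparator phrase; ``None`` signals no comparator."""
    rules = rules if rules is not None else _default_rules()
    return rules.lookup("comparator", surface)


_TEMPORAL_RE = re.compile(
    r"^(?:within|last|past|inthelast|inthepast)"
    r"(\d+|" + "|".join(_NUMBER_WORDS) + r")"
    r"(day|week|month|year)s?$"
)


def normalize_temporal(surface: str, rules: RuleSet | None = None) -> tuple[str, bool]:
    """Canonicalize a temporal window; returns ``(window, resolved)``.

    Table patterns apply first; other ``within/last/past N unit`` phrases
    collapse to a canonical ``within N unit`` form (day counts divisible by
    7 become weeks) so windows stay machine-comparable.  Unmatched surfaces
    pass through with ``resolved=False``.
    """
    rules = rules if rules is not None else _default_rules()
    hit = rules.lookup("temporal", surface)
    if hit is not None:
        return hit, True
    m = _TEMPORAL_RE.match(_key(surface))
    if m:
        num_s, unit = m.groups()
        n = _NUMBER_WORDS.get(num_s, None) if not num_s.isdigit() else int(num_s)
        if n is not None:
            if unit == "day" and n % 7 == 0:
                n, unit = n // 7, "week"
            plural = "s" if n != 1 else ""
            return f"within {n} {unit}{plural}", True
    return surface.strip(), False


def normalize_unit(surface: str, rules: RuleSet | None = None) -> tuple[str, bool]:
    """Canonicalize a unit spelling; returns ``(unit, resolved)``."""
    rules = rules if rules is not None else _default_rules()
    hit = rules.lookup("unit", surface)
    if hit is not None:
        return hit, True
    return surface.strip(), False


_VALUE_RE = re.compile(
    r"^\s*(?P<cmp>≤|≥|<|>|=|less than or equal to|greater than or equal to|"
    r"less than|greater than)?\s*"
    r"(?P<num>\d[\d,]*(?:\.\d+)?)\s*(?P<unit>.*)$",
    re.IGNORECASE,
)


def parse_value_expression(
    text: str, rules: RuleSet | None = None
) -> tuple[str | None, float | None, str | None]:
    """Split a value phrase like ``≤2.5x ULN`` into (comparator, value, unit).

    Multiplier-of-normal-limit units are canonicalized to ``xULN``/``xLLN``;
    other units go through the unit rules.  Returns ``(None, None, None)``
    when no leading number is found.
    """
    rules = rules if rules is not None else _default_rules()
    m = _VALUE_RE.match(text)
    if not m or not m.group("num"):
        return None, None, None
    cmp_raw = m.group("cmp")
    comparator = normalize_comparator(cmp_raw, rules) if cmp_raw else None
    if cmp_raw and comparator is None and cmp_raw in COMPARATORS:
        comparator = cmp_raw
    value = float(m.group("num").replace(",", ""))
    unit_raw = m.group("unit").strip()
    unit: str | None
    if not unit_raw:
        unit = None
    else:
        k = _key(unit_raw)
        if re.fullmatch(r"[x×]?uln", k):
            unit = "xULN"
        elif re.fullmatch(r"[x×]?lln", k):
            unit = "xLLN"
        else:
            unit, _ = normalize_unit(unit_raw, rules)
    return comparator, value, unit


class CurationOverrides:
    """Manual-curation table: flagged surface -> canonical."""

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map = {_key(k): v for k, v in (mapping or {}).items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "CurationOverrides":
        mapping: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#") or row[0] == "surface":
                    continue
                mapping[row[0]] = row[1]
        return cls(mapping)

    def lookup(self, surface: str) -> str | None:
        return self._map.get(_key(surface))

    def __len__(self) -> int:
        return len(self._map)


def apply_curation(
    attrs: list[NormalizedAttribute], overrides: CurationOverrides
) -> list[NormalizedAttribute]:
    """Apply manual-curation overrides; overrides win over rule output.

    Overriding a surface that a rule already resolved emits a warning but is
    applied (the curators outrank the rules).
    """
    out: list[NormalizedAttribute] = []
    for attr in attrs:
        target = overrides.lookup(attr.surface)
        if target is None:
            out.append(attr)
            continue
        if not attr.uncurated:
            warnings.warn(
                f"curation override for {attr.surface!r} conflicts with "
                f"{attr.provenance} result {attr.canonical_name!r}; override applied",
                stacklevel=2,
            )
        out.append(
            NormalizedAttribute(
                attr.surface,
                target,
                cui=attr.cui,
                comparator=attr.comparator,
                value=attr.value,
                unit=attr.unit,
                temporal=attr.temporal,
                provenance="curation",
            )
        )
    return out


_DEFAULT_RULES: RuleSet | None = None
_DEFAULT_DICT: ConceptDictionary | None = None


def _default_rules() -> RuleSet:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def _default_dictionary() -> ConceptDictionary:
    global _DEFAULT_DICT
    if _DEFAULT_DICT is None:
        _DEFAULT_DICT = load_concept_dictionary()
    return _DEFAULT_DICT
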