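"""Eligibility-criteria entity/relation schema and annotation data model.

The schema distinguishes *primary* entity groups (the clinical subject of a
criterion: a laboratory test, a comorbidity, a prior therapy, ...) from
*modifier* groups that constrain them (a value limit, a time window, a
negation cue, ...).  Relations run from a primary mention to a modifier
mention, with the single exception of ``has_outcome`` which connects two
primary mentions (e.g. a prior therapy and the disease status it produced).
Anything that fits no primary group is labelled ``other_observation``.

The bundled schema ships 10 primary groups, 9 modifier groups and 1 other
group, and 10 relation types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


class SchemaError(ValueError):
    """Raised when an ontology file violates the schema dialect."""


@dataclass(frozen=True)
class EntityGroup:
    name: str
    category: str  # primary | modifier | other
    description: str = ""

    _CATEGORIES = ("primary", "modifier", "other")

    def __post_init__(self) -> None:
        if self.category not in self._CATEGORIES:
            raise SchemaError(f"unknown category {self.category!r} for group {self.name!r}")


@dataclass(frozen=True)
class RelationType:
    name: str
    source_category: str
    target_category: str


@dataclass
class EntityMention:
    """A typed entity span. Offsets are 0-based, half-open characters."""

    mention_id: str
    start: int
    end: int
    surface: str
    group: str
    attribute: str = ""

    @property
    def label(self) -> str:
        """The ``group::attribute`` label used for tagging and scoring."""
        return f"{self.group}::{self.attribute}" if self.attribute else self.group


@dataclass
class RelationMention:
    relation: str
    source: str  # mention_id of the source (primary) mention
    target: str  # mention_id of the target mention


@dataclass
class AnnotatedCriterion:
    """One eligibility-criterion sentence with gold or predicted annotations."""

    trial_id: str
    section: str  # inclusion | exclusion
    text: str
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[RelationMention] = field(default_factory=list)

    def mention_by_id(self, mention_id: str) -> EntityMention | None:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        return None


class Ontology:
    """A validated set of entity groups and relation types."""

    def __init__(self, groups: list[EntityGroup], relations: list[RelationType]):
        self._groups: dict[str, EntityGroup] = {}
        for g in groups:
            key = g.name.lower()
            if key in self._groups:
                raise SchemaError(f"duplicate group name {g.name!r}")
            self._groups[key] = g
        self._relations: dict[str, RelationType] = {}
        valid_cats = {g.category for g in groups}
        for r in relations:
            if r.name.lower() in self._relations:
                raise SchemaError(f"duplicate relation name {r.name!r}")
            for cat in (r.source_category, r.target_category):
                if cat not in valid_cats:
                    raise SchemaError(
                        f"relation {r.name!r} references unknown category {cat!r}"
                    )
            self._relations[r.name.lower()] = r
        if not self._groups:
            raise SchemaError("ontology defines no entity groups")

    @property
    def groups(self) -> list[EntityGroup]:
        return list(self._groups.values())

    @property
    def relations(self) -> list[RelationType]:
        return list(self._relations.values())

    def group(self, name: str) -> EntityGroup | None:
        return self._groups.get(name.lower())

    def relation(self, name: str) -> RelationType | None:
        return self._relations.get(name.lower())

    def groups_in(self, category: str) -> list[EntityGroup]:
        return [g for g in self._groups.values() if g.category == category]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self._groups.values():
            counts[g.category] = counts.get(g.category, 0) + 1
        return counts


def _default_path() -> Path:
    return Path(str(resources.files("elikb").joinpath("data/ontology.tsv")))


def load_ontology(path: str | Path | None = None) -> Ontology:
    """Load an ontology file (or the bundled default).

    Dialect: tab-separated lines; ``group<TAB>name<TAB>category<TAB>descr``
    and ``relation<TAB>name<TAB>source_category<TAB>target_category``.
    Lines starting with ``#`` and blank lines are ignored.
    """
    p = Path(path) if path is not None else _default_path()
    groups: list[EntityGroup] = []
    relations: list[RelationType] = []
    for lineno, raw in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "group":
            if len(fields) < 3:
                raise SchemaError(f"line {lineno}: group record needs name and category")
            groups.append(EntityGroup(fields[1], fields[2], fields[3] if len(fields) > 3 else ""))
        elif kind == "relation":
            if len(fields) < 4:
                raise SchemaError(f"line {lineno}: relation record needs 3 fields")
            relations.append(RelationType(fields[1], fields[2], fields[3]))
        else:
            raise SchemaError(f"line {lineno}: unknown record kind {kind!r}")
    return Ontology(groups, relations)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_annotation(criterion: AnnotatedCriterion, ontology: Ontology) -> ValidationReport:
    """Check an annotated criterion against the schema.

    Violations are data, not exceptions: the report lists every problem found
    (unknown groups/relations, spans outside the text, surface/slice
    mismatches, duplicate ids, overlapping mentions — flat tagging only —
    dangling relation arguments and category constraint breaches).
    The input is never mutated.
    """
    v: list[str] = []
    seen_ids: set[str] = set()
    text = criterion.text
    for m in criterion.mentions:
        if m.mention_id in seen_ids:
            v.append(f"duplicate mention id {m.mention_id}")
        seen_ids.add(m.mention_id)
        if not (0 <= m.start < m.end):
            v.append(f"{m.mention_id}: invalid span [{m.start},{m.end})")
        elif m.end > len(text):
            v.append(f"{m.mention_id}: span [{m.start},{m.end}) exceeds text length {len(text)}")
        elif text[m.start:m.end] != m.surface:
            v.append(
                f"{m.mention_id}: surface {m.surface!r} != text slice "
                f"{text[m.start:m.end]!r}"
            )
        if ontology.group(m.group) is None:
            v.append(f"{m.mention_id}: unknown group {m.group!r}")
    ordered = sorted(
        (m for m in criterion.mentions if 0 <= m.start < m.end),
        key=lambda m: (m.start, m.end),
    )
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            v.append(f"overlapping mentions {a.mention_id} and {b.mention_id}")
    by_id = {m.mention_id: m for m in criterion.mentions}
    for r in criterion.relations:
        rt = ontology.relation(r.relation)
        if rt is None:
            v.append(f"unknown relation type {r.relation!r}")
            continue
        src = by_id.get(r.source)
        tgt = by_id.get(r.target)
        if src is None:
            v.append(f"{r.relation}: dangling source {r.source}")
        if tgt is None:
            v.append(f"{r.relation}: dangling target {r.target}")
        if src is not None and (g := ontology.group(src.group)) is not None:
            if g.category != rt.source_category:
                v.append(
                    f"{r.relation}: source {r.source} is {g.category}, "
                    f"requires {rt.source_category}"
                )
        if tgt is not None and (g := ontology.group(tgt.group)) is not None:
            if g.category != rt.target_category:
                v.append(
                    f"{r.relation}: target {r.target} is {g.category}, "
                    f"requires {rt.target_category}"
                )
    return ValidationReport(v)
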