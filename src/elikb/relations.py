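"""Rule-based relation linking between primary and modifier mentions.

Each modifier mention is linked to the nearest preceding compatible primary
mention in the sentence (falling back to the nearest following one), and the
relation name is determined by the modifier's group.  Modifiers with no
primary mention in the sentence are reported as unlinked.  Purely
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ontology import AnnotatedCriterion, EntityMention, Ontology, RelationMention

# modifier group -> relation name (the primary->modifier edge inventory)
MODIFIER_RELATION: dict[str, str] = {
    "value": "has_value_limit",
    "temporal": "has_temporal_limit",
    "negation": "has_negation",
    "exception": "has_exception",
    "dose": "has_dose_limit",
    "lines_of_therapy": "has_line_of_therapy_limit",
    "grade": "has_grade_limit",
    "condition": "has_condition",
    "evidence": "need_evidence",
}


@dataclass
class LinkResult:
    relations: list[RelationMention] = field(default_factory=list)
    unlinked: list[str] = field(default_factory=list)  # modifier mention ids


def link_relations(criterion: AnnotatedCriterion, ontology: Ontology) -> LinkResult:
    """Attach every modifier mention to its nearest compatible primary."""
    primaries: list[EntityMention] = []
    modifiers: list[EntityMention] = []
    for m in sorted(criterion.mentions, key=lambda m: m.start):
        g = ontology.group(m.group)
        if g is None:
            continue
        if g.category == "primary":
            primaries.append(m)
        elif g.category == "modifier":
            modifiers.append(m)
    result = LinkResult()
    for mod in modifiers:
        relname = MODIFIER_RELATION.get(mod.group)
        if relname is None:
            result.unlinked.append(mod.mention_id)
            continue
        preceding = [p for p in primaries if p.end <= mod.start]
        following = [p for p in primaries if p.start >= mod.end]
        if preceding:
            src = min(preceding, key=lambda p: mod.start - p.end)
        elif following:
            src = min(following, key=lambda p: p.start - mod.end)
        else:
            result.unlinked.append(mod.mention_id)
            continue
        result.relations.append(RelationMention(relname, src.mention_id, mod.mention_id))
    return result
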