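"""Standoff (BRAT-style) persistence for annotated criteria.

Entity lines: ``Tn<TAB>group::attribute start end<TAB>surface``
Relation lines: ``Rn<TAB>relname Arg1:Tx Arg2:Ty``

Offsets are 0-based half-open character offsets into the ``.txt`` content.
``write_standoff`` emits entities sorted by span and relations in input
order, so read∘write and write∘read are identities modulo line order.
"""

from __future__ import annotations

import re
from pathlib import Path

from .ontology import AnnotatedCriterion, EntityMention, RelationMention


class StandoffParseError(ValueError):
    """Raised on malformed standoff lines, bad offsets or dangling arguments."""


_ENT_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_REL_RE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)\s*$")


def read_standoff(
    txt: str, ann: str, trial_id: str = "", section: str = "inclusion"
) -> AnnotatedCriterion:
    """Parse a ``.txt``/``.ann`` pair into an :class:`AnnotatedCriterion`."""
    mentions: list[EntityMention] = []
    relations: list[RelationMention] = []
    for raw in ann.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith("T"):
            m = _ENT_RE.match(line)
            if m is None:
                raise StandoffParseError(f"malformed entity line: {line!r}")
            tid, label, start_s, end_s, surface = m.groups()
            start, end = int(start_s), int(end_s)
            if end > len(txt) or start >= end:
                raise StandoffParseError(
                    f"{tid}: offsets [{start},{end}) outside text of length {len(txt)}"
                )
            if txt[start:end] != surface:
                raise StandoffParseError(
                    f"{tid}: surface {surface!r} does not match text slice "
                    f"{txt[start:end]!r}"
                )
            group, _, attribute = label.partition("::")
            mentions.append(EntityMention(tid, start, end, surface, group, attribute))
        elif line.startswith("R"):
            m = _REL_RE.match(line)
            if m is None:
                raise StandoffParseError(f"malformed relation line: {line!r}")
            _, relname, src, tgt = m.groups()
            relations.append(RelationMention(relname, src, tgt))
        else:
            raise StandoffParseError(f"unrecognized standoff line: {line!r}")
    known = {m.mention_id for m in mentions}
    for r in relations:
        for arg in (r.source, r.target):
            if arg not in known:
                raise StandoffParseError(f"{r.relation}: dangling argument {arg}")
    return AnnotatedCriterion(trial_id, section, txt, mentions, relations)


def write_standoff(criterion: AnnotatedCriterion) -> tuple[str, str]:
    """Serialize a criterion to a ``(txt, ann)`` pair."""
    lines: list[str] = []
    for m in sorted(criterion.mentions, key=lambda m: (m.start, m.end, m.mention_id)):
        lines.append(f"{m.mention_id}\t{m.label} {m.start} {m.end}\t{m.surface}")
    for i, r in enumerate(criterion.relations, 1):
        rid = f"R{i}"
        lines.append(f"{rid}\t{r.relation} Arg1:{r.source} Arg2:{r.target}")
    return criterion.text, "\n".join(lines) + ("\n" if lines else "")


def read_standoff_files(txt_path: str | Path, ann_path: str | Path, **kw) -> AnnotatedCriterion:
    return read_standoff(
        Path(txt_path).read_text(encoding="utf-8"),
        Path(ann_path).read_text(encoding="utf-8"),
        **kw,
    )


def write_standoff_files(criterion: AnnotatedCriterion, txt_path: str | Path, ann_path: str | Path) -> None:
    txt, ann = write_standoff(criterion)
    Path(txt_path).write_text(txt, encoding="utf-8")
    Path(ann_path).write_text(ann, encoding="utf-8")
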