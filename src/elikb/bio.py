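"""BIO tag encoding between mention spans and token-level labels.

Labels are ``B-<group::attribute>`` / ``I-<group::attribute>`` / ``O``.
Mentions must start and end on token boundaries; adjacent mentions with the
same label encode as ``B,B`` so the round trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ontology import AnnotatedCriterion, EntityMention
from .tokenizer import TokenSequence


class AlignmentError(ValueError):
    """A mention boundary falls inside a token."""


@dataclass
class BIOSequence:
    labels: list[str]

    def __post_init__(self) -> None:
        prev = "O"
        for lab in self.labels:
            if lab.startswith("I-"):
                body = lab[2:]
                if prev == "O" or prev[2:] != body:
                    raise ValueError(f"invalid BIO transition {prev} -> {lab}")
            prev = lab

    def __len__(self) -> int:
        return len(self.labels)


def mentions_to_bio(criterion: AnnotatedCriterion, tokens: TokenSequence) -> BIOSequence:
    """Encode gold mentions as a BIO label per token."""
    labels = ["O"] * len(tokens.tokens)
    starts = {t.start: i for i, t in enumerate(tokens.tokens)}
    ends = {t.end: i for i, t in enumerate(tokens.tokens)}
    for m in sorted(criterion.mentions, key=lambda m: m.start):
        if m.start not in starts or m.end not in ends:
            raise AlignmentError(
                f"mention {m.mention_id} span [{m.start},{m.end}) not on token boundaries"
            )
        i0, i1 = starts[m.start], ends[m.end]
        labels[i0] = f"B-{m.label}"
        for i in range(i0 + 1, i1 + 1):
            labels[i] = f"I-{m.label}"
    return BIOSequence(labels)


def bio_to_mentions(bio: BIOSequence, tokens: TokenSequence) -> list[EntityMention]:
    """Decode BIO labels back to mentions with character spans."""
    mentions: list[EntityMention] = []
    i = 0
    n = len(bio.labels)
    while i < n:
        lab = bio.labels[i]
        if lab.startswith("B-"):
            body = lab[2:]
            j = i
            while j + 1 < n and bio.labels[j + 1] == f"I-{body}":
                j += 1
            start = tokens.tokens[i].start
            end = tokens.tokens[j].end
            group, _, attribute = body.partition("::")
            mentions.append(
                EntityMention(
                    f"T{len(mentions) + 1}",
                    start,
                    end,
                    tokens.text[start:end],
                    group,
                    attribute,
                )
            )
            i = j + 1
        else:
            i += 1
    return mentions
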