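"""Deterministic lexicon tagger.

A longest-match, left-to-right greedy baseline: phrases from a lexicon
(surface phrase -> ``group::attribute``) are matched case-insensitively
against the token stream.  Used for pre-annotation and as a closed-form
reference: on a corpus generated from its own lexicon it recovers every
mention (F1 = 1).
"""

from __future__ import annotations

from .bio import BIOSequence
from .tokenizer import TokenSequence, tokenize


class PhraseLexicon:
    """Maps token phrases to entity labels, keyed case-insensitively."""

    def __init__(self, entries: dict[str, str] | None = None):
        self._phrases: dict[tuple[str, ...], str] = {}
        self.max_len = 0
        for phrase, label in (entries or {}).items():
            self.add(phrase, label)

    def add(self, phrase: str, label: str) -> None:
        key = tuple(t.lower() for t in tokenize(phrase).surfaces())
        self._phrases[key] = label
        self.max_len = max(self.max_len, len(key))

    def lookup(self, token_surfaces: tuple[str, ...]) -> str | None:
        return self._phrases.get(tuple(t.lower() for t in token_surfaces))

    def __len__(self) -> int:
        return len(self._phrases)

    def items(self):
        return self._phrases.items()


def lexicon_tag(tokens: TokenSequence, lexicon: PhraseLexicon) -> BIOSequence:
    """Greedy longest-match tagging; deterministic."""
    surfaces = tokens.surfaces()
    n = len(surfaces)
    labels = ["O"] * n
    i = 0
    while i < n:
        matched = False
        for span in range(min(lexicon.max_len, n - i), 0, -1):
            label = lexicon.lookup(tuple(surfaces[i : i + span]))
            if label is not None:
                labels[i] = f"B-{label}"
                for j in range(i + 1, i + span):
                    labels[j] = f"I-{label}"
                i += span
                matched = True
                break
        if not matched:
            i += 1
    return BIOSequence(labels)
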