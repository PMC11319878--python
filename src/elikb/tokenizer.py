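"""Deterministic tokenizer for eligibility-criterion sentences.

Rules (in order):

1. comparator glyphs ``≤ ≥ < > =`` are always single-character tokens, even
   when glued to a number (``≤2.5x`` → ``≤``, ``2.5x``);
2. the punctuation ``( ) ; :`` is split into its own tokens;
3. every other maximal run of non-space, non-special characters is one token,
   so units glued to numbers (``2.5x``) and numbers with internal commas
   (``100,000``) stay whole; a trailing comma or period is stripped off the
   token (the comma becomes its own token, the period is dropped);
4. whitespace separates tokens and is never part of one.

Token spans index the original text, so joining surfaces with the original
inter-token gaps reconstructs the sentence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
import re


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


@dataclass
class TokenSequence:
    tokens: list[Token]
    text: str
    sentence_ref: str = ""

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def reconstruct(self) -> str:
        """Rebuild the text from token spans plus original gaps."""
        out: list[str] = []
        prev_end = 0
        for t in self.tokens:
            out.append(self.text[prev_end:t.start])
            out.append(t.surface)
            prev_end = t.end
        out.append(self.text[prev_end:])
        return "".join(out)


_TOKEN_RE = re.compile(r"[≤≥<>=]|[^\s≤≥<>=();:]+|[();:]")


def tokenize(text: str, sentence_ref: str = "") -> TokenSequence:
    """Segment a sentence; raises ``ValueError`` on empty input."""
    if not text or not text.strip():
        raise ValueError("cannot tokenize empty text")
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        surf, start = m.group(0), m.start()
        while surf and surf[-1] in ".,":
            tail = surf[-1]
            surf = surf[:-1]
            if tail == ",":
                pos = start + len(surf)
                tokens.append(Token(",", pos, pos + 1))
        if surf:
            tokens.append(Token(surf, start, start + len(surf)))
    tokens.sort(key=lambda t: t.start)
    return TokenSequence(tokens, text, sentence_ref)
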