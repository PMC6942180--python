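"""Text normalization shared by the terminology portal and the annotator.

Normalization is deliberately aggressive and language-neutral: lowercase,
diacritics stripped (NFKD, combining marks removed), tokens are maximal runs
of word characters, decimal numbers ("7.2", "7,2") kept as single tokens and
"%" kept as a token of its own so lab values like "HbA1c a 7.2 %" survive
tokenization.  Character offsets always point into the raw text.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

_TOKEN_RE = re.compile(r"\d+[.,]\d+|\w+|%", re.UNICODE)
_NORM_KEEP = re.compile(r"[^\w%.,]", re.UNICODE)
_NUMBER_RE = re.compile(r"\d+(?:[.,]\d+)?$")
_SENTENCE_BREAK = set(".!?\n")


def strip_accents(s: str) -> str:
    return "".join(c for c in unicodedata.normalize("NFKD", s) if not unicodedata.combining(c))


def norm_text(s: str) -> str:
    """Normalized form of a string: accent-stripped lowercase."""
    return strip_accents(s).lower()


@dataclass(frozen=True)
class Token:
    text: str      # surface form in the raw text
    norm: str      # normalized form
    start: int     # character offset, 0-based
    end: int       # exclusive character offset
    sentence: int  # 0-based sentence index
    is_number: bool


def tokenize(text: str) -> list[Token]:
    """Tokenize raw text into normalized tokens with offsets and sentence indexes.

    Sentence boundaries are drawn at '.', '!', '?' or newline occurring
    between tokens; the dot inside a decimal number never splits a sentence
    because the number is consumed as one token.
    """
    tokens: list[Token] = []
    sentence = 0
    last_end = 0
    for m in _TOKEN_RE.finditer(text):
        gap = text[last_end : m.start()]
        if tokens and any(c in _SENTENCE_BREAK for c in gap):
            sentence += 1
        surface = m.group(0)
        norm = norm_text(surface)
        # compatibility decomposition can emit symbols ("½" -> "1⁄2");
        # keep only word characters so token norms re-tokenize to themselves
        cleaned = _NORM_KEEP.sub("", norm)
        tokens.append(
            Token(
                text=surface,
                norm=cleaned or norm,
                start=m.start(),
                end=m.end(),
                sentence=sentence,
                is_number=bool(_NUMBER_RE.match(surface)),
            )
        )
        last_end = m.end()
    return tokens


def norm_tokens(s: str) -> tuple[str, ...]:
    """Normalized token tuple of a phrase (used for lexicon entries and triggers)."""
    return tuple(t.norm for t in tokenize(s))


def parse_number(token: str) -> float:
    """Parse a number token, accepting the decimal comma."""
    return float(token.replace(",", "."))
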