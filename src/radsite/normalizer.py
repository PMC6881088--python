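"""Deterministic tokenization of raw treatment-site strings.

Site names typed into a record-and-verify EMR are short, noisy phrases:
mixed case, ad-hoc abbreviations, and separators such as ``/``, ``-`` and
``#`` used inconsistently ("Prostate/Prox SV", "Whole Brain #2").  The
tokenizer splits such a string into classified tokens that every later
stage (dictionary lookup, abbreviation resolution, term assembly) operates
on.  It is a total function: any input, including the empty string, yields
a well-defined token list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import List


class TokenKind(str, Enum):
    WORD = "word"
    NUMBER = "number"
    PUNCT = "punct"


@dataclass(frozen=True)
class Token:
    """One classified token of a site-name string.

    ``span`` is the half-open character interval of ``text`` in the raw
    string; spans of successive tokens are non-overlapping and increasing,
    and the raw string is recovered by re-inserting the skipped whitespace.
    """

    text: str
    norm: str
    kind: TokenKind
    index: int
    span: tuple[int, int]


# '#'+digits is one number token ("#2"); a run of letters/digits is one
# token; any other non-space character stands alone as punctuation.
# Underscore is excluded from \w so it falls through to the punct branch.
_TOKEN_RE = re.compile(r"#\d+|[^\W_]+|\S", re.UNICODE)

_DIGITS_RE = re.compile(r"#?\d+\Z")


def _classify(text: str) -> TokenKind:
    if _DIGITS_RE.match(text):
        return TokenKind.NUMBER
    if len(text) == 1 and not text.isalnum():
        return TokenKind.PUNCT
    return TokenKind.WORD


def tokenize(raw: str) -> List[Token]:
    """Split a raw site name into classified tokens.

    Whitespace separates tokens and is discarded; every other character is
    part of exactly one token, so token spans partition the non-whitespace
    content of ``raw``.

    >>> [(t.norm, t.kind.value) for t in tokenize("Prostate/Prox SV")]
    [('prostate', 'word'), ('/', 'punct'), ('prox', 'word'), ('sv', 'word')]
    """
    tokens: List[Token] = []
    for match in _TOKEN_RE.finditer(raw):
        text = match.group(0)
        tokens.append(
            Token(
                text=text,
                norm=text.casefold(),
                kind=_classify(text),
                index=len(tokens),
                span=(match.start(), match.end()),
            )
        )
    return tokens


def normalize_term(term: str) -> str:
    """Canonical lookup key for a dictionary term.

    Tokenizes and re-joins with single spaces, lowercased, so that the same
    key is produced whether a term arrives as ``"S/C"``, ``"s / c"`` or
    ``"s/c "`` — matching the way token runs are joined during term
    assembly.
    """
    return " ".join(t.norm for t in tokenize(term))
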