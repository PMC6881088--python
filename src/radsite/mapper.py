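"""Term assembly: from resolved tokens to concept annotations.

After tokenization and per-token resolution, the longest contiguous token
runs whose joined form is a dictionary term are emitted as concept
annotations (greedy, left to right).  Punctuation tokens become
punctuation annotations (the ``T000`` sentinel); number tokens and words
that resolve but match no term are left unmapped; tokens the resolver gave
up on are listed as unresolved.

:class:`Annotator` bundles a lexicon, a bigram model and resolver settings
into the end-to-end pipeline: ``tokenize -> resolve -> assemble``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

from . import _tabledata
from .lexicon import Lexicon, build_fixture_lexicon
from .normalizer import Token, TokenKind, tokenize
from .resolver import BigramModel, Resolution, ResolverConfig, resolve_token, train_bigrams

#: sentinel semantic type for punctuation annotations
PUNCT_SEMTYPE = "T000"

#: punctuation whose annotations are shown in bracket output; the hyphen is
#: treated as a silent separator, the slash is printed
PRINTED_PUNCT = frozenset({"/"})


@dataclass(frozen=True)
class ConceptAnnotation:
    """One annotated region of a site name.

    ``token_span`` is a half-open interval over token indices.  ``kind`` is
    ``concept`` (dictionary term), ``punctuation`` (sentinel ``T000``) or
    ``unmapped`` (number, or resolved word matching no term).
    """

    surface_label: str
    cuis: tuple[str, ...]
    semtypes: tuple[str, ...]
    token_span: tuple[int, int]
    kind: str

    def bracket(self) -> str:
        """Bracket rendering, e.g. ``supraclavicular region [C0446461:T029]``."""
        if self.kind == "punctuation":
            return f"{self.surface_label} [PUNC:{PUNCT_SEMTYPE}]"
        return f"{self.surface_label} [{','.join(self.cuis)}:{','.join(self.semtypes)}]"


@dataclass
class SiteAnnotation:
    """Full annotation of one raw site-name string."""

    raw: str
    annotations: List[ConceptAnnotation] = field(default_factory=list)
    unresolved_tokens: List[int] = field(default_factory=list)

    @property
    def concepts(self) -> List[ConceptAnnotation]:
        return [a for a in self.annotations if a.kind == "concept"]


def assemble_terms(
    tokens: Sequence[Token],
    resolutions: Dict[int, Resolution],
    lexicon: Lexicon,
) -> List[ConceptAnnotation]:
    """Greedy leftmost-longest matching of resolved tokens against terms.

    At each position the longest window of tokens — starting and ending on
    a resolved word, possibly spanning punctuation or numbers — whose
    joined resolved form is a lexicon term becomes one concept annotation;
    matching restarts after it.  Unresolved words yield no annotation (the
    caller records them); interior punctuation of a matched term is
    swallowed by the term's span.
    """
    max_window = lexicon.max_term_tokens

    def effective(tok: Token) -> Optional[str]:
        if tok.kind is TokenKind.WORD:
            res = resolutions.get(tok.index)
            if res is None or res.status == "unresolved":
                return None
            return res.resolved_word
        return tok.norm

    annotations: List[ConceptAnnotation] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok.kind is TokenKind.PUNCT:
            annotations.append(ConceptAnnotation(
                surface_label=tok.text, cuis=(), semtypes=(PUNCT_SEMTYPE,),
                token_span=(i, i + 1), kind="punctuation"))
            i += 1
            continue
        if tok.kind is TokenKind.NUMBER:
            annotations.append(ConceptAnnotation(
                surface_label=tok.text, cuis=(), semtypes=(),
                token_span=(i, i + 1), kind="unmapped"))
            i += 1
            continue
        if effective(tok) is None:  # unresolved word: no annotation
            i += 1
            continue

        matched = None
        limit = min(len(tokens), i + max_window)
        parts: List[str] = []
        for j in range(i, limit):
            part = effective(tokens[j])
            if part is None:  # unresolved word breaks the window
                break
            parts.append(part)
            if tokens[j].kind is not TokenKind.WORD:
                continue  # a term window must end on a word token
            key = " ".join(parts)
            if key in lexicon.entries:
                matched = (j + 1, lexicon.entries[key][0])
        if matched is not None:
            end, entry = matched
            annotations.append(ConceptAnnotation(
                surface_label=entry.preferred_label, cuis=tuple(entry.cuis),
                semtypes=tuple(entry.semtypes), token_span=(i, end), kind="concept"))
            i = end
        else:
            annotations.append(ConceptAnnotation(
                surface_label=tok.text, cuis=(), semtypes=(),
                token_span=(i, i + 1), kind="unmapped"))
            i += 1
    return annotations


def build_model(lexicon: Lexicon, dev_strings: Iterable[str] = ()) -> BigramModel:
    """Train bigram statistics on lexicon terms plus development strings."""
    corpus = lexicon.term_token_sequences()
    for raw in dev_strings:
        words = [t.norm for t in tokenize(raw) if t.kind is TokenKind.WORD]
        if words:
            corpus.append(words)
    return train_bigrams(corpus)


class Annotator:
    """End-to-end pipeline for a fixed lexicon/model/configuration."""

    def __init__(
        self,
        lexicon: Lexicon,
        model: Optional[BigramModel] = None,
        config: Optional[ResolverConfig] = None,
        english_words: Optional[Iterable[str]] = None,
    ) -> None:
        self.lexicon = lexicon
        self.model = model if model is not None else build_model(lexicon)
        self.config = config or ResolverConfig()
        self.english_words = (
            frozenset(w.casefold() for w in english_words)
            if english_words is not None
            else _tabledata.DEFAULT_ENGLISH_WORDS
        )

    # -- resolution ------------------------------------------------------

    def _resolve_all(self, tokens: Sequence[Token]) -> Dict[int, Resolution]:
        resolutions: Dict[int, Resolution] = {}
        pending: List[Token] = []
        for tok in tokens:
            if tok.kind is not TokenKind.WORD:
                continue
            if self.lexicon.has_token(tok.norm):
                resolutions[tok.index] = Resolution(tok.index, "exact", tok.norm)
            elif tok.norm in self.english_words:
                resolutions[tok.index] = Resolution(tok.index, "english", tok.norm)
            else:
                pending.append(tok)

        def context(tok: Token, step: int) -> Optional[str]:
            # nearest already-resolved word token, skipping punctuation/numbers
            j = tok.index + step
            while 0 <= j < len(tokens):
                if tokens[j].kind is TokenKind.WORD:
                    res = resolutions.get(j)
                    return res.resolved_word if res and res.status in ("exact", "english") else None
                j += step
            return None

        for tok in pending:
            resolutions[tok.index] = resolve_token(
                tok, context(tok, -1), context(tok, +1),
                self.model, self.lexicon.token_vocabulary, self.config)
        return resolutions

    # -- pipeline --------------------------------------------------------

    def annotate(self, raw: str) -> SiteAnnotation:
        tokens = tokenize(raw)
        resolutions = self._resolve_all(tokens)
        annotations = assemble_terms(tokens, resolutions, self.lexicon)
        unresolved = [
            t.index for t in tokens
            if t.kind is TokenKind.WORD and resolutions[t.index].status == "unresolved"
        ]
        return SiteAnnotation(raw=raw, annotations=annotations, unresolved_tokens=unresolved)


def annotate_site(
    raw: str,
    lexicon: Lexicon,
    model: Optional[BigramModel] = None,
    config: Optional[ResolverConfig] = None,
    english_words: Optional[Iterable[str]] = None,
) -> SiteAnnotation:
    """Annotate one raw site name (convenience wrapper over Annotator)."""
    return Annotator(lexicon, model, config, english_words).annotate(raw)


def fixture_annotator(config: Optional[ResolverConfig] = None) -> Annotator:
    """Pipeline over the embedded lexicon, with bigram statistics trained on
    its terms and the embedded development strings."""
    lex = build_fixture_lexicon()
    model = build_model(lex, (raw for raw, _, _ in _tabledata.TOP_SITES))
    return Annotator(lex, model, config)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def serialize_annotation(
    site: SiteAnnotation,
    style: str = "bracket",
    printed_punct: frozenset[str] = PRINTED_PUNCT,
) -> str:
    """Render a SiteAnnotation.

    ``bracket`` joins the concept annotations (and printed punctuation)
    with tabs; ``tsv`` prepends the raw string, concept count and appends
    unresolved token texts; ``jsonl`` is one JSON object.
    """
    if style not in ("bracket", "tsv", "jsonl"):
        raise ValueError(f"unknown style {style!r}")

    tokens = tokenize(site.raw)
    if style == "jsonl":
        return json.dumps(
            {
                "raw": site.raw,
                "annotations": [
                    {"label": a.surface_label, "cuis": list(a.cuis),
                     "semtypes": list(a.semtypes), "token_span": list(a.token_span),
                     "kind": a.kind}
                    for a in site.annotations
                ],
                "unresolved": [tokens[i].text for i in site.unresolved_tokens],
            },
            ensure_ascii=False, sort_keys=True,
        )

    visible = [
        a for a in site.annotations
        if a.kind == "concept"
        or (a.kind == "punctuation" and a.surface_label in printed_punct)
    ]
    cells = [a.bracket() for a in visible]
    if style == "bracket":
        return "\t".join(cells)
    unresolved = ",".join(tokens[i].text for i in site.unresolved_tokens)
    return "\t".join([site.raw, str(len(site.concepts))] + cells + [unresolved])
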