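"""Application terminology for treatment-site normalization.

The dictionary has two layers: a subset of a UMLS-style concept source
restricted to anatomical / spatial semantic types (body part T023, body
location or region T029, body space or junction T030, spatial concept
T082, ...), and a manually curated supplement of radiotherapy
abbreviations and concepts the subset misses (``SCV``, ``MLB``, ``WBRT``,
...).  Supplement entries shadow subset entries on surface collision,
since the supplement exists precisely to correct gaps.

A self-contained fixture lexicon built from the embedded reference tables
makes the whole pipeline runnable without a UMLS license.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from . import _tabledata
from .normalizer import TokenKind, normalize_term, tokenize

logger = logging.getLogger(__name__)

#: semantic types of topographical entities — the default subset filter
DEFAULT_SEMTYPE_FILTER = frozenset({"T023", "T029", "T030", "T082"})

_SEMTYPE_OK = lambda s: len(s) == 4 and s[0] == "T" and s[1:].isdigit()


@dataclass
class ConceptEntry:
    """One dictionary sense: a normalized term with its coded concept.

    ``cuis`` may be empty only for supplement entries (curated concepts
    that have no identifier in the source vocabulary).
    """

    term: str
    cuis: List[str]
    semtypes: List[str]
    source: str  # "umls_subset" | "supplement"
    preferred_label: str

    def __post_init__(self) -> None:
        if not self.semtypes:
            raise ValueError(f"entry {self.term!r} has no semantic types")
        bad = [s for s in self.semtypes if not _SEMTYPE_OK(s)]
        if bad:
            raise ValueError(f"entry {self.term!r} has malformed semantic types {bad}")
        if not self.cuis and self.source != "supplement":
            raise ValueError(f"entry {self.term!r} lacks CUIs but is not a supplement entry")
        if self.source not in ("umls_subset", "supplement"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class SupplementRecord:
    """A curated abbreviation or concept: ``surface`` denotes ``expansion``."""

    surface: str
    expansion: str
    cuis: List[str]
    semtypes: List[str]

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise ValueError("supplement surface is empty")
        if not self.expansion.strip():
            raise ValueError(f"supplement record {self.surface!r} has empty expansion")
        if not self.semtypes:
            raise ValueError(f"supplement record {self.surface!r} has blank semtypes")


@dataclass
class Lexicon:
    """Normalized term -> concept entries, plus the single-token vocabulary.

    Keys are produced by :func:`radsite.normalizer.normalize_term`, so
    lookups are case- and whitespace-insensitive.  Entries from the
    supplement are stored ahead of subset entries under the same key.
    """

    entries: Dict[str, List[ConceptEntry]] = field(default_factory=dict)
    token_vocabulary: set[str] = field(default_factory=set)
    semtype_filter: set[str] = field(default_factory=lambda: set(DEFAULT_SEMTYPE_FILTER))

    def add(self, entry: ConceptEntry, shadow: bool = False) -> None:
        key = normalize_term(entry.term)
        entry = replace(entry, term=key)
        bucket = self.entries.setdefault(key, [])
        bucket.insert(0, entry) if shadow else bucket.append(entry)
        for tok in tokenize(key):
            if tok.kind is TokenKind.WORD:
                self.token_vocabulary.add(tok.norm)

    def lookup(self, term: str) -> List[ConceptEntry]:
        """All entries for a term; empty list when unknown."""
        return list(self.entries.get(normalize_term(term), ()))

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.entries

    def has_token(self, token_norm: str) -> bool:
        return token_norm in self.token_vocabulary

    @property
    def max_term_tokens(self) -> int:
        """Longest term length in tokens — bounds the term-assembly window."""
        return max((len(tokenize(t)) for t in self.entries), default=0)

    def term_token_sequences(self) -> List[List[str]]:
        """Word-token sequences of all multi-token terms (bigram training)."""
        out = []
        for term in self.entries:
            words = [t.norm for t in tokenize(term) if t.kind is TokenKind.WORD]
            if len(words) >= 2:
                out.append(words)
        return out


# --------------------------------------------------------------------------
# concept source (MRCONSO/MRSTY-style pipe-delimited files)
# --------------------------------------------------------------------------

def read_concept_source(
    path_concepts: str | Path,
    path_semtypes: str | Path,
    semtype_filter: Iterable[str] = DEFAULT_SEMTYPE_FILTER,
    *,
    concept_cols: tuple[int, int] = (0, 1),
    semtype_cols: tuple[int, int] = (0, 1),
) -> Lexicon:
    """Build a lexicon from pipe-delimited concept and semantic-type files.

    ``path_concepts`` holds ``string|CUI`` rows, ``path_semtypes`` holds
    ``CUI|semtype`` rows (column positions configurable so wider RRF-style
    exports can be consumed).  A string is admitted iff its CUI carries at
    least one semantic type in ``semtype_filter``; the entry is tagged with
    the admitted types only.  Strings sharing a normalized form merge into
    one entry with de-duplicated CUI/semtype lists in first-seen order.

    Malformed rows are skipped with a logged warning; missing files raise
    ``FileNotFoundError``.
    """
    semtype_filter = set(semtype_filter)
    if not semtype_filter:
        raise ValueError("semtype_filter must be non-empty")

    cui_semtypes: Dict[str, List[str]] = {}
    skipped = 0
    for lineno, line in enumerate(_read_lines(path_semtypes), 1):
        parts = line.split("|")
        try:
            cui = parts[semtype_cols[0]].strip()
            sty = parts[semtype_cols[1]].strip()
        except IndexError:
            cui = sty = ""
        if not cui or not _SEMTYPE_OK(sty):
            skipped += 1
            logger.warning("semtype file %s line %d malformed (skipped, %d so far)",
                           path_semtypes, lineno, skipped)
            continue
        bucket = cui_semtypes.setdefault(cui, [])
        if sty not in bucket:
            bucket.append(sty)

    lex = Lexicon(semtype_filter=semtype_filter)
    skipped = 0
    for lineno, line in enumerate(_read_lines(path_concepts), 1):
        parts = line.split("|")
        try:
            surface = parts[concept_cols[0]].strip()
            cui = parts[concept_cols[1]].strip()
        except IndexError:
            surface = cui = ""
        if not surface or not cui:
            skipped += 1
            logger.warning("concept file %s line %d malformed (skipped, %d so far)",
                           path_concepts, lineno, skipped)
            continue
        admitted = [s for s in cui_semtypes.get(cui, ()) if s in semtype_filter]
        if not admitted:
            continue
        key = normalize_term(surface)
        existing = next((e for e in lex.entries.get(key, ()) if e.source == "umls_subset"), None)
        if existing is None:
            lex.add(ConceptEntry(term=key, cuis=[cui], semtypes=list(admitted),
                                 source="umls_subset", preferred_label=surface.strip()))
        else:
            if cui not in existing.cuis:
                existing.cuis.append(cui)
            for s in admitted:
                if s not in existing.semtypes:
                    existing.semtypes.append(s)
    return lex


def _read_lines(path: str | Path) -> Iterable[str]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                yield line


# --------------------------------------------------------------------------
# supplement terminology
# --------------------------------------------------------------------------

def load_supplement(path: str | Path) -> List[SupplementRecord]:
    """Read the curated supplement TSV (surface/expansion/cuis/semtypes).

    ``cuis`` and ``semtypes`` are semicolon-joined; ``cuis`` may be blank.
    Duplicate surfaces with identical payloads collapse to one record;
    conflicting duplicates are a fatal error reporting both rows.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"surface", "expansion", "cuis", "semtypes"} - set(frame.columns)
    if missing:
        raise ValueError(f"supplement {path} lacks columns: {sorted(missing)}")

    records: Dict[str, SupplementRecord] = {}
    for row in frame.itertuples(index=False):
        rec = SupplementRecord(
            surface=row.surface.strip(),
            expansion=row.expansion.strip(),
            cuis=_split_list(row.cuis),
            semtypes=_split_list(row.semtypes),
        )
        key = normalize_term(rec.surface)
        prior = records.get(key)
        if prior is None:
            records[key] = rec
        elif (prior.expansion, prior.cuis, prior.semtypes) != (rec.expansion, rec.cuis, rec.semtypes):
            raise ValueError(
                f"conflicting supplement rows for surface {rec.surface!r}: "
                f"{prior} vs {rec}"
            )
    return list(records.values())


def _split_list(cell: str) -> List[str]:
    return [p.strip() for p in cell.split(";") if p.strip()]


def merge_supplement(lexicon: Lexicon, records: Sequence[SupplementRecord]) -> Lexicon:
    """Fold supplement records into the lexicon (in place; returns it).

    Both the surface and its expansion become lookup keys resolving to the
    same entry.  On exact surface collision with a subset term the
    supplement entry is returned first.
    """
    for rec in records:
        entry = ConceptEntry(
            term=rec.surface,
            cuis=list(rec.cuis),
            semtypes=list(rec.semtypes),
            source="supplement",
            preferred_label=rec.expansion,
        )
        lexicon.add(entry, shadow=True)
        if normalize_term(rec.expansion) != normalize_term(rec.surface):
            lexicon.add(replace(entry, term=rec.expansion), shadow=True)
        lexicon.semtype_filter.update(rec.semtypes)
    return lexicon


# --------------------------------------------------------------------------
# fixture lexicon (embedded reference vocabulary)
# --------------------------------------------------------------------------

def fixture_supplement_records() -> List[SupplementRecord]:
    return [
        SupplementRecord(surface=s, expansion=e, cuis=list(c), semtypes=list(t))
        for s, e, c, t in _tabledata.SUPPLEMENT_FIXTURE
    ]


def build_fixture_lexicon() -> Lexicon:
    """The embedded lexicon covering the reference site names.

    Contains every concept of the worked example (with the exact CUI and
    semantic-type lists) plus the curated abbreviation surfaces, so the
    whole pipeline runs with no external vocabulary files.
    """
    lex = Lexicon()
    for label, cuis, semtypes in _tabledata.UMLS_FIXTURE_CONCEPTS:
        lex.add(ConceptEntry(term=label, cuis=list(cuis), semtypes=list(semtypes),
                             source="umls_subset", preferred_label=label))
        lex.semtype_filter.update(semtypes)
    merge_supplement(lex, fixture_supplement_records())
    return lex


# --------------------------------------------------------------------------
# lexicon TSV serialization (round-trippable)
# --------------------------------------------------------------------------

def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    rows = []
    for key in sorted(lexicon.entries):
        for e in lexicon.entries[key]:
            rows.append(
                {"term": e.term, "cuis": ";".join(e.cuis), "semtypes": ";".join(e.semtypes),
                 "source": e.source, "preferred_label": e.preferred_label}
            )
    pd.DataFrame(rows, columns=["term", "cuis", "semtypes", "source", "preferred_label"]).to_csv(
        path, sep="\t", index=False
    )


def read_lexicon(path: str | Path, semtype_filter: Optional[Iterable[str]] = None) -> Lexicon:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lex = Lexicon(semtype_filter=set(semtype_filter) if semtype_filter else set())
    # supplement rows shadow on insert, so add subset rows first to keep order
    for row in sorted(frame.itertuples(index=False), key=lambda r: r.source == "supplement"):
        lex.add(
            ConceptEntry(term=row.term, cuis=_split_list(row.cuis),
                         semtypes=_split_list(row.semtypes), source=row.source,
                         preferred_label=row.preferred_label),
            shadow=(row.source == "supplement"),
        )
        lex.semtype_filter.update(_split_list(row.semtypes))
    return lex
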