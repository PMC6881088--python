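"""Seeded generator of labeled noisy site-name corpora.

Emulates the noise actually observed in EMR site names: arbitrary casing
("WHole Brain"), curated abbreviations standing in for full terms (SCV,
WBRT, Prox ...), single-character typos, decorations ("#2", "PCI",
"Retreat", "photons"), and separator swaps ("whole brain-2").  Every case
carries a replayable corruption log, and its gold annotation is computed
from the clean canonical string — so the generator stays independent of
the resolver it is used to test.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .evaluation import GoldConcept, GoldRecord, write_gold
from .lexicon import SupplementRecord, fixture_supplement_records
from .mapper import Annotator, SiteAnnotation

_LETTERS = string.ascii_lowercase
_CASE_MODES = ("upper", "lower", "title", "capitalize", "swapcase")

Op = List  # JSON-serializable op: [name, *params]


@dataclass
class CorruptionConfig:
    """Per-operation corruption probabilities.

    Probabilities are per site name for abbreviation substitution and
    decoration, per chunk (whitespace-delimited word) for case mangling and
    character edits, and per gap for separator swaps.  ``max_edits`` bounds
    the edits applied to any single chunk.  All-zero probabilities leave
    the canonical string untouched.
    """

    p_abbrev: float = 0.3
    p_case: float = 0.3
    p_edit: float = 0.1
    max_edits: int = 1
    p_separator: float = 0.1
    p_decorate: float = 0.1
    decorations: Tuple[str, ...] = ("2", "1", "#2", "PCI", "RT", "Retreat", "photons")
    separators: Tuple[str, ...] = ("-", "/")

    @classmethod
    def lookup_noise(cls) -> "CorruptionConfig":
        """Case mangling + known-abbreviation substitution only — noise the
        dictionary absorbs by exact lookup."""
        return cls(p_abbrev=0.5, p_case=0.5, p_edit=0.0, p_separator=0.0, p_decorate=0.0)

    @classmethod
    def edit_noise(cls, p_edit: float = 0.5) -> "CorruptionConfig":
        """At most one character edit per chunk, nothing else — noise the
        fuzzy resolver must absorb."""
        return cls(p_abbrev=0.0, p_case=0.0, p_edit=p_edit, max_edits=1,
                   p_separator=0.0, p_decorate=0.0)

    @classmethod
    def identity(cls) -> "CorruptionConfig":
        return cls(p_abbrev=0.0, p_case=0.0, p_edit=0.0, p_separator=0.0, p_decorate=0.0)


@dataclass
class SyntheticCase:
    """A (canonical, corrupted) pair with its frozen gold annotation."""

    canonical: str
    corrupted: str
    expected: SiteAnnotation
    ops_applied: List[Op] = field(default_factory=list)
    seed: int = 0

    @property
    def gold(self) -> GoldRecord:
        """Gold record keyed by the corrupted string (what the pipeline sees)."""
        return GoldRecord(
            raw=self.corrupted,
            gold_concepts=[
                GoldConcept(label=a.surface_label, cuis=a.cuis, semtypes=a.semtypes)
                for a in self.expected.concepts
            ],
        )


def default_abbreviation_map(
    records: Optional[Sequence[SupplementRecord]] = None,
) -> Dict[str, List[str]]:
    """Map normalized expansion -> surfaces, from supplement records."""
    records = fixture_supplement_records() if records is None else records
    out: Dict[str, List[str]] = {}
    for rec in records:
        out.setdefault(" ".join(rec.expansion.casefold().split()), []).append(rec.surface)
    return out


# --------------------------------------------------------------------------
# corruption: sample ops, then replay them
# --------------------------------------------------------------------------

def replay(canonical: str, ops: Sequence[Op]) -> str:
    """Re-apply a corruption log to its canonical string.

    Ops are applied in order to a chunk list (``canonical.split()``):
    ``abbrev`` replaces a chunk range with an abbreviation's chunks,
    ``edit`` applies one character edit inside a chunk, ``case`` rewrites a
    chunk's casing, ``sep`` swaps the separator at a join position, and
    ``decorate`` appends trailing text.
    """
    chunks = canonical.split()
    seps: Optional[List[str]] = None
    tail: List[str] = []
    for op in ops:
        name = op[0]
        if name == "abbrev":
            _, i, j, surface = op
            chunks[i:j] = surface.split()
        elif name == "edit":
            _, idx, pos, kind, char = op
            c = chunks[idx]
            if kind == "ins":
                chunks[idx] = c[:pos] + char + c[pos:]
            elif kind == "del":
                chunks[idx] = c[:pos] + c[pos + 1:]
            else:  # sub
                chunks[idx] = c[:pos] + char + c[pos + 1:]
        elif name == "case":
            _, idx, text = op
            chunks[idx] = text
        elif name == "sep":
            if seps is None:
                seps = [" "] * max(0, len(chunks) - 1)
            _, gap, sep = op
            seps[gap] = sep
        elif name == "decorate":
            tail.append(op[1])
        else:
            raise ValueError(f"unknown corruption op {name!r}")
    if seps is None:
        seps = [" "] * max(0, len(chunks) - 1)
    out = "".join(c + s for c, s in zip(chunks, seps)) + (chunks[-1] if chunks else "")
    for t in tail:
        out = f"{out} {t}"
    return out


def _sample_ops(
    canonical: str,
    config: CorruptionConfig,
    rng: random.Random,
    abbrev_map: Dict[str, List[str]],
) -> List[Op]:
    chunks = canonical.split()
    ops: List[Op] = []

    # abbreviation substitution: one expansion occurrence, chosen at random.
    # Longer expansions claim their span first, so a short expansion never
    # replaces part of a longer one ("radiotherapy" inside "whole-brain
    # radiotherapy"), which would change the denoted concept.
    if config.p_abbrev > 0 and rng.random() < config.p_abbrev:
        matches: List[Tuple[int, int, List[str]]] = []
        folded = [c.casefold() for c in chunks]
        taken: set[int] = set()
        ordered = sorted(abbrev_map.items(), key=lambda kv: (-len(kv[0].split()), kv[0]))
        for expansion, surfaces in ordered:
            exp_chunks = expansion.split()
            for i in range(len(folded) - len(exp_chunks) + 1):
                span = range(i, i + len(exp_chunks))
                if folded[i:i + len(exp_chunks)] == exp_chunks and not taken & set(span):
                    matches.append((i, i + len(exp_chunks), surfaces))
                    taken.update(span)
        if matches:
            i, j, surfaces = matches[rng.randrange(len(matches))]
            surface = surfaces[rng.randrange(len(surfaces))]
            ops.append(["abbrev", i, j, surface])
            chunks[i:j] = surface.split()

    # character edits, at most max_edits per chunk
    if config.p_edit > 0:
        for idx, chunk in enumerate(chunks):
            if rng.random() >= config.p_edit:
                continue
            for _ in range(rng.randint(1, max(1, config.max_edits))):
                c = chunks[idx]
                kind = rng.choice(("ins", "del", "sub"))
                if kind == "del" and len(c) <= 1:
                    kind = "ins"
                if kind == "ins":
                    pos = rng.randrange(len(c) + 1)
                else:
                    pos = rng.randrange(len(c))
                char = rng.choice(_LETTERS)
                ops.append(["edit", idx, pos, kind, char])
                chunks[idx] = replay(c, [["edit", 0, pos, kind, char]])

    # case mangling per chunk
    if config.p_case > 0:
        for idx, chunk in enumerate(chunks):
            if rng.random() >= config.p_case:
                continue
            mode = rng.choice(_CASE_MODES)
            if mode == "swapcase":
                text = chunk.swapcase()
            else:
                text = getattr(chunk, mode)()
            if text != chunk:
                ops.append(["case", idx, text])
                chunks[idx] = text

    # separator swaps at join positions
    if config.p_separator > 0:
        for gap in range(max(0, len(chunks) - 1)):
            if rng.random() < config.p_separator:
                ops.append(["sep", gap, rng.choice(config.separators)])

    # trailing decoration
    if config.p_decorate > 0 and rng.random() < config.p_decorate:
        ops.append(["decorate", rng.choice(config.decorations)])

    return ops


def corrupt(
    canonical: str,
    config: CorruptionConfig,
    seed: int,
    annotator: Annotator,
    abbrev_map: Optional[Dict[str, List[str]]] = None,
) -> SyntheticCase:
    """Produce one corrupted variant of ``canonical`` with its gold label.

    Deterministic under ``(seed, config)``; the returned ``ops_applied``
    log replays to ``corrupted`` exactly.  The gold annotation is computed
    from the clean canonical string.
    """
    if not canonical.strip():
        raise ValueError("canonical string is empty")
    rng = random.Random(seed)
    abbrev_map = default_abbreviation_map() if abbrev_map is None else abbrev_map
    ops = _sample_ops(canonical, config, rng, abbrev_map)
    corrupted = replay(canonical, ops)
    expected = annotator.annotate(canonical)
    return SyntheticCase(canonical=canonical, corrupted=corrupted,
                         expected=expected, ops_applied=ops, seed=seed)


def generate_corpus(
    canonical_set: Sequence[str],
    n: int,
    config: CorruptionConfig,
    seed: int,
    annotator: Annotator,
    abbrev_map: Optional[Dict[str, List[str]]] = None,
) -> List[SyntheticCase]:
    """Draw ``n`` cases uniformly over ``canonical_set``, corrupting each
    independently (per-case seeds derive from ``seed``)."""
    if not canonical_set:
        raise ValueError("canonical_set is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    cases = []
    for _ in range(n):
        canonical = canonical_set[rng.randrange(len(canonical_set))]
        cases.append(corrupt(canonical, config, rng.randrange(2**31), annotator, abbrev_map))
    return cases


# --------------------------------------------------------------------------
# output files
# --------------------------------------------------------------------------

def write_corpus(cases: Sequence[SyntheticCase], path: str | Path) -> None:
    pd.DataFrame([{"site": c.corrupted, "count": 1} for c in cases]).to_csv(
        path, sep="\t", index=False)


def write_gold_for_cases(cases: Sequence[SyntheticCase], path: str | Path) -> None:
    write_gold([c.gold for c in cases], path)


def write_manifest(
    cases: Sequence[SyntheticCase], config: CorruptionConfig, seed: int, path: str | Path
) -> None:
    payload = {
        "seed": seed,
        "config": asdict(config),
        "cases": [
            {"canonical": c.canonical, "corrupted": c.corrupted,
             "seed": c.seed, "ops": c.ops_applied}
            for c in cases
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


#: clean canonical site names used as the default generator inputs — the
#: dictionary-covered phrases behind the most frequent EMR entries
DEFAULT_CANONICAL_SITES = (
    "pelvis",
    "supraclavicular region",
    "whole brain",
    "tumor bed boost",
    "left breast",
    "right chest wall",
    "right breast",
    "left chest wall",
    "boost",
    "prostate",
    "proximal seminal vesicle",
    "whole-brain radiotherapy",
    "midline block",
    "brain",
)
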