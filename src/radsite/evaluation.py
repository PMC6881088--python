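"""Entity-level scoring of predicted annotations against a gold standard.

Each predicted concept (punctuation and unmapped annotations are excluded)
may match one unused gold concept: a match requires a shared CUI, falling
back to case-insensitive label equality when either side carries no CUI
(curated supplement concepts such as the midline block have none).
Matching is a maximum bipartite matching, so the count of true positives
never depends on annotation order.  Recall and precision are pooled over
the corpus (micro-averaged); an undefined ratio (zero denominator) is
reported as n/a rather than 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .mapper import ConceptAnnotation, SiteAnnotation

_BRACKET_RE = re.compile(r"\s*(?P<label>[^\[\]]*?)\s*\[(?P<cuis>[^:\]]*):(?P<semtypes>[^\]]*)\]\s*\Z")


@dataclass(frozen=True)
class GoldConcept:
    """One gold-standard concept: CUIs (possibly empty) and a label."""

    label: str
    cuis: tuple[str, ...]
    semtypes: tuple[str, ...] = ()


@dataclass
class GoldRecord:
    """Gold annotation of one raw site name; may have no mappable concept."""

    raw: str
    gold_concepts: List[GoldConcept] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.raw:
            raise ValueError("gold record with empty raw string")


@dataclass
class EvalResult:
    """Pooled TP/FP/FN with the derived recall and precision."""

    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None


def _compatible(pred: ConceptAnnotation, gold: GoldConcept) -> bool:
    if pred.cuis and gold.cuis:
        return bool(set(pred.cuis) & set(gold.cuis))
    return pred.surface_label.casefold() == gold.label.casefold()


def match_concepts(predicted: SiteAnnotation, gold: GoldRecord) -> Tuple[int, int, int]:
    """Count (tp, fp, fn) for one site via maximum bipartite matching.

    Each gold concept matches at most one prediction and vice versa;
    unmatched predictions are false positives, unmatched gold concepts
    false negatives.
    """
    preds = predicted.concepts
    golds = gold.gold_concepts
    if not preds or not golds:
        return 0, len(preds), len(golds)

    adj = np.array([[_compatible(p, g) for g in golds] for p in preds], dtype=np.int8)
    if not adj.any():
        return 0, len(preds), len(golds)
    assignment = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    tp = int((assignment >= 0).sum())
    return tp, len(preds) - tp, len(golds) - tp


def evaluate_corpus(
    predictions: Sequence[SiteAnnotation],
    golds: Sequence[GoldRecord],
) -> EvalResult:
    """Pool per-site counts into corpus-level recall/precision.

    Predictions and gold records must be aligned row for row on the raw
    string; any misalignment is fatal and reports the offending strings.
    """
    if len(predictions) != len(golds):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(golds)} gold records")
    mismatched = [
        (p.raw, g.raw) for p, g in zip(predictions, golds) if p.raw != g.raw
    ]
    if mismatched:
        shown = "; ".join(f"{p!r} != {g!r}" for p, g in mismatched[:5])
        raise ValueError(f"unaligned records: {shown}")

    tp = fp = fn = 0
    for pred, gold in zip(predictions, golds):
        t, p, n = match_concepts(pred, gold)
        tp, fp, fn = tp + t, fp + p, fn + n
    return EvalResult(tp=tp, fp=fp, fn=fn)


# --------------------------------------------------------------------------
# gold files and reports
# --------------------------------------------------------------------------

def parse_bracket_concept(text: str) -> GoldConcept:
    """Parse ``label [cui1,cui2:Ta,Tb]`` (empty CUI list renders ``[:Ta]``)."""
    m = _BRACKET_RE.match(text)
    if not m:
        raise ValueError(f"malformed bracket concept: {text!r}")
    split = lambda s: tuple(p.strip() for p in s.split(",") if p.strip())
    return GoldConcept(label=m.group("label"),
                       cuis=split(m.group("cuis")),
                       semtypes=split(m.group("semtypes")))


def gold_from_annotation(site: SiteAnnotation) -> GoldRecord:
    """Freeze a pipeline annotation as a gold record (concepts only)."""
    return GoldRecord(
        raw=site.raw,
        gold_concepts=[
            GoldConcept(label=a.surface_label, cuis=a.cuis, semtypes=a.semtypes)
            for a in site.concepts
        ],
    )


def write_gold(records: Sequence[GoldRecord], path: str | Path) -> None:
    rows = [
        {"raw": r.raw,
         "gold": ";".join(f"{c.label} [{','.join(c.cuis)}:{','.join(c.semtypes)}]"
                          for c in r.gold_concepts)}
        for r in records
    ]
    pd.DataFrame(rows, columns=["raw", "gold"]).to_csv(path, sep="\t", index=False)


def read_gold(path: str | Path) -> List[GoldRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"raw", "gold"} <= set(frame.columns):
        raise ValueError(f"gold file {path} needs columns raw, gold")
    records = []
    for row in frame.itertuples(index=False):
        concepts = [parse_bracket_concept(c) for c in row.gold.split(";") if c.strip()]
        records.append(GoldRecord(raw=row.raw, gold_concepts=concepts))
    return records


def format_report(result: EvalResult, name: str = "Customized NLP System") -> str:
    """Plain-text report mirroring the recall/precision table layout."""
    fmt = lambda x: "n/a" if x is None else f"{x:.2f}"
    lines = [
        "Application\tTP\tFP\tFN\tRecall TP/(TP+FN)\tPrecision TP/(TP+FP)",
        f"{name}\t{result.tp}\t{result.fp}\t{result.fn}"
        f"\t{fmt(result.recall)}\t{fmt(result.precision)}",
    ]
    return "\n".join(lines)
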