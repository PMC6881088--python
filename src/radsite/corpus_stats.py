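"""Descriptive statistics over a corpus of raw site-name strings.

Counting is case-sensitive — "Whole Brain", "whole brain" and "WHole
Brain" are distinct rows, exactly as they are distinct entries in the EMR
— even though annotation downstream is case-insensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Tuple, Union

import pandas as pd

from .mapper import Annotator

logger = logging.getLogger(__name__)

CorpusInput = Iterable[Union[str, Tuple[str, int]]]


@dataclass
class FrequencyTable:
    """Site-name strings with usage counts, most frequent first.

    Ties keep first-occurrence order; ``total_entries`` is the number of
    site-name entries represented, ``n_unique`` the number of distinct
    strings.
    """

    rows: List[Tuple[str, int]]

    @property
    def total_entries(self) -> int:
        return sum(c for _, c in self.rows)

    @property
    def n_unique(self) -> int:
        return len(self.rows)


def build_frequency_table(corpus: CorpusInput) -> FrequencyTable:
    """Count exact (case-sensitive) strings; accepts raw strings or
    pre-counted ``(string, count)`` pairs."""
    counts: dict[str, int] = {}
    for item in corpus:
        if isinstance(item, str):
            name, n = item, 1
        else:
            name, n = item[0], int(item[1])
        counts[name] = counts.get(name, 0) + n
    rows = sorted(counts.items(), key=lambda kv: -kv[1])  # stable: ties keep insertion order
    return FrequencyTable(rows=rows)


def top_k_share(
    table: FrequencyTable,
    k: int,
    basis: str = "total",
    denominator: Optional[int] = None,
) -> Tuple[int, float]:
    """Total uses of the ``k`` most frequent strings, and their share.

    The share's denominator is, by ``basis``: ``"total"`` — the table's
    total entry count; ``"unique"`` — its number of distinct strings; or an
    explicit ``denominator`` (used when the table at hand is a printed
    excerpt of a larger corpus whose size is known separately).  The share
    is a percentage rounded to one decimal.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > table.n_unique:
        logger.warning("k=%d exceeds %d unique rows; using all rows", k, table.n_unique)
        k = table.n_unique
    top_sum = sum(c for _, c in table.rows[:k])
    if denominator is None:
        if basis == "total":
            denominator = table.total_entries
        elif basis == "unique":
            denominator = table.n_unique
        else:
            raise ValueError(f"unknown basis {basis!r}")
    share = round(100.0 * top_sum / denominator, 1) if denominator else float("nan")
    return top_sum, share


def mean_uses_per_unique(table: FrequencyTable) -> Optional[float]:
    """Mean number of times a unique string was used, to two decimals;
    ``None`` for an empty table."""
    if table.n_unique == 0:
        return None
    return mean_uses(table.total_entries, table.n_unique)


def mean_uses(total_entries: int, n_unique: int) -> float:
    """``total_entries / n_unique`` to two decimals (for corpora known only
    through their summary counts)."""
    return round(total_entries / n_unique, 2)


def variant_group(
    table: FrequencyTable,
    annotator: Annotator,
    target_concept: Union[str, Iterable[str]],
) -> FrequencyTable:
    """Rows whose annotation contains the target concept, counts preserved.

    ``target_concept`` is a CUI or a preferred label (or a collection of
    either; any hit keeps the row).  An unknown concept simply yields an
    empty sub-table with a warning.
    """
    targets = {target_concept} if isinstance(target_concept, str) else set(target_concept)
    target_norm = {t.casefold() for t in targets}

    kept = []
    for name, count in table.rows:
        site = annotator.annotate(name)
        hit = any(
            (set(a.cuis) & targets) or a.surface_label.casefold() in target_norm
            for a in site.concepts
        )
        if hit:
            kept.append((name, count))
    if not kept:
        logger.warning("no rows annotate to %r", target_concept)
    return FrequencyTable(rows=kept)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_corpus(path: str | Path) -> FrequencyTable:
    """Read a corpus TSV/CSV with column ``site`` and optional ``count``;
    a headerless file is treated as one site name per line."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "site" not in frame.columns:
        names = [frame.columns[0]] + frame.iloc[:, 0].tolist()
        return build_frequency_table(n for n in names if n)
    if "count" in frame.columns:
        pairs = zip(frame["site"], (int(c) for c in frame["count"]))
        return build_frequency_table(pairs)
    return build_frequency_table(site for site in frame["site"] if site)


def write_table(table: FrequencyTable, path: str | Path) -> None:
    pd.DataFrame(table.rows, columns=["site", "count"]).to_csv(path, sep="\t", index=False)
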