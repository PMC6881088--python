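"""Resolution of unknown tokens by bigram context and edit distance.

Treatment-site strings are riddled with arbitrary abbreviations and typos
(``supraclavicular`` has been observed as SCV, SCL, S/C, SC, S Clav, Sc V,
Sclav, SCLV ...).  When a token is neither in the dictionary vocabulary nor
an English word, candidate replacements are proposed from bigram context —
vocabulary tokens seen after the left neighbor or before the right
neighbor in the terminology and development strings — and ranked by
Levenshtein distance, with the conditional bigram probability breaking
ties.  If no context is available (or it proposes nothing) the full token
vocabulary is the candidate pool, weighted by unigram frequency.

Everything here is deterministic: same inputs, same resolution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import edlib

from .normalizer import Token


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character edits turning ``a`` into ``b``."""
    if a == b:
        return 0
    if not a or not b:
        return len(a) + len(b)
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class BigramModel:
    """Adjacency statistics over word-token sequences.

    ``next_counts[t][u]`` counts occurrences of ``u`` immediately after
    ``t``; ``prev_counts`` is the mirror; ``unigram_counts`` counts token
    occurrences (so conditional probabilities are counts over the context
    token's occurrences).
    """

    next_counts: Dict[str, Counter] = field(default_factory=dict)
    prev_counts: Dict[str, Counter] = field(default_factory=dict)
    unigram_counts: Counter = field(default_factory=Counter)

    @property
    def total_tokens(self) -> int:
        return sum(self.unigram_counts.values())

    def p_next(self, context: str, word: str) -> float:
        denom = self.unigram_counts.get(context, 0)
        return self.next_counts.get(context, Counter()).get(word, 0) / denom if denom else 0.0

    def p_prev(self, context: str, word: str) -> float:
        denom = self.unigram_counts.get(context, 0)
        return self.prev_counts.get(context, Counter()).get(word, 0) / denom if denom else 0.0

    def p_unigram(self, word: str) -> float:
        total = self.total_tokens
        return self.unigram_counts.get(word, 0) / total if total else 0.0


def train_bigrams(term_corpus: Iterable[Sequence[str]]) -> BigramModel:
    """Count adjacent ordered token pairs, once per occurrence.

    ``term_corpus`` holds word-token sequences: tokenized multi-word
    dictionary terms and, optionally, tokenized development-set strings.
    """
    model = BigramModel()
    for seq in term_corpus:
        for tok in seq:
            model.unigram_counts[tok] += 1
        for left, right in zip(seq, seq[1:]):
            model.next_counts.setdefault(left, Counter())[right] += 1
            model.prev_counts.setdefault(right, Counter())[left] += 1
    return model


@dataclass(frozen=True)
class Candidate:
    """A proposed replacement for an unknown token."""

    word: str
    distance: int
    context_prob: float
    origin: str  # "left_context" | "right_context" | "global"


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving one token."""

    token_index: int
    status: str  # "exact" | "english" | "fuzzy" | "unresolved"
    resolved_word: Optional[str] = None
    candidate: Optional[Candidate] = None


@dataclass
class ResolverConfig:
    """Knobs of the abbreviation-resolution step.

    max_distance
        Acceptance threshold on edit distance.  ``"auto"`` scales with the
        candidate: ``max(1, len(candidate) // 3)`` — one edit is always
        tolerated, longer words may drift further.
    rank_order
        ``"distance_first"`` picks the closest candidate and uses context
        probability only for ties; ``"probability_first"`` inverts that.
    """

    max_distance: int | str = "auto"
    rank_order: str = "distance_first"

    def threshold_for(self, candidate_word: str) -> int:
        if self.max_distance == "auto":
            return max(1, len(candidate_word) // 3)
        return int(self.max_distance)


def generate_candidates(
    unknown: Token | str,
    left: Optional[str],
    right: Optional[str],
    model: BigramModel,
    vocab: Iterable[str],
) -> List[Candidate]:
    """Propose vocabulary replacements for an unknown token.

    Candidates are vocabulary tokens observed after ``left`` and/or before
    ``right``; when neither context yields anything, every vocabulary token
    is a candidate with its unigram relative frequency.  Each candidate
    carries its Levenshtein distance to the unknown token.  The list is
    sorted by (distance, -probability, word); an empty vocabulary yields an
    empty list.
    """
    norm = unknown.norm if isinstance(unknown, Token) else unknown.casefold()
    vocab = set(vocab)
    pool: Dict[str, Candidate] = {}

    def offer(word: str, prob: float, origin: str) -> None:
        if word not in vocab:
            return
        prior = pool.get(word)
        if prior is None or prob > prior.context_prob:
            pool[word] = Candidate(word=word, distance=levenshtein(norm, word),
                                   context_prob=prob, origin=origin)

    if left is not None:
        for word in model.next_counts.get(left, ()):  # tokens seen after left
            offer(word, model.p_next(left, word), "left_context")
    if right is not None:
        for word in model.prev_counts.get(right, ()):  # tokens seen before right
            offer(word, model.p_prev(right, word), "right_context")

    if not pool:
        for word in vocab:
            pool[word] = Candidate(word=word, distance=levenshtein(norm, word),
                                   context_prob=model.p_unigram(word), origin="global")

    return sorted(pool.values(), key=lambda c: (c.distance, -c.context_prob, c.word))


def resolve_token(
    unknown: Token | str,
    left: Optional[str],
    right: Optional[str],
    model: BigramModel,
    vocab: Iterable[str],
    config: Optional[ResolverConfig] = None,
) -> Resolution:
    """Pick the best qualifying candidate for an unknown token.

    A candidate qualifies when its distance is within the configured
    threshold.  Under the default ranking the closest candidate wins, with
    higher context probability then lexicographic word order breaking
    ties; ``probability_first`` swaps the first two keys.  No qualifying
    candidate means the token stays unresolved.
    """
    config = config or ResolverConfig()
    index = unknown.index if isinstance(unknown, Token) else -1
    candidates = generate_candidates(unknown, left, right, model, vocab)
    qualifying = [c for c in candidates if c.distance <= config.threshold_for(c.word)]
    if not qualifying:
        return Resolution(token_index=index, status="unresolved")

    if config.rank_order == "probability_first":
        key = lambda c: (-c.context_prob, c.distance, c.word)
    else:
        key = lambda c: (c.distance, -c.context_prob, c.word)
    best = min(qualifying, key=key)
    return Resolution(token_index=index, status="fuzzy", resolved_word=best.word, candidate=best)
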