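"""Independent reference implementations used as test oracles.

Deliberately naive: plain dynamic programming, exhaustive enumeration and
brute-force search, sharing no code with the package paths they check.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


def segment_oracle(words: Sequence[str], terms: set[str]) -> List[Tuple[int, int, bool]]:
    """Leftmost-longest segmentation by exhaustive window enumeration.

    Returns (start, end, matched) pieces: at each position every window
    length is tried and the longest whose joined words form a term wins;
    otherwise the single word is an unmatched piece.
    """
    out: List[Tuple[int, int, bool]] = []
    i = 0
    while i < len(words):
        matches = [
            j for j in range(i + 1, len(words) + 1)
            if " ".join(words[i:j]) in terms
        ]
        if matches:
            out.append((i, max(matches), True))
            i = max(matches)
        else:
            out.append((i, i + 1, False))
            i += 1
    return out


def max_matching_bruteforce(compat: Sequence[Sequence[bool]]) -> int:
    """Maximum bipartite matching size by exhaustive recursive search."""
    n_pred = len(compat)
    n_gold = len(compat[0]) if n_pred else 0

    def search(i: int, used: frozenset) -> int:
        if i == n_pred:
            return 0
        best = search(i + 1, used)  # leave prediction i unmatched
        for j in range(n_gold):
            if j not in used and compat[i][j]:
                best = max(best, 1 + search(i + 1, used | {j}))
        return best

    return search(0, frozenset())


def count_pairs(sequences: Sequence[Sequence[str]]) -> Dict[Tuple[str, str], int]:
    """Brute-force tally of adjacent ordered token pairs."""
    counts: Dict[Tuple[str, str], int] = {}
    for seq in sequences:
        for k in range(len(seq) - 1):
            pair = (seq[k], seq[k + 1])
            counts[pair] = counts.get(pair, 0) + 1
    return counts
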