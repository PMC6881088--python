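# Methods

## Problem and model

A radiotherapy treatment site is the free-text label a provider types for
one radiation field in a record-and-verify EMR. The label denotes one or
more clinical concepts (an anatomical target, a laterality, a device, a
procedure), but its surface form is uncontrolled: arbitrary casing,
abbreviations peculiar to radiation oncology, typos, trailing decorations
and inconsistent separators. `radsite` models normalization as a
three-stage deterministic pipeline — tokenize, resolve, map — over a
task-specific terminology. There is no randomness anywhere in annotation;
identical input, terminology and configuration give identical output.

## Terminology

The dictionary merges two layers keyed by normalized surface form:

- a **semantic-type-filtered subset** of a UMLS-style concept source.
  The default filter is the topographical types T023 (Body Part, Organ, or
  Organ Component), T029 (Body Location or Region), T030 (Body Space or
  Junction) and T082 (Spatial Concept). A surface string is admitted when
  its CUI carries at least one admitted type, and the entry keeps only the
  admitted types. One normalized term may carry several CUIs; they are
  kept as an ordered list in source order and no disambiguation among them
  is attempted.
- a **curated supplement** of abbreviations and domain concepts the subset
  misses. Both the abbreviation surface and its expansion become lookup
  keys for the same entry; supplement entries may have no CUI (e.g. the
  midline block) and shadow subset entries on exact surface collision,
  since the supplement exists to correct gaps.

Lookup keys are produced by tokenizing the term and joining the lowercased
tokens with single spaces. This subsumes lowercase/whitespace-collapse for
ordinary terms and additionally makes punctuation-bearing surfaces
(`S/C`, `whole-brain radiotherapy`) matchable by the same window-join rule
the mapper uses.

The embedded fixture lexicon reconstructs the reference vocabulary: 15
subset concepts with their exact CUI/semantic-type lists and 15 supplement
surfaces (8 spellings of supraclavicular, WBRT/wbxrt, MLB, Prox, SV, PCI,
RT). PCI and RT carry no CUI claim — only their expansions and the
procedure type T061. Where the reference output cases the same concept's
display label inconsistently, one preferred label per concept is kept;
coded content is unaffected.

## Tokenization

Whitespace separates tokens; a run of letters/digits is a word; a run of
digits (optionally prefixed `#`) is a number; any other character stands
alone as punctuation. Spans are recorded so the raw string is recoverable.
Numbers are preserved as tokens but never annotated — trailing field
numbers (`whole brain 2`) carry no concept. Non-ASCII letters are word
characters; norms use `str.casefold()`.

## Unknown-token resolution

Resolution statuses, in order of attempt:

1. **exact** — the token is in the terminology's token vocabulary.
   Supplement surfaces therefore short-circuit here; `SCV` never reaches
   the fuzzy stage.
2. **english** — the token is in a configurable English wordlist. The word
   is considered understood (no fuzzy rescue is attempted) but produces no
   concept unless it also participates in a terminology term. The default
   list is a small set of ordinary words observed decorating site names
   (`Retreat`, `photons`, `Proton`, `Primary`, `modulate`, ...), and a
   newline-delimited wordlist can be supplied via configuration.
3. **fuzzy** — candidates are generated from bigram context and ranked by
   edit distance.
4. **unresolved** — no qualifying candidate; the token is reported in the
   annotation's unresolved list.

**Bigram statistics** are trained on the multi-token terminology terms and
on development-set strings (both by default; the fixture pipeline trains
on its terms plus the embedded reference site names). Only word tokens
enter training; punctuation and numbers are dropped. For context token
`c`, P(w | c) = count(c, w) / count(c) with the unigram occurrence count
as denominator.

**Candidate generation** for an unknown token takes the vocabulary tokens
observed after the left neighbor and before the right neighbor (union,
keeping the higher probability when a word arrives from both sides). The
neighbor used as context is the nearest word token — punctuation and
numbers are skipped, consistent with training — provided it resolved
exactly or as English. Whenever context proposes nothing (including the
no-context case), the full token vocabulary becomes the candidate pool
weighted by unigram relative frequency.

**Ranking.** Edit distance is the Levenshtein distance (unit insertions,
deletions, substitutions; computed by `edlib`). A candidate qualifies when
its distance is within the threshold; among qualifying candidates the
minimum distance wins, ties broken by higher context probability, then
lexicographic word order. "Closest first, probability as tie-break"
preserves the edit distance as the primary signal; the alternative
probability-first ordering is available via `rank_order`.

**Threshold.** `max_distance="auto"` (default) admits
`max(1, len(candidate) // 3)` edits: one edit is always tolerated, so
short abbreviations remain reachable, and longer words may drift
proportionally further. A fixed integer threshold can be configured
instead. The per-candidate scaling means a corrupted token can be rescued
by a long candidate while a short candidate at the same distance is
rejected — deliberate, as one edit in a three-letter token is a different
word more often than not.

## Term assembly

Greedy leftmost-longest matching: at each position, the longest window of
tokens — starting and ending on a resolved word, possibly spanning
punctuation or numbers — whose joined resolved forms equal a terminology
key becomes one concept annotation, and matching restarts after it. The
window length is bounded by the longest term in the terminology. Greedy
segmentation (rather than global optimization) is deterministic and
reproduces every reference example; an exhaustive enumeration oracle in
the test suite guards the equivalence on random small instances.

Punctuation annotations carry the sentinel semantic type `T000`. In
bracket output only the slash is printed; the hyphen is treated as a
silent separator (it joins or separates terms but is not itself shown) —
this matches the reference output, which prints a `PUNC` cell for
`Prostate/Prox SV` but none for `SCV-MLB`. Both are excluded from
evaluation either way.

## Evaluation

Entity-level, concept-by-concept. Punctuation and unmapped annotations are
excluded from predictions. A prediction is compatible with a gold concept
when the two share at least one CUI; when either side has no CUIs,
case-insensitive label equality is the fallback. True positives are the
size of a **maximum bipartite matching** between predictions and gold
concepts (computed with `scipy`), so each gold concept matches at most
once and the count is independent of annotation order; an exhaustive
matching oracle verifies this on small instances. Counts are pooled over
the corpus (micro-averaged): recall = TP/(TP+FN), precision = TP/(TP+FP).
A zero denominator is reported as `n/a`, never as 0, to avoid silently
inflating or deflating scores. The identities TP+FN = number of gold
concepts and TP+FP = number of predicted concepts hold on every run and
are asserted in the acceptance checks.

The CUI-overlap criterion for a true positive is this package's decision;
exact-list equality and span-level alternatives would both be stricter,
and the overlap rule is the natural reading for entries that legitimately
carry several CUIs.

## Corpus statistics

Frequency tables count exact strings case-sensitively (distinct casings
are distinct EMR entries), sorted by count with ties in first-occurrence
order. The top-k share supports two denominator bases — the table's total
entry count or its number of unique strings — plus an explicit override
for the common situation where the table at hand is a printed excerpt of a
larger corpus whose summary counts are known separately. Variant grouping
annotates each row and keeps those whose concepts hit a target CUI or
label. `mean_uses` computes total entries per unique string to two
decimals.

## Synthetic-data generator

The generator emulates the documented noise taxonomy rather than a generic
typo model. Operations, applied in fixed order to the whitespace-chunked
canonical string: abbreviation substitution (a supplement expansion
occurring in the string is replaced by one of its surfaces; longer
expansions claim their span first so a short expansion never rewrites part
of a longer one), single-character edits per chunk (up to `max_edits`),
case mangling per chunk, separator swaps (space to `-` or `/`), and a
trailing decoration (`2`, `#2`, `PCI`, `RT`, `Retreat`, `photons`). Every
case records a complete operation log; `replay(canonical, ops)`
reconstructs the corrupted string exactly, and the manifest written next
to a generated corpus contains the log for every case.

Gold annotations are computed from the clean canonical string and frozen,
keeping the generator independent of resolver behavior. Default
probabilities (0.3 abbreviation, 0.3 case, 0.1 edit, 0.1 separator, 0.1
decoration) reflect that casing and abbreviation variation dominate the
observed spellings while typos and decorations are minority noise. Two
presets mark the regimes the tests probe: `lookup_noise` (case +
abbreviation only — exact-lookup paths, which must score perfectly) and
`edit_noise` (at most one character edit per chunk — the resolver's
domain).

The generator does not model inter-physician labeling habits, patient
structure, prescription hierarchies, or out-of-vocabulary concepts; a
perfect score on `lookup_noise` corpora demonstrates the dictionary and
normalization machinery, not performance on clinical free text at large.

## Check sizes and determinism

The accuracy checks use 1,000-case corpora (5 seeds, pooled, for the
edit-noise recall floor of 0.95); oracle equivalence is exhaustive for
edit distance over all string pairs of length ≤ 6 on a three-letter
alphabet and sampled (500 random instances) for term assembly. All
randomness flows from explicit integer seeds through `random.Random`;
CLI runs are byte-reproducible under a fixed seed, verified by double-run
hash comparison.

## Known limitations

- The headline accuracy of the original clinical deployment cannot be
  re-measured here: the institutional test set and its oncologist-reviewed
  gold standard are not distributable. The synthetic corpora bound the
  pipeline's behavior under the documented noise classes instead.
- The fixture lexicon covers the reference vocabulary only; real use
  requires a licensed concept source, which the pipe-delimited reader and
  column-map options are designed to consume.
- One reference row carries an unexplained parenthetical (`(222.0)`) after
  a concept; it is not reproduced.
- Laterality and negation are taken literally from tokens; no inference is
  attempted.
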