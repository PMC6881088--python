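# radsite

Normalization of free-text radiotherapy treatment-site names to coded
concepts.

Radiation-oncology record-and-verify EMRs let providers type the treatment
site of each radiation field as free text. The result is a glut of
spellings for the same clinical entity — whole-brain treatment alone shows
up as `Whole Brain`, `WBRT`, `wbxrt`, `WHole Brain`, `whole brain-2`,
`WBRT (PCI)` and two dozen more — which makes it nearly impossible to
assemble cohorts of similarly treated patients from the EMR. `radsite`
maps those strings onto coded concepts: UMLS-style Concept Unique
Identifiers (CUIs) with semantic-type codes.

It is intended for informaticists and radiation oncologists building
structured treatment repositories from EMR extracts.

## Method

The pipeline has three deterministic stages:

1. **Tokenize.** A site name splits into classified tokens: words, numbers
   (`2`, `#2`) and single-character punctuation (`/`, `-`, `(`, ...).

2. **Resolve.** Each word token is looked up in the application
   terminology — a UMLS-style concept source filtered to topographical
   semantic types (body part T023, body region T029, body space/junction
   T030, spatial concept T082), merged with a curated supplement of
   radiotherapy abbreviations and concepts the subset misses (SCV, MLB,
   WBRT, ...). Tokens that miss the terminology are checked against an
   English wordlist; tokens that miss both are treated as unknown
   abbreviations or typos and resolved from bigram context: candidate
   words are the vocabulary tokens observed adjacent to the unknown
   token's neighbors (falling back to the whole vocabulary when context
   proposes nothing), each candidate gets its Levenshtein distance
   d(unknown, candidate), and the closest candidate within a threshold
   wins, with the conditional bigram probability P(candidate | context)
   breaking ties.

3. **Map.** Resolved tokens are assembled greedily left-to-right into the
   longest contiguous runs matching terminology entries; each matched run
   becomes one concept annotation `label [CUI1,CUI2,...:T1,T2,...]`.

Entity-level evaluation counts a predicted concept as a true positive when
it shares a CUI with an unused gold concept (label equality for CUI-less
supplement concepts), pooled over the corpus: recall = TP/(TP+FN),
precision = TP/(TP+FP).

An embedded fixture lexicon (reconstructed reference vocabulary) makes the
whole pipeline runnable with no UMLS license, and a seeded synthetic-noise
generator produces labeled corpora that emulate the observed noise: case
mangling, abbreviation substitution, single-character typos, decorations
(`#2`, `PCI`, `Retreat`) and separator swaps.

## Worked example

```sh
$ printf 'site\nSCV-MLB\nProstate/Prox SV\nWBRT\nwhole brin\n' > demo.tsv
$ radsite annotate --fixture demo.tsv
supraclavicular region [C0446461:T029]	midline block [:T169]
Prostate [C0033572,C1278980,C1882832:T023]	/ [PUNC:T000]	Proximal [C0205107:T082]	Seminal Vesicle [C1278984:T023]
whole-brain radiotherapy [C1520143:T061]
whole [C0444667:T081]	brain [C0006104,C1269537,C1882598,C1273723:T023,T029]
```

Reading the output: `SCV-MLB` resolves two curated abbreviations — the
supraclavicular region (CUI C0446461, semantic type T029 "Body Location or
Region") and the midline block, a field-shaping device with no CUI in the
source vocabulary (`[:T169]`). `Prostate/Prox SV` yields three anatomical
concepts plus the slash, annotated with the punctuation sentinel
`[PUNC:T000]`. `WBRT` maps as a whole to whole-brain radiotherapy (a
therapeutic procedure, T061). In `whole brin`, the typo `brin` is not in
the terminology; the bigram model proposes `brain` (observed after
`whole`), one edit away, and the token is rescued.

The same pipeline is available as a library:

```python
from radsite import fixture_annotator

annotator = fixture_annotator()
site = annotator.annotate("whole brin")
for a in site.annotations:
    print(a.kind, "|", a.bracket())
# concept | whole [C0444667:T081]
# concept | brain [C0006104,C1269537,C1882598,C1273723:T023,T029]
```

Other subcommands: `radsite stats` (frequency tables, top-k usage share,
mean uses per unique site), `radsite evaluate` (recall/precision against a
gold TSV), `radsite synth` (seeded synthetic corpora with gold labels and
a replayable corruption manifest), `radsite build-lexicon` (build and
serialize a terminology from pipe-delimited concept/semantic-type files
and a supplement TSV).

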