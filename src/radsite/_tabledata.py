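"""Embedded reference data for the worked example.

A small, self-contained snapshot of the institutional vocabulary: the
concepts behind the most frequent treatment-site strings, the curated
abbreviation supplement, the frequency table of the top site names, and
the 27 observed spellings of whole-brain radiotherapy.  These power the
fixture lexicon and the regression/acceptance checks without requiring a
UMLS license or access to the original EMR extract.

Each UMLS-subset tuple is ``(preferred_label, cuis, semtypes)``; the
normalized surface key is derived from the label.  Supplement rows are
``(surface, expansion, cuis, semtypes)``.
"""

# --- concepts reachable through the UMLS semantic-type subset -------------

UMLS_FIXTURE_CONCEPTS = [
    ("pelvis", ["C0030797", "C0559769", "C0030786", "C1279864"], ["T023", "T029", "T030"]),
    ("supraclavicular region", ["C0446461"], ["T029"]),
    ("whole", ["C0444667"], ["T081"]),
    ("brain", ["C0006104", "C1269537", "C1882598", "C1273723"], ["T023", "T029"]),
    ("tumor", ["C0027651", "C3273930", "C1578706"], ["T191", "T170", "T033"]),
    ("bed", ["C1547114"], ["T082"]),
    ("Boost", ["C1511253"], ["T169"]),
    ("Left Breast", ["C0222601"], ["T023"]),
    ("right", ["C0205090"], ["T082"]),
    ("Chest wall", ["C0205076"], ["T023"]),
    ("Right Breast", ["C0222600"], ["T023"]),
    ("Left", ["C0205091"], ["T082"]),
    ("Prostate", ["C0033572", "C1278980", "C1882832"], ["T023"]),
    ("Proximal", ["C0205107"], ["T082"]),
    ("Seminal Vesicle", ["C1278984"], ["T023"]),
]

# --- manually curated supplement: domain abbreviations and concepts -------
# Supplement rows may have no CUI (concepts missing from the UMLS subset,
# e.g. the field-shaping midline block).

SUPPLEMENT_FIXTURE = [
    ("SCV", "supraclavicular region", ["C0446461"], ["T029"]),
    ("SCL", "supraclavicular region", ["C0446461"], ["T029"]),
    ("S/C", "supraclavicular region", ["C0446461"], ["T029"]),
    ("SC", "supraclavicular region", ["C0446461"], ["T029"]),
    ("S Clav", "supraclavicular region", ["C0446461"], ["T029"]),
    ("Sc V", "supraclavicular region", ["C0446461"], ["T029"]),
    ("Sclav", "supraclavicular region", ["C0446461"], ["T029"]),
    ("SCLV", "supraclavicular region", ["C0446461"], ["T029"]),
    ("WBRT", "whole-brain radiotherapy", ["C1520143"], ["T061"]),
    ("wbxrt", "whole-brain radiotherapy", ["C1520143"], ["T061"]),
    ("MLB", "midline block", [], ["T169"]),
    ("Prox", "Proximal", ["C0205107"], ["T082"]),
    ("SV", "Seminal Vesicle", ["C1278984"], ["T023"]),
    ("PCI", "prophylactic cranial irradiation", [], ["T061"]),
    ("RT", "radiotherapy", [], ["T061"]),
]

# --- the most frequent site names, with their expected concept output -----
# (raw string, frequency, expected bracket-serialized concept annotations).
# Expected punctuation annotations are included only where the reference
# output prints one (the slash); label casing is compared case-insensitively
# because the reference output itself cases the same concept both ways.

TOP_SITES = [
    ("Pelvis", 450, ["pelvis [C0030797,C0559769,C0030786,C1279864:T023,T029,T030]"]),
    ("SCV", 428, ["supraclavicular region [C0446461:T029]"]),
    ("Whole Brain", 298, ["whole [C0444667:T081]", "brain [C0006104,C1269537,C1882598,C1273723:T023,T029]"]),
    ("whole brain", 266, ["whole [C0444667:T081]", "brain [C0006104,C1269537,C1882598,C1273723:T023,T029]"]),
    ("Tumor Bed Boost", 262, ["tumor [C0027651,C3273930,C1578706:T191,T170,T033]", "bed [C1547114:T082]", "Boost [C1511253:T169]"]),
    ("Left Breast", 260, ["Left Breast [C0222601:T023]"]),
    ("Right Chest Wall", 241, ["right [C0205090:T082]", "Chest wall [C0205076:T023]"]),
    ("Right Breast", 239, ["Right Breast [C0222600:T023]"]),
    ("Left Chest Wall", 206, ["Left [C0205091:T082]", "Chest wall [C0205076:T023]"]),
    ("pelvis", 198, ["pelvis [C0030797,C0559769,C0030786,C1279864:T023,T029,T030]"]),
    ("Boost", 194, ["Boost [C1511253:T169]"]),
    ("Whole brain", 189, ["whole [C0444667:T081]", "brain [C0006104,C1269537,C1882598,C1273723:T023,T029]"]),
    ("Prostate/Prox SV", 159, ["Prostate [C0033572,C1278980,C1882832:T023]", "/ [PUNC:T000]", "Proximal [C0205107:T082]", "Seminal Vesicle [C1278984:T023]"]),
    ("boost", 148, ["Boost [C1511253:T169]"]),
    ("SCV-MLB", 147, ["supraclavicular region [C0446461:T029]", "midline block [:T169]"]),
    ("SCV MLB", 139, ["supraclavicular region [C0446461:T029]", "midline block [:T169]"]),
    ("Right breast", 134, ["Right Breast [C0222600:T023]"]),
    ("Prostate", 129, ["Prostate [C0033572,C1278980,C1882832:T023]"]),
    ("WBRT", 128, ["whole-brain radiotherapy [C1520143:T061]"]),
]

# --- observed spellings of whole-brain radiotherapy, with frequencies -----

WHOLE_BRAIN_VARIANTS = [
    ("Whole Brain", 298),
    ("whole brain", 266),
    ("Whole brain", 189),
    ("WBRT", 128),
    ("Brain", 113),
    ("brain", 21),
    ("wbxrt", 8),
    ("WHOLE BRAIN", 6),
    ("Whole brain 2", 3),
    ("whole brain PCI", 3),
    ("whole Brain", 3),
    ("Whole Brain #2", 3),
    ("Whole Brain PCI", 3),
    ("Whole Brain Retreat", 2),
    ("WHole Brain", 2),
    ("whole brain 1", 2),
    ("Whole Brain RT", 2),
    ("WBRT (PCI)", 2),
    ("whole brain-2", 1),
    ("Whole Brain photons", 1),
    ("PCI, whole brain", 1),
    ("Whole brain/eyes/BOS", 1),
    ("Whole Brain Proton", 1),
    ("whole brain modulate", 1),
    ("whole brain 2", 1),
    ("Whole brain Primary", 1),
    ("Whole Brain-PCI", 1),
]

# Corpus-wide counts from the source EMR extract (the full corpus itself is
# not redistributable): number of site-name entries and of unique strings.
CORPUS_TOTAL_ENTRIES = 31118
CORPUS_UNIQUE_SITES = 11018

# --- default English wordlist --------------------------------------------
# Ordinary English words seen decorating site names.  A hit here marks the
# token as understood (so no fuzzy rescue is attempted) but contributes no
# concept unless the word is also a dictionary token.

DEFAULT_ENGLISH_WORDS = frozenset(
    {
        "retreat", "photons", "photon", "proton", "protons", "primary",
        "modulate", "modulated", "eyes", "eye", "initial", "final", "total",
        "upper", "lower", "with", "and", "only", "plus", "new", "old",
        "field", "fields",
    }
)
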