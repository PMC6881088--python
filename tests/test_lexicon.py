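import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radsite.lexicon import (
    ConceptEntry,
    Lexicon,
    SupplementRecord,
    build_fixture_lexicon,
    fixture_supplement_records,
    load_supplement,
    merge_supplement,
    read_concept_source,
    read_lexicon,
    write_lexicon,
)
from radsite import _tabledata


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _source(tmp_path, concept_rows, semtype_rows):
    return (
        _write(tmp_path / "concepts.psv", concept_rows or [""]),
        _write(tmp_path / "semtypes.psv", semtype_rows or [""]),
    )


class TestReadConceptSource:
    def test_admits_by_semantic_type(self, tmp_path):
        concepts, semtypes = _source(tmp_path, ["Pelvis|C0030797"], ["C0030797|T023"])
        lex = read_concept_source(concepts, semtypes, {"T023"})
        (entry,) = lex.lookup("pelvis")
        assert entry.cuis == ["C0030797"]
        assert entry.semtypes == ["T023"]
        assert entry.preferred_label == "Pelvis"
        assert lex.lookup("PELVIS") == [entry]  # case-insensitive lookup

    def test_empty_concept_file(self, tmp_path):
        concepts, semtypes = _source(tmp_path, [], ["C1|T023"])
        lex = read_concept_source(concepts, semtypes, {"T023"})
        assert lex.entries == {}

    def test_multi_string_cui_keeps_admitted_types_only(self, tmp_path):
        surfaces = ["Arm", "arm NOS", "Upper limb", "limb, upper", "ARM"]
        concepts, semtypes = _source(
            tmp_path,
            [f"{s}|C0003798" for s in surfaces],
            ["C0003798|T023", "C0003798|T047"],
        )
        lex = read_concept_source(concepts, semtypes, {"T023"})
        # brute-force re-filter: every surface is admitted, 'Arm'/'ARM' merge
        admitted = {lex.lookup(s)[0].term for s in surfaces}
        assert admitted == {"arm", "arm nos", "upper limb", "limb , upper"}
        for key in admitted:
            (entry,) = lex.entries[key]
            assert entry.semtypes == ["T023"]

    def test_excluded_semtype_rejected(self, tmp_path):
        concepts, semtypes = _source(tmp_path, ["Fever|C0015967"], ["C0015967|T184"])
        lex = read_concept_source(concepts, semtypes, {"T023"})
        assert lex.lookup("fever") == []

    def test_malformed_rows_skipped(self, tmp_path):
        concepts, semtypes = _source(
            tmp_path, ["Pelvis|C1", "justonefield", "|C2"], ["C1|T023", "C2|notatype"]
        )
        lex = read_concept_source(concepts, semtypes, {"T023"})
        assert list(lex.entries) == ["pelvis"]

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_concept_source(tmp_path / "nope.psv", tmp_path / "also_nope.psv", {"T023"})

    def test_empty_filter_rejected(self, tmp_path):
        concepts, semtypes = _source(tmp_path, ["a|C1"], ["C1|T023"])
        with pytest.raises(ValueError):
            read_concept_source(concepts, semtypes, set())


@given(
    rows=st.lists(
        st.tuples(
            st.text(alphabet="abc ", min_size=1, max_size=6).filter(str.strip),
            st.sampled_from(["C1", "C2", "C3", "C4"]),
        ),
        max_size=20,
    ),
    types=st.dictionaries(
        st.sampled_from(["C1", "C2", "C3", "C4"]),
        st.sets(st.sampled_from(["T023", "T029", "T047", "T184"]), min_size=1),
    ),
)
@settings(max_examples=60, deadline=None)
def test_filter_soundness(tmp_path_factory, rows, types):
    """Every admitted entry carries >=1 admitted type, and exactly the
    strings a brute-force line scan admits are present."""
    tmp = tmp_path_factory.mktemp("src")
    flt = {"T023", "T029"}
    concepts = _write(tmp / "c.psv", [f"{s}|{c}" for s, c in rows] or [""])
    semtypes = _write(
        tmp / "s.psv", [f"{c}|{t}" for c, ts in types.items() for t in ts] or [""]
    )
    lex = read_concept_source(concepts, semtypes, flt)

    expected_keys = {
        " ".join(s.casefold().split())
        for s, c in rows
        if types.get(c) and types[c] & flt
    }
    assert set(lex.entries) == expected_keys
    for bucket in lex.entries.values():
        for entry in bucket:
            assert set(entry.semtypes) <= flt


class TestSupplement:
    HEADER = "surface\texpansion\tcuis\tsemtypes"

    def test_load_basic_and_blank_cuis(self, tmp_path):
        path = _write(
            tmp_path / "supp.tsv",
            [self.HEADER,
             "WBRT\twhole-brain radiotherapy\tC1520143\tT061",
             "MLB\tmidline block\t\tT169"],
        )
        records = load_supplement(path)
        assert records[0] == SupplementRecord(
            "WBRT", "whole-brain radiotherapy", ["C1520143"], ["T061"])
        assert records[1].cuis == []

    def test_empty_file(self, tmp_path):
        assert load_supplement(_write(tmp_path / "supp.tsv", [self.HEADER])) == []

    def test_identical_duplicates_collapse(self, tmp_path):
        row = "SV\tSeminal Vesicle\tC1278984\tT023"
        records = load_supplement(_write(tmp_path / "supp.tsv", [self.HEADER, row, row]))
        assert len(records) == 1

    def test_conflicting_duplicates_fatal(self, tmp_path):
        path = _write(
            tmp_path / "supp.tsv",
            [self.HEADER,
             "SV\tSeminal Vesicle\tC1278984\tT023",
             "SV\tsigmoid volvulus\tC0158738\tT047"],
        )
        with pytest.raises(ValueError, match="SV"):
            load_supplement(path)

    def test_blank_semtypes_fatal(self, tmp_path):
        path = _write(tmp_path / "supp.tsv", [self.HEADER, "SV\tSeminal Vesicle\tC1278984\t"])
        with pytest.raises(ValueError):
            load_supplement(path)

    def test_merge_surface_and_expansion_resolve_identically(self):
        lex = Lexicon()
        merge_supplement(lex, [SupplementRecord(
            "SCV", "supraclavicular region", ["C0446461"], ["T029"])])
        for key in ("scv", "SCV", "supraclavicular region"):
            (entry,) = lex.lookup(key)
            assert (entry.cuis, entry.semtypes) == (["C0446461"], ["T029"])
            assert entry.source == "supplement"

    def test_merge_onto_empty_lexicon(self):
        lex = merge_supplement(Lexicon(), fixture_supplement_records())
        assert all(e.source == "supplement" for b in lex.entries.values() for e in b)

    def test_supplement_shadows_umls_on_collision(self):
        lex = Lexicon()
        lex.add(ConceptEntry("scv", ["C9999999"], ["T047"], "umls_subset", "scv"))
        merge_supplement(lex, [SupplementRecord("SCV", "supraclavicular region",
                                                ["C0446461"], ["T029"])])
        entries = lex.lookup("scv")
        assert [e.source for e in entries] == ["supplement", "umls_subset"]
        assert entries[0].cuis == ["C0446461"]


class TestFixtureLexicon:
    def test_pelvis_entry(self, fixture_lexicon):
        (entry,) = [e for e in fixture_lexicon.lookup("pelvis") if e.source == "umls_subset"]
        assert entry.cuis == ["C0030797", "C0559769", "C0030786", "C1279864"]
        assert entry.semtypes == ["T023", "T029", "T030"]

    def test_wbrt_abbreviation(self, fixture_lexicon):
        entry = fixture_lexicon.lookup("wbrt")[0]
        assert (entry.cuis, entry.semtypes) == (["C1520143"], ["T061"])
        assert entry.preferred_label == "whole-brain radiotherapy"

    def test_unknown_term(self, fixture_lexicon):
        assert fixture_lexicon.lookup("zzz") == []

    def test_every_reference_concept_retrievable(self, fixture_lexicon):
        for label, cuis, semtypes in _tabledata.UMLS_FIXTURE_CONCEPTS:
            hits = [e for e in fixture_lexicon.lookup(label)
                    if e.cuis == list(cuis) and e.semtypes == list(semtypes)]
            assert hits, label
        for surface, expansion, _, _ in _tabledata.SUPPLEMENT_FIXTURE:
            assert fixture_lexicon.lookup(surface), surface
            assert fixture_lexicon.lookup(expansion), expansion

    def test_token_vocabulary_covers_entry_terms(self, fixture_lexicon):
        from radsite.normalizer import TokenKind, tokenize
        for term in fixture_lexicon.entries:
            for tok in tokenize(term):
                if tok.kind is TokenKind.WORD:
                    assert fixture_lexicon.has_token(tok.norm)


def test_round_trip_serialization(tmp_path, fixture_lexicon):
    path = tmp_path / "lexicon.tsv"
    write_lexicon(fixture_lexicon, path)
    loaded = read_lexicon(path)
    assert loaded.entries == fixture_lexicon.entries
    assert loaded.token_vocabulary == fixture_lexicon.token_vocabulary
    assert loaded.semtype_filter == fixture_lexicon.semtype_filter
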