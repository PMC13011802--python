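"""Dictionary construction, normalization, filtering and lookup."""

import io

import pytest
from hypothesis import given, strategies as st

from glycolit import (
    Dictionary,
    Entry,
    compile_from_ontology,
    jaccard,
    load_delimited,
    normalize_label,
    write_delimited,
)
from glycolit._porter import stem

# Frozen expected stems: hand-derived by applying the classic Porter
# algorithm; most pairs are the algorithm definition's own examples.
PORTER_VECTORS = {
    "caresses": "caress", "ponies": "poni", "ties": "ti", "cats": "cat",
    "feed": "feed", "agreed": "agre", "plastered": "plaster", "bled": "bled",
    "motoring": "motor", "sing": "sing", "conflated": "conflat",
    "troubled": "troubl", "sized": "size", "hopping": "hop", "tanned": "tan",
    "falling": "fall", "hissing": "hiss", "fizzed": "fizz", "failing": "fail",
    "filing": "file", "happy": "happi", "sky": "sky",
    "relational": "relat", "conditional": "condit", "rational": "ration",
    "valenci": "valenc", "digitizer": "digit", "radicalli": "radic",
    "differentli": "differ", "vileli": "vile", "analogousli": "analog",
    "operator": "oper", "feudalism": "feudal", "decisiveness": "decis",
    "hopefulness": "hope", "callousness": "callous", "formaliti": "formal",
    "sensitiviti": "sensit", "sensibiliti": "sensibl",
    "triplicate": "triplic", "formative": "form", "formalize": "formal",
    "electriciti": "electr", "electrical": "electr", "hopeful": "hope",
    "goodness": "good", "revival": "reviv", "allowance": "allow",
    "inference": "infer", "airliner": "airlin", "gyroscopic": "gyroscop",
    "adjustable": "adjust", "defensible": "defens", "irritant": "irrit",
    "replacement": "replac", "adjustment": "adjust", "dependent": "depend",
    "adoption": "adopt", "communism": "commun", "activate": "activ",
    "angulariti": "angular", "homologous": "homolog", "effective": "effect",
    "bowdlerize": "bowdler", "probate": "probat", "rate": "rate",
    "cease": "ceas", "controll": "control", "roll": "roll",
    "generalizations": "gener", "oscillators": "oscil",
    # domain vocabulary
    "sialylated": "sialyl", "sialyl": "sialyl", "lewis": "lewi",
    "arthritis": "arthriti", "rheumatoid": "rheumatoid", "tumour": "tumour",
    "neoplasm": "neoplasm", "gm1": "gm1", "a": "a",
}


@pytest.mark.parametrize("word,expected", sorted(PORTER_VECTORS.items()))
def test_porter_stem_vectors(word, expected):
    assert stem(word) == expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("", ()),
        ("sialyl Lewis A", ("sialyl", "lewi", "a")),
        ("rheumatoid arthritis", ("rheumatoid", "arthriti")),
        ("GM1, (the ganglioside)", ("gm1", "the", "gangliosid")),
        ("...!!!", ()),
    ],
)
def test_normalize_label(text, expected):
    assert normalize_label(text) == expected


@given(st.text(max_size=60))
def test_normalize_is_total_and_punctuation_free(text):
    toks = normalize_label(text)
    assert isinstance(toks, tuple)
    assert all(t == t.lower() for t in toks)


def test_morphological_variant_meets_printed_threshold():
    """'sialylated Lewis A' vs 'sialyl Lewis A' stems to identical token
    sets, so the similarity clears the 0.91 threshold."""
    s = jaccard(
        normalize_label("sialylated Lewis A"), normalize_label("sialyl Lewis A")
    )
    assert s >= 0.91


class TestLoadDelimited:
    def test_duplicate_pairs_collapse(self):
        d, report = load_delimited("a\tX:1\na\tX:1\nb\tX:2\n")
        assert len(d) == 2
        assert report.loaded == 2 and report.collapsed == 1

    def test_paper_synonym_line(self):
        d, _ = load_delimited("tumor\tMONDO:0005070\n")
        [entry] = d.entries
        assert entry.pair == ("tumor", "MONDO:0005070")

    def test_malformed_line_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            d, report = load_delimited("only-one-column\nok\tX:1\n")
        assert len(d) == 1 and report.rejected == 1
        assert "malformed" in caplog.text

    def test_empty_and_comment_only_input(self):
        d, report = load_delimited("# comment\n\n")
        assert len(d) == 0 and report.rejected == 0

    def test_round_trip_preserves_live_pairs_and_black_ledger(self, neoplasm_dict):
        neoplasm_dict.add_black_entry("tumor", "MONDO:0005070")
        buf = io.StringIO()
        write_delimited(neoplasm_dict, buf)
        d2, _ = load_delimited(buf.getvalue())
        assert {e.pair for e in d2} == {e.pair for e in neoplasm_dict}
        assert d2.black == neoplasm_dict.black


class TestFilterShortEntries:
    def test_short_abbreviation_removed_long_form_kept(self):
        d = Dictionary(
            entries=[Entry("RA", "MONDO:0008383"), Entry("rheumatoid arthritis", "MONDO:0008383")]
        )
        removed = d.filter_short_entries(min_len=4, scope="all")
        assert removed == 1
        assert [e.label for e in d] == ["rheumatoid arthritis"]

    def test_min_len_one_is_identity(self, neoplasm_dict):
        before = len(neoplasm_dict)
        assert neoplasm_dict.filter_short_entries(min_len=1) == 0
        assert len(neoplasm_dict) == before

    def test_threshold_counts(self):
        d = Dictionary(
            entries=[Entry(s, f"X:{i}") for i, s in enumerate(["ab", "abc", "abcd", "abcde"])]
        )
        d.filter_short_entries(min_len=4, scope="all")
        assert sorted(e.label for e in d) == ["abcd", "abcde"]

    def test_synonyms_only_spares_canonical_names(self):
        d = Dictionary(
            entries=[
                Entry("GM1", "Glycan:G48558GR", canonical=True),
                Entry("GD3", "Glycan:G98544DH"),
            ]
        )
        d.filter_short_entries(min_len=4, scope="synonyms-only")
        assert [e.label for e in d] == ["GM1"]

    def test_idempotent_and_never_grows(self, neoplasm_dict):
        n0 = len(neoplasm_dict)
        neoplasm_dict.filter_short_entries(min_len=6, scope="all")
        n1 = len(neoplasm_dict)
        assert n1 <= n0
        assert neoplasm_dict.filter_short_entries(min_len=6, scope="all") == 0
        assert len(neoplasm_dict) == n1


class TestLedgers:
    def test_black_survives_recompilation(self, toy_obo):
        d = compile_from_ontology(toy_obo, "D:0")
        d.add_black_entry("colon carcinoma", "D:1")
        fresh = compile_from_ontology(toy_obo, "D:0")
        d.rebuild_from(fresh.entries)
        assert ("colon carcinoma", "D:1") not in d
        assert ("carcinoma of colon", "D:1") in d

    def test_white_survives_recompilation(self, toy_obo):
        d = compile_from_ontology(toy_obo, "D:0")
        d.add_white_entry("sialylated Lewis A", "Glycan:X")
        d.rebuild_from(compile_from_ontology(toy_obo, "D:0").entries)
        assert ("sialylated Lewis A", "Glycan:X") in d

    def test_white_entry_idempotent(self):
        d = Dictionary()
        d.add_white_entry("x", "X:1")
        d.add_white_entry("x", "X:1")
        assert len(d) == 1

    def test_black_of_absent_pair_recorded_without_live_change(self, neoplasm_dict):
        n = len(neoplasm_dict)
        neoplasm_dict.add_black_entry("nonexistent", "X:9")
        assert len(neoplasm_dict) == n
        assert ("nonexistent", "X:9") in neoplasm_dict.black


class TestCompileFromOntology:
    def test_subtree_extraction(self, toy_obo):
        d = compile_from_ontology(toy_obo, "D:0")
        pairs = {e.pair for e in d}
        assert ("colon carcinoma", "D:1") in pairs
        assert ("carcinoma of colon", "D:1") in pairs
        assert ("disease", "D:0") in pairs

    def test_sibling_branch_excluded(self, toy_obo):
        d = compile_from_ontology(toy_obo, "D:0")
        assert not any(e.identifier.startswith("X:") for e in d)

    def test_obsolete_terms_excluded(self, toy_obo):
        d = compile_from_ontology(toy_obo, "D:0")
        assert not any(e.identifier == "D:3" for e in d)

    def test_leaf_root_yields_only_leaf_entries(self, toy_obo):
        d = compile_from_ontology(toy_obo, "D:1")
        assert {e.identifier for e in d} == {"D:1"}

    def test_missing_root_raises_naming_id(self, toy_obo):
        with pytest.raises(KeyError, match="NOPE:1"):
            compile_from_ontology(toy_obo, "NOPE:1")

    def test_cyclic_is_a_raises(self):
        cyclic = (
            "format-version: 1.2\nontology: toy\n\n"
            "[Term]\nid: C:1\nname: one\nis_a: C:2\n\n"
            "[Term]\nid: C:2\nname: two\nis_a: C:1\n"
        )
        with pytest.raises(ValueError, match="cyclic"):
            compile_from_ontology(cyclic, "C:1")

    def test_subtree_entries_superset_of_descendant_compile(self, toy_obo):
        whole = {e.pair for e in compile_from_ontology(toy_obo, "D:0")}
        sub = {e.pair for e in compile_from_ontology(toy_obo, "D:1")}
        assert sub <= whole


class TestLookup:
    def test_exact_term_scores_one(self, neoplasm_dict):
        hits = neoplasm_dict.lookup_ids_by_term("tumor", threshold=1.0)
        assert hits == [("MONDO:0005070", "tumor", 1.0)]

    def test_similarity_match_at_printed_threshold(self, glycan_dict):
        hits = glycan_dict.lookup_ids_by_term("sialylated Lewis A", threshold=0.91)
        assert ("Glycan:GSYN0001A", "sialyl Lewis A", 1.0) in hits

    def test_disjoint_term_no_hit(self, neoplasm_dict):
        assert neoplasm_dict.lookup_ids_by_term("zebrafish", threshold=0.5) == []

    def test_empty_term_empty_result(self, neoplasm_dict):
        assert neoplasm_dict.lookup_ids_by_term("", threshold=0.5) == []

    def test_terms_by_id_returns_all_ten_synonyms(self, neoplasm_dict):
        labels = neoplasm_dict.lookup_terms_by_id("MONDO:0005070")
        assert len(labels) == 10
        assert "neoplasm" in labels and "tumour disease" in labels

    def test_terms_by_id_unknown_identifier(self, neoplasm_dict):
        assert neoplasm_dict.lookup_terms_by_id("MONDO:9999999") == []

    def test_blacklisted_synonym_dropped_from_both_directions(self, neoplasm_dict):
        neoplasm_dict.add_black_entry("tumor", "MONDO:0005070")
        assert len(neoplasm_dict.lookup_terms_by_id("MONDO:0005070")) == 9
        assert neoplasm_dict.lookup_ids_by_term("tumor", threshold=1.0) == []

    @given(st.data())
    def test_threshold_one_equals_brute_force_scan(self, data):
        labels = data.draw(
            st.lists(
                st.text(alphabet="abcdefg ", min_size=1, max_size=12).filter(str.strip),
                min_size=1,
                max_size=30,
            )
        )
        d = Dictionary(
            entries=[Entry(lab, f"X:{i % 7}") for i, lab in enumerate(labels)]
        )
        term = data.draw(st.sampled_from(labels))
        got = {(i, l) for i, l, _ in d.lookup_ids_by_term(term, threshold=1.0)}
        key = set(normalize_label(term))
        brute = {
            (e.identifier, e.label)
            for e in d
            if set(e.norm_key) == key and jaccard(key, e.norm_key) == 1.0
        }
        assert got == brute
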