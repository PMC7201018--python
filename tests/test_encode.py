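"""Fixed-shape encodings: padding, trigrams, domain sentences, PPI matrix,
term selection and label vectors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gofuse import encode
from gofuse.errors import ConfigurationError, ShapeError, ValidationError
from gofuse.io import AnnotationRecord, DomainHit, ScoredLink

AA = st.sampled_from("ACDEFGHIKLMNPQRSTVWY")


class TestSequencePadding:
    def test_pads_to_target_with_non_residue_symbol(self):
        padded = encode.pad_sequence("MKV", target_len=10)
        assert padded == "MKV" + encode.PAD_CHAR * 7
        assert len(padded) == 10

    def test_exact_length_unchanged(self):
        seq = "A" * 1500
        assert encode.pad_sequence(seq) == seq

    def test_overlong_sequence_names_protein(self):
        with pytest.raises(ValidationError, match="P9"):
            encode.pad_sequence("A" * 1501, protein_id="P9")

    @given(st.text(alphabet=AA, min_size=3, max_size=300))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_trigram_count_is_length_minus_two(self, seq):
        assert len(encode.extract_trigrams(seq)) == len(seq) - 2

    def test_trigram_windows_slide_by_one(self):
        assert encode.extract_trigrams("MKVA") == ["MKV", "KVA"]
        assert encode.extract_trigrams("MKV") == ["MKV"]

    def test_too_short_for_any_window(self):
        with pytest.raises(ValidationError):
            encode.extract_trigrams("MK")


class TestTrigramEmbedding:
    def test_padded_length_1500_gives_1498_rows(self, trigram_table):
        padded = encode.pad_sequence("MKVLH" * 100)  # 500 residues
        tokens = encode.extract_trigrams(padded)
        assert len(tokens) == 1498
        mat = encode.embed_trigrams(tokens, trigram_table, expected_len=1498)
        assert mat.shape == (1498, 100)

    def test_padding_trigrams_are_zero_rows(self, trigram_table):
        mat = encode.encode_sequence("MKVLH", trigram_table, target_len=10)
        # positions 0..2 are real trigrams; 3.. contain the padding symbol
        assert np.abs(mat[:3]).sum() > 0
        np.testing.assert_array_equal(mat[3:], 0.0)

    def test_fully_padded_input_is_zero_matrix(self, trigram_table):
        tokens = [encode.PAD_CHAR * 3] * 8
        np.testing.assert_array_equal(encode.embed_trigrams(tokens, trigram_table), 0.0)

    def test_out_of_vocabulary_token_maps_to_zero(self, trigram_table):
        mat = encode.embed_trigrams(["AAA", "XKV"], trigram_table)
        assert np.abs(mat[0]).sum() > 0
        np.testing.assert_array_equal(mat[1], 0.0)

    def test_wrong_token_count_is_shape_error(self, trigram_table):
        with pytest.raises(ShapeError):
            encode.embed_trigrams(["AAA"], trigram_table, expected_len=2)


class TestDomainDedupAndSort:
    def test_identical_hits_collapse_to_first(self):
        h = DomainHit("P1", "D1", 60, 200)
        assert encode.dedup_domain_hits([h, DomainHit("P1", "D1", 60, 200)]) == [h]

    def test_nearly_identical_hits_both_kept(self):
        hits = [DomainHit("P1", "D1", 60, 200), DomainHit("P1", "D1", 60, 201)]
        assert len(encode.dedup_domain_hits(hits)) == 2

    def test_empty_list(self):
        assert encode.dedup_domain_hits([]) == []

    def test_detached_hits_keep_positional_order(self):
        a, b = DomainHit("P", "A", 10, 50), DomainHit("P", "B", 60, 200)
        assert encode.sort_domains([b, a]) == [a, b]

    def test_containing_pair_ordered_by_center(self):
        outer = DomainHit("P", "B", 60, 200)   # center 130
        inner = DomainHit("P", "C", 100, 140)  # center 120
        assert encode.sort_domains([outer, inner]) == [inner, outer]

    def test_center_tie_broken_by_start(self):
        a, b = DomainHit("P", "A", 10, 30), DomainHit("P", "B", 15, 25)
        assert encode.sort_domains([b, a]) == [a, b]

    @given(st.lists(
        st.tuples(st.integers(1, 50), st.integers(0, 100), st.text("AB", min_size=1, max_size=2)),
        max_size=12,
    ))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_sort_is_permutation_and_idempotent(self, raw):
        hits = [DomainHit("P", d, s, s + w) for s, w, d in raw]
        out = encode.sort_domains(hits)
        assert sorted(map(repr, out)) == sorted(map(repr, hits))
        assert encode.sort_domains(out) == out
        centers = [encode.center_point(h) for h in out]
        assert centers == sorted(centers)


class TestDomainVocabAndSentence:
    def test_vocab_reserves_padding_index(self):
        hits = [DomainHit("P", d, 1, 5) for d in ("D2", "D1", "D1")]
        vocab = encode.build_domain_vocab(hits)
        assert vocab.size == 3
        assert vocab["D1"] == 1 and vocab["D2"] == 2  # sorted order, 0 reserved

    def test_empty_vocab_is_padding_only(self):
        assert encode.build_domain_vocab([]).size == 1

    def test_sentence_indices_and_padding_tail(self):
        vocab = encode.build_domain_vocab(
            [DomainHit("P", "B", 1, 2), DomainHit("P", "C", 1, 2)]
        )
        hits = [DomainHit("P", "C", 100, 140), DomainHit("P", "B", 60, 200)]
        sentence = encode.encode_domain_sentence(hits, vocab, max_len=5)
        np.testing.assert_array_equal(sentence, [vocab["C"], vocab["B"], 0, 0, 0])

    def test_no_hits_gives_all_padding(self):
        vocab = encode.build_domain_vocab([])
        np.testing.assert_array_equal(
            encode.encode_domain_sentence([], vocab, 3), [0, 0, 0]
        )

    def test_too_many_hits_names_protein(self):
        vocab = encode.build_domain_vocab([DomainHit("P", "D", 1, 2)])
        hits = [DomainHit("P", "D", i, i + 1) for i in range(1, 7)]
        with pytest.raises(ValidationError, match="P7"):
            encode.encode_domain_sentence(hits, vocab, 5, protein_id="P7")


class TestPPIMatrix:
    def test_symmetric_fill_above_threshold(self):
        mat = encode.build_ppi_matrix([ScoredLink("P1", "P2", 700)], ["P1", "P2"])
        np.testing.assert_array_equal(mat, [[0, 700], [700, 0]])

    def test_score_exactly_at_threshold_dropped(self):
        mat = encode.build_ppi_matrix([ScoredLink("P1", "P2", 400)], ["P1", "P2"])
        np.testing.assert_array_equal(mat, 0.0)

    def test_no_links_gives_zero_matrix(self):
        np.testing.assert_array_equal(encode.build_ppi_matrix([], ["P1", "P2"]), 0.0)

    def test_unknown_endpoints_ignored(self):
        mat = encode.build_ppi_matrix([ScoredLink("P1", "Q9", 800)], ["P1", "P2"])
        np.testing.assert_array_equal(mat, 0.0)

    def test_normalization_switch(self):
        mat = encode.build_ppi_matrix(
            [ScoredLink("P1", "P2", 500)], ["P1", "P2"], normalize=True
        )
        assert mat[0, 1] == pytest.approx(0.5)

    @given(st.lists(
        st.tuples(st.integers(0, 7), st.integers(0, 7), st.integers(0, 1000)),
        max_size=30,
    ))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_symmetry_zero_diagonal_and_threshold(self, raw):
        proteins = [f"P{i}" for i in range(8)]
        links = [
            ScoredLink(f"P{a}", f"P{b}", s) for a, b, s in raw if a != b
        ]
        mat = encode.build_ppi_matrix(links, proteins)
        np.testing.assert_array_equal(mat, mat.T)
        np.testing.assert_array_equal(np.diag(mat), 0.0)
        nonzero = mat[mat > 0]
        assert (nonzero > encode.PPI_SCORE_THRESHOLD).all()


class TestTermSelectionAndLabels:
    def test_selection_orders_by_count_then_id(self, toy_annotations):
        ts = encode.select_go_terms(toy_annotations, "MF", min_count=2)
        assert ts.terms == ["GO:0000001", "GO:0000002"]
        assert ts.counts == {"GO:0000001": 5, "GO:0000002": 2}

    def test_min_count_one_keeps_all_annotated_terms(self, toy_annotations):
        ts = encode.select_go_terms(toy_annotations, "MF", min_count=1)
        assert len(ts) == 3

    def test_unreachable_threshold_is_configuration_error(self, toy_annotations):
        with pytest.raises(ConfigurationError):
            encode.select_go_terms(toy_annotations, "MF", min_count=99)

    def test_duplicate_annotations_count_distinct_proteins(self):
        anns = [AnnotationRecord("P1", "GO:0000001", "MF")] * 3
        ts = encode.select_go_terms(anns, "MF", min_count=1)
        assert ts.counts["GO:0000001"] == 1

    def test_label_vector_alignment(self, toy_annotations):
        ts = encode.select_go_terms(toy_annotations, "MF", min_count=2)
        np.testing.assert_array_equal(
            encode.build_label_vector("P1", toy_annotations, ts), [1, 1]
        )
        np.testing.assert_array_equal(
            encode.build_label_vector("P5", toy_annotations, ts), [1, 0]
        )
        np.testing.assert_array_equal(
            encode.build_label_vector("P99", toy_annotations, ts), [0, 0]
        )

    def test_non_selected_annotation_gives_zero_vector(self, toy_annotations):
        ts = encode.select_go_terms(toy_annotations, "MF", min_count=2)
        only_rare = [AnnotationRecord("P8", "GO:0000003", "MF")]
        np.testing.assert_array_equal(
            encode.build_label_vector("P8", toy_annotations + only_rare, ts), [0, 0]
        )

    def test_label_matrix_counts_respect_min_count(self, toy_annotations):
        ts = encode.select_go_terms(toy_annotations, "MF", min_count=2)
        proteins = sorted({a.protein_id for a in toy_annotations})
        mat = encode.build_label_matrix(proteins, toy_annotations, ts)
        assert (mat.sum(axis=0) >= ts.min_count).all()


class TestVocabularySizing:
    @pytest.mark.parametrize("n_domains, table_rows", [(14242, 14243), (6707, 6708), (3, 4)])
    def test_lookup_table_rows_include_padding(self, n_domains, table_rows):
        hits = [DomainHit("P", f"D{i}", 1, 2) for i in range(n_domains)]
        assert encode.build_domain_vocab(hits).size == table_rows
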