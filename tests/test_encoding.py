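"""Unit and property tests for the base/codon one-hot encodings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgeclass import encoding as enc

# independent pure-Python re-implementation used as a brute-force oracle
_VEC = {"A": [0, 0, 0, 1], "C": [0, 0, 1, 0], "G": [0, 1, 0, 0],
        "T": [1, 0, 0, 0]}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_LEX = "ACGT"


def oracle_revcomp(seq):
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def oracle_boh(seq):
    rows = [_VEC.get(b, [0, 0, 0, 0]) for b in seq]
    rows += [_VEC.get(b, [0, 0, 0, 0]) for b in oracle_revcomp(seq)]
    return np.array(rows, dtype=np.uint8)


def oracle_frames(seq):
    frames = []
    for strand in (seq, oracle_revcomp(seq)):
        for off in range(3):
            codons = []
            i = off
            while i + 3 <= len(strand):
                codons.append(strand[i:i + 3])
                i += 3
            frames.append(codons)
    return frames


def oracle_coh(seq):
    rows = []
    for frame in oracle_frames(seq):
        for codon in frame:
            vec = [0] * 64
            if all(b in _LEX for b in codon):
                vec[_LEX.index(codon[0]) * 16 + _LEX.index(codon[1]) * 4
                    + _LEX.index(codon[2])] = 1
            rows.append(vec)
    return np.array(rows, dtype=np.uint8)


def random_seq(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


class TestReverseComplement:
    def test_worked_example(self):
        assert enc.reverse_complement("ACGTTCGAACG") == "CGTTCGAACGT"

    def test_palindrome(self):
        assert enc.reverse_complement("ACGT") == "ACGT"

    def test_ambiguous_maps_to_n(self):
        assert enc.reverse_complement("ART") == "ANT"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            enc.reverse_complement("")

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    def test_involution(self, seq):
        assert enc.reverse_complement(enc.reverse_complement(seq)) == seq


class TestBaseOneHot:
    def test_letter_map(self):
        mat = enc.encode_boh("ACGT")
        np.testing.assert_array_equal(
            mat[:4], [[0, 0, 0, 1], [0, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 0]])

    def test_single_a(self):
        np.testing.assert_array_equal(
            enc.encode_boh("A"), [[0, 0, 0, 1], [1, 0, 0, 0]])

    def test_ambiguous_row_is_zero(self):
        np.testing.assert_array_equal(enc.encode_boh("N"), np.zeros((2, 4)))

    def test_strand_symmetry_of_letter_map(self):
        # complement's 4-vector is the reversal of the base's 4-vector
        for base in "ACGT":
            fwd = enc.encode_boh(base)[0]
            comp = enc.encode_boh(_COMP[base])[0]
            np.testing.assert_array_equal(comp, fwd[::-1])

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for length in range(3, 201):
            seq = random_seq(rng, length, "ACGTN")
            mat = enc.encode_boh(seq)
            assert mat.shape == (2 * length, 4)
            np.testing.assert_array_equal(mat, oracle_boh(seq))

    def test_column_sum_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = random_seq(rng, 50, "ACGTN")
            ambiguous = seq.count("N")
            assert enc.encode_boh(seq).sum() == 2 * len(seq) - 2 * ambiguous


class TestCodonFrames:
    def test_worked_example(self):
        frames = enc.expand_codon_frames("ACGTTCGAACG")
        assert frames[0] == ["ACG", "TTC", "GAA"]
        assert len(frames) == 6
        assert sum(len(f) for f in frames) == 18
        assert frames == oracle_frames("ACGTTCGAACG")

    def test_minimal_sequence(self):
        assert enc.expand_codon_frames("ACG") == [
            ["ACG"], [], [], ["CGT"], [], []]

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            enc.expand_codon_frames("AC")

    def test_codon_count_closed_form(self):
        rng = np.random.default_rng(2)
        for length in range(3, 101):
            seq = random_seq(rng, length)
            frames = enc.expand_codon_frames(seq)
            assert sum(len(f) for f in frames) == 2 * (length - 2)


class TestCodonOneHot:
    def test_aaa_is_column_zero(self):
        mat = enc.encode_coh("AAA")
        assert mat[0, 0] == 1 and mat[0].sum() == 1

    def test_lexicographic_indexing(self):
        assert enc.codon_index("AAA") == 0
        assert enc.codon_index("AAC") == 1
        assert enc.codon_index("TTT") == 63
        assert enc.codon_index("ANA") is None

    def test_worked_example_shape_and_row_sums(self):
        mat = enc.encode_coh("ACGTTCGAACG")
        assert mat.shape == (18, 64)
        np.testing.assert_array_equal(mat.sum(axis=1), np.ones(18))

    def test_ambiguous_codon_zero_row(self):
        mat = enc.encode_coh("ANA")
        assert mat[0].sum() == 0

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(3)
        for length in range(3, 201, 7):
            seq = random_seq(rng, length, "ACGTN")
            mat = enc.encode_coh(seq)
            assert mat.shape == (2 * (length - 2), 64)
            np.testing.assert_array_equal(mat, oracle_coh(seq))

    def test_deterministic(self):
        seq = random_seq(np.random.default_rng(4), 60)
        np.testing.assert_array_equal(enc.encode_coh(seq), enc.encode_coh(seq))
        np.testing.assert_array_equal(enc.encode_boh(seq), enc.encode_boh(seq))


class TestPadding:
    def test_group_a_short_fragment(self):
        seq = random_seq(np.random.default_rng(5), 100)
        padded = enc.pad_for_group(enc.encode_boh(seq), enc.encode_coh(seq), "A")
        assert padded.boh.shape == (800, 4)
        assert padded.coh.shape == (800, 64)
        assert padded.original_length == 100
        assert padded.boh[200:].sum() == 0
        assert padded.coh[196:].sum() == 0

    def test_group_a_exact_length(self):
        seq = random_seq(np.random.default_rng(6), 400)
        padded = enc.pad_for_group(enc.encode_boh(seq), enc.encode_coh(seq), "A")
        assert padded.boh.shape == (800, 4)
        assert padded.boh.sum() == 800  # no padding rows on boh
        assert padded.coh[796:].sum() == 0

    def test_data_rows_unchanged(self):
        seq = random_seq(np.random.default_rng(7), 150)
        boh, coh = enc.encode_boh(seq), enc.encode_coh(seq)
        padded = enc.pad_for_group(boh, coh, "B")
        np.testing.assert_array_equal(padded.boh[:300], boh)
        np.testing.assert_array_equal(padded.coh[:296], coh)

    def test_too_long_errors(self):
        seq = random_seq(np.random.default_rng(8), 500)
        with pytest.raises(ValueError):
            enc.pad_for_group(enc.encode_boh(seq), enc.encode_coh(seq), "A")


class TestTracks:
    """Index tracks drive the fast path; they must agree with the matrices."""

    def test_tracks_match_dense_encoding(self):
        rng = np.random.default_rng(9)
        for length in (3, 10, 57, 120):
            seq = random_seq(rng, length, "ACGTN")
            bt = enc.base_index_track(seq)
            dense = enc.encode_boh(seq)
            for row, col in enumerate(bt):
                if col < 0:
                    assert dense[row].sum() == 0
                else:
                    assert dense[row, col] == 1
            ct = enc.codon_index_track(seq)
            dense_c = enc.encode_coh(seq)
            for row, col in enumerate(ct):
                if col < 0:
                    assert dense_c[row].sum() == 0
                else:
                    assert dense_c[row, col] == 1

    def test_encode_batch_shapes(self):
        rng = np.random.default_rng(10)
        seqs = [random_seq(rng, n) for n in (100, 250, 400)]
        boh, coh = enc.encode_batch(seqs, "A")
        assert boh.shape == (3, 800, 4)
        assert coh.shape == (3, 800, 64)
        np.testing.assert_array_equal(boh[0, :200], enc.encode_boh(seqs[0]))
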