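import numpy as np
import pytest

from panhgt import align
from oracles import blosum62_sub, dna_sub, global_affine_score, local_affine_score


def _random_dna(rng, max_len=60, min_len=1):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list("ACGT"), n))


def _random_protein(rng, max_len=20, min_len=1):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), n))


def test_global_dna_score_matches_bruteforce():
    rng = np.random.default_rng(11)
    sub = dna_sub(5.0, -4.0)
    for _ in range(60):
        a, b = _random_dna(rng), _random_dna(rng)
        score, n_id, n_pairs, aln_len = align.global_dna_alignment_stats(a, b)
        oracle = global_affine_score(a, b, sub, 10.0, 0.5)
        assert score == pytest.approx(oracle, abs=1e-9)
        assert 0 <= n_id <= n_pairs <= aln_len
        assert aln_len >= max(len(a), len(b))


def test_global_dna_score_matches_biopython():
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.5  # open 10 + first-column extension 0.5
    aligner.extend_gap_score = -0.5
    rng = np.random.default_rng(5)
    for _ in range(40):
        a, b = _random_dna(rng), _random_dna(rng)
        score, *_ = align.global_dna_alignment_stats(a, b)
        assert score == pytest.approx(aligner.score(a, b), abs=1e-9)


def test_local_protein_score_matches_bruteforce():
    rng = np.random.default_rng(12)
    submat = align.blosum62_matrix()
    sub = blosum62_sub()
    for _ in range(60):
        a, b = _random_protein(rng), _random_protein(rng)
        got = align.local_protein_score(a, b, submat)
        assert got == pytest.approx(local_affine_score(a, b, sub, 11.0, 1.0),
                                    abs=1e-9)


def test_local_protein_score_matches_biopython():
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    rng = np.random.default_rng(13)
    submat = align.blosum62_matrix()
    for _ in range(40):
        a, b = _random_protein(rng), _random_protein(rng)
        got = align.local_protein_score(a, b, submat)
        assert got == pytest.approx(aligner.score(a, b), abs=1e-9)


def test_banded_local_full_band_matches_bruteforce():
    rng = np.random.default_rng(14)
    sub = dna_sub(1.0, -1.0)
    for _ in range(40):
        a, b = _random_dna(rng, 50), _random_dna(rng, 50)
        band = max(len(a), len(b))
        score, n_id, n_pairs, aln_len, span = align.banded_local_dna_stats(
            align.encode_dna(a), align.encode_dna(b), 0, band)
        assert score == pytest.approx(local_affine_score(a, b, sub, 5.0, 2.0),
                                      abs=1e-9)
        assert 0 <= n_id <= n_pairs <= aln_len
        assert span <= len(a)


def test_banded_local_narrow_band_never_beats_full():
    rng = np.random.default_rng(15)
    for _ in range(20):
        a, b = _random_dna(rng, 80, 30), _random_dna(rng, 80, 30)
        full = align.banded_local_dna_stats(
            align.encode_dna(a), align.encode_dna(b), 0, max(len(a), len(b)))
        narrow = align.banded_local_dna_stats(
            align.encode_dna(a), align.encode_dna(b), 0, 4)
        assert narrow[0] <= full[0] + 1e-9


def test_n_scores_as_mismatch():
    score, n_id, n_pairs, aln_len = align.global_dna_alignment_stats(
        "ANNNA", "ANNNA")
    assert n_id == 2  # N never matches, even against itself
    assert n_pairs == 5


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align.global_dna_alignment_stats("", "ACGT")


def test_identical_sequences_perfect():
    s = "ACGTACGTACGT"
    score, n_id, n_pairs, aln_len = align.global_dna_alignment_stats(s, s)
    assert score == 5.0 * len(s)
    assert n_id == n_pairs == aln_len == len(s)


def test_global_protein_stats_roundtrip():
    n_id, n_pairs, aln_len = align.global_protein_alignment_stats(
        "MKTAYIAKQR", "MKTAYIAKQR")
    assert n_id == n_pairs == aln_len == 10
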