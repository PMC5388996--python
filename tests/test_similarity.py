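import itertools

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from nbscensus import similarity
from nbscensus.models import SimilarityRecord

from _oracles import best_alignment_score, column_scan_similarity

PARAMS = similarity.AlignParams()


def _score_fn():
    alphabet, S = similarity._scoring(PARAMS)
    return lambda x, y: S[alphabet.index(x), alphabet.index(y)]


def random_protein(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), n))


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        seq = "MKVLWAALLVTFLAGCQA"
        aa, ab, score = similarity.global_align(seq, seq)
        assert aa == ab == seq
        rec = similarity.pairwise_similarity(aa, ab)
        assert rec.matched_length == len(seq) and rec.similarity == 1.0

    def test_single_gap_column(self):
        aa, ab, _ = similarity.global_align("AAG", "AG")
        assert len(aa) == len(ab) == 3
        assert ab.count("-") == 1 and aa.count("-") == 0

    def test_single_column_score_is_matrix_entry(self):
        _, _, score = similarity.global_align("A", "A")
        mat = substitution_matrices.load("BLOSUM62")
        assert score == mat["A", "A"]

    def test_score_symmetric_under_swap(self, rng):
        a = random_protein(rng, 40)
        b = random_protein(rng, 35)
        _, _, s1 = similarity.global_align(a, b)
        _, _, s2 = similarity.global_align(b, a)
        assert s1 == pytest.approx(s2)

    def test_rejects_bad_characters(self):
        with pytest.raises(ValueError):
            similarity.global_align("MK1", "MK")
        with pytest.raises(ValueError):
            similarity.global_align("", "MK")

    def test_optimal_vs_exhaustive_enumeration_short(self, rng):
        """DP score equals brute-force enumeration over all alignments."""
        fn = _score_fn()
        letters = "ACDE"
        seqs = [
            "".join(p)
            for L in (1, 2)
            for p in itertools.product(letters, repeat=L)
        ]
        for a, b in itertools.combinations_with_replacement(seqs, 2):
            _, _, got = similarity.global_align(a, b)
            assert got == pytest.approx(
                best_alignment_score(a, b, fn, PARAMS.gap_open, PARAMS.gap_extend)
            ), (a, b)
        for _ in range(60):
            a = random_protein(rng, int(rng.integers(3, 7)), letters)
            b = random_protein(rng, int(rng.integers(3, 7)), letters)
            _, _, got = similarity.global_align(a, b)
            assert got == pytest.approx(
                best_alignment_score(a, b, fn, PARAMS.gap_open, PARAMS.gap_extend)
            ), (a, b)

    def test_matches_biopython_global_aligner(self, rng):
        """Independent cross-check against Bio.Align.PairwiseAligner scores."""
        aligner = Align.PairwiseAligner()
        mat = substitution_matrices.load("BLOSUM62")
        aligner.substitution_matrix = mat
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aligner.mode = "global"
        for _ in range(15):
            a = random_protein(rng, int(rng.integers(20, 60)))
            b = random_protein(rng, int(rng.integers(20, 60)))
            _, _, got = similarity.global_align(
                a, b, similarity.AlignParams(x_neutral=False)
            )
            assert got == pytest.approx(aligner.score(a, b))


class TestPairwiseSimilarity:
    def test_direct_counts(self):
        rec = similarity.pairwise_similarity("MKV", "MKV")
        assert (rec.matched_length, rec.similarity) == (3, 1.0)
        rec = similarity.pairwise_similarity("MKV", "MRV")
        assert rec.matched_length == 3
        assert rec.similarity == pytest.approx(2 / 3)
        assert rec.distance == pytest.approx(1 / 3)

    def test_gap_columns_excluded(self):
        rec = similarity.pairwise_similarity("MK-V", "M-AV")
        assert rec.matched_length == 2  # columns 1 and 4

    def test_x_never_identical(self):
        rec = similarity.pairwise_similarity("XX", "XX")
        assert rec.matched_length == 2 and rec.similarity == 0.0

    def test_all_gap_flagged_unusable(self):
        rec = similarity.pairwise_similarity("M-", "-M")
        assert not rec.usable

    def test_column_scan_oracle(self, rng):
        chars = list("ACDEF-")
        for _ in range(100):
            n = int(rng.integers(5, 30))
            aa = "".join(rng.choice(chars, n))
            ab = "".join(rng.choice(chars, n))
            rec = similarity.pairwise_similarity(aa, ab)
            matched, sim = column_scan_similarity(aa, ab)
            assert rec.matched_length == matched
            if matched:
                assert rec.similarity == pytest.approx(sim)


def make_rec(a, b, sim, matched=300):
    return SimilarityRecord(a, b, matched, 1 - sim, sim)


class TestFilters:
    def test_matched_length_strictly_greater(self):
        recs = [make_rec("a", "b", 0.9, 200), make_rec("a", "c", 0.9, 201)]
        kept = similarity.filter_matched_length(recs)
        assert [r.gene_b for r in kept] == ["c"]
        assert similarity.filter_matched_length([]) == []

    def test_low_similarity_genes(self):
        recs = [make_rec("a1", "b", 0.25), make_rec("a2", "b", 0.30), make_rec("a3", "b", 0.8)]
        low = similarity.low_similarity_genes(recs, ["a1", "a2", "a3", "a4"])
        # a2's best is 0.30 exactly: not "less than 30%"; a4 has no record at all
        assert low == ["a1", "a4"]


class TestThresholdCensus:
    def test_published_proportions(self):
        assert similarity.threshold_proportion(140, 246) == 57
        assert similarity.threshold_proportion(202, 246) == 82
        assert similarity.threshold_proportion(310, 365) == 85
        assert similarity.threshold_proportion(185, 246) == 75
        assert similarity.threshold_proportion(87, 246) == 35

    def test_strict_threshold_and_monotonicity(self):
        recs = [make_rec("a1", "b1", 0.90), make_rec("a2", "b1", 0.91), make_rec("a3", "b1", 0.40)]
        census = similarity.threshold_census(recs, 4)
        # similarity == 0.90 is NOT > 90%
        assert census.n_nonredundant[90] == 1
        assert census.n_nonredundant[40] == 2
        assert census.n_nonredundant[30] == 3
        counts = [census.n_nonredundant[t] for t in census.thresholds]
        assert counts == sorted(counts)

    def test_empty_records_all_zero(self):
        census = similarity.threshold_census([], 10)
        assert all(v == 0 for v in census.n_nonredundant.values())

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            similarity.threshold_census([], 0)


class TestAllVsAll:
    def test_symmetry_of_similarity(self, small_records):
        a = [r.gene for r in small_records[:3]]
        b = [r.gene for r in small_records[3:6]]
        fwd = {(r.gene_a, r.gene_b): r.similarity for r in similarity.all_vs_all(a, b)}
        rev = {(r.gene_b, r.gene_a): r.similarity for r in similarity.all_vs_all(b, a)}
        assert fwd.keys() == rev.keys()
        for k in fwd:
            assert fwd[k] == pytest.approx(rev[k])

    def test_prefilter_is_subset(self, small_records):
        a = [r.gene for r in small_records[:4]]
        b = [r.gene for r in small_records[4:8]]
        full = {(r.gene_a, r.gene_b) for r in similarity.all_vs_all(a, b)}
        pre = {
            (r.gene_a, r.gene_b)
            for r in similarity.all_vs_all(a, b, prefilter=True, min_shared_kmers=5)
        }
        assert pre <= full
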