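"""Counting, Markov expectation and score identities for the k-mer engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgks import (
    GenomeSequence,
    InvalidInputError,
    InvalidParameterError,
    count_kmers,
    expected_counts,
    kmer_rank,
    rank_to_kmer,
    score_signature,
    wgks_signature,
)
from wgks.kmer import ExpectedTable, KmerCountTable

from conftest import random_dna


def naive_counts(records, k):
    """Independent oracle: test every offset by string comparison."""
    counts = {}
    for rec in records:
        rec = rec.upper()
        for i in range(len(rec) - k + 1):
            w = rec[i : i + k]
            if all(c in "ACGT" for c in w):
                counts[w] = counts.get(w, 0) + 1
    out = np.zeros(4 ** k, dtype=np.int64)
    for w, c in counts.items():
        out[kmer_rank(w)] = c
    return out


class TestCounting:
    def test_hand_example(self):
        t = count_kmers(GenomeSequence("g", ["ACGT"]), 2)
        assert t["AC"] == t["CG"] == t["GT"] == 1
        assert t.total == 3

    def test_ambiguous_only_record_counts_nothing(self):
        assert count_kmers(GenomeSequence("g", ["N"]), 1).total == 0

    def test_empty_record_rejected(self):
        with pytest.raises(InvalidInputError):
            GenomeSequence("g", [""])

    def test_k_below_one_rejected(self, toy_genome):
        with pytest.raises(InvalidParameterError):
            count_kmers(toy_genome, 0)

    def test_k_longer_than_records_rejected(self, toy_genome):
        with pytest.raises(InvalidParameterError):
            count_kmers(toy_genome, 5)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, k, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(100, 10_000))
        records = [random_dna(rng, length)]
        if seed % 2:  # mix in N runs and a second record
            records.append(random_dna(rng, 500, alphabet="ACGTN"))
        genome = GenomeSequence(f"g{seed}", records)
        got = count_kmers(genome, k).counts
        np.testing.assert_array_equal(got, naive_counts(records, k))

    def test_windows_do_not_span_records(self):
        joined = count_kmers(GenomeSequence("g", ["ACGTAC"]), 3).counts
        split = count_kmers(GenomeSequence("g", ["ACG", "TAC"]), 3).counts
        assert joined.sum() == 4 and split.sum() == 2
        np.testing.assert_array_equal(
            split, naive_counts(["ACG", "TAC"], 3)
        )

    def test_lowercase_normalized(self):
        a = count_kmers(GenomeSequence("g", ["acgtACGT"]), 3).counts
        b = count_kmers(GenomeSequence("g", ["ACGTACGT"]), 3).counts
        np.testing.assert_array_equal(a, b)

    def test_canonical_mode_counts_both_strands(self):
        g = GenomeSequence("g", ["AAAC"])
        t = count_kmers(g, 3, canonical=True)
        assert t["AAA"] == 1 and t["AAC"] == 1
        assert t["TTT"] == 1 and t["GTT"] == 1
        assert t.total == 4


class TestLexicographicOrder:
    def test_rank_roundtrip_all_3mers(self):
        words = [rank_to_kmer(r, 3) for r in range(64)]
        assert words[0] == "AAA" and words[-1] == "TTT"
        assert words == sorted(words)
        assert [kmer_rank(w) for w in words] == list(range(64))

    @given(st.integers(min_value=0, max_value=4 ** 6 - 1))
    @settings(deadline=None)
    def test_rank_is_base4_encoding(self, rank):
        word = rank_to_kmer(rank, 6)
        assert sum("ACGT".index(c) * 4 ** (5 - i) for i, c in enumerate(word)) == rank


class TestExpectedCounts:
    def test_hand_example_aaaa(self, toy_genome):
        o2, o1 = count_kmers(toy_genome, 2), count_kmers(toy_genome, 1)
        e = expected_counts(o2, o1, 3)
        assert e["AAA"] == pytest.approx(3 * 3 / 4)  # O(AA)^2 / O(A)

    def test_zero_prefix_gives_zero(self, toy_genome):
        o2, o1 = count_kmers(toy_genome, 2), count_kmers(toy_genome, 1)
        e = expected_counts(o2, o1, 3)
        assert e["CAA"] == 0.0 and e["AAC"] == 0.0

    def test_k_below_three_rejected(self, toy_genome):
        o1 = count_kmers(toy_genome, 1)
        with pytest.raises(InvalidParameterError):
            expected_counts(o1, o1, 2)

    def test_word_length_mismatch_rejected(self, toy_genome):
        o2, o1 = count_kmers(toy_genome, 2), count_kmers(toy_genome, 1)
        with pytest.raises(InvalidParameterError):
            expected_counts(o1, o2, 3)

    def test_iid_sequence_expectation_tracks_observation(self):
        # on a long i.i.d. uniform sequence E(w) ~ O(w) for every word
        rng = np.random.default_rng(11)
        g = GenomeSequence("iid", [random_dna(rng, 1_000_000)])
        o4, o3, o2 = (count_kmers(g, k) for k in (4, 3, 2))
        e = expected_counts(o3, o2, 4)
        rel = np.abs(e.expected - o4.counts) / o4.counts
        assert rel.max() < 0.15 and rel.mean() < 0.03


class TestScores:
    def test_identities(self):
        o = KmerCountTable(1, np.array([2, 3, 0, 0]))
        e = ExpectedTable(1, np.array([2.0, 0.0, 4.0, 0.0]))
        s = score_signature(o, e).scores
        assert s[0] == 0.0      # O = E > 0
        assert s[1] == 1.0      # O > 0 = E
        assert s[2] == -1.0     # E > 0 = O
        assert s[3] == 0.0      # O = E = 0
        assert np.all(np.abs(s) <= 1.0)

    def test_hand_score(self):
        o = KmerCountTable(1, np.array([2, 0, 0, 0]))
        e = ExpectedTable(1, np.array([2.25, 0, 0, 0.0]))
        assert score_signature(o, e).scores[0] == pytest.approx(-0.25 / 4.25)

    def test_monotone_in_observed(self):
        e = ExpectedTable(1, np.full(4, 2.5))
        scores = [
            score_signature(KmerCountTable(1, np.full(4, o)), e).scores[0]
            for o in range(6)
        ]
        assert np.all(np.diff(scores) > 0)

    def test_k_mismatch_rejected(self, toy_genome):
        o = count_kmers(toy_genome, 2)
        e = ExpectedTable(3, np.zeros(64))
        with pytest.raises(InvalidParameterError):
            score_signature(o, e)


class TestSignaturePipeline:
    def test_vector_length_is_4_to_k(self, rng):
        g = GenomeSequence("g", [random_dna(rng, 2000)])
        assert len(wgks_signature(g, 5)) == 4 ** 5

    def test_micro_example_k3(self):
        sig = wgks_signature(GenomeSequence("g", ["AAAA"]), 3)
        assert sig["AAA"] == pytest.approx(-0.25 / 4.25)
        # every other word has O = 0 and E = 0 -> neutral 0
        assert sig["CCC"] == 0.0 and sig["AAC"] == 0.0
        scores = sig.scores
        assert np.all(scores >= -1.0) and np.all(scores <= 1.0)

    @pytest.mark.parametrize("k", [3, 4, 6])
    def test_duplication_invariance(self, k, rng):
        g = GenomeSequence(
            "g", [random_dna(rng, 3000), random_dna(rng, 2000, alphabet="ACGTN")]
        )
        s1 = wgks_signature(g, k).scores
        s2 = wgks_signature(g.duplicated(), k).scores
        assert np.abs(s1 - s2).max() <= 1e-12

    def test_k_out_of_range_rejected(self, toy_genome):
        with pytest.raises(InvalidParameterError):
            wgks_signature(toy_genome, 2)
        with pytest.raises(InvalidParameterError):
            wgks_signature(toy_genome, 13)
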