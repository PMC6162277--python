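import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sexlink import dna, kmers
from sexlink.io import FastqRecord

from oracles import naive_kmer_count, naive_substring_hits


def make_table(counts: dict[str, int], k: int) -> kmers.KmerCountTable:
    codes = {}
    for w, n in counts.items():
        codes[dna.kmer_to_code(dna.canonical(w))] = n
    arr = np.array(sorted(codes), dtype=np.uint64)
    vals = np.array([codes[int(c)] for c in arr], dtype=np.uint32)
    return kmers.KmerCountTable(kmers.KmerSpace(k), arr, vals)


class TestCountKmers:
    def test_palindromic_word(self):
        assert kmers.count_kmers(["ACGT"], kmers.KmerSpace(4)).to_dict() == {
            "ACGT": 1
        }

    def test_two_windows(self):
        assert kmers.count_kmers(["AAAAA"], kmers.KmerSpace(4)).to_dict() == {
            "AAAA": 2
        }

    def test_matches_bruteforce_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        table = kmers.count_kmers([seq], kmers.KmerSpace(16))
        assert table.to_dict() == naive_kmer_count([seq], 16)

    def test_n_windows_skipped(self):
        table = kmers.count_kmers(["ACGNACG"], kmers.KmerSpace(3))
        assert table.to_dict() == naive_kmer_count(["ACGNACG"], 3)

    def test_strand_symmetry(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        t1 = kmers.count_kmers([seq], kmers.KmerSpace(16))
        t2 = kmers.count_kmers([dna.revcomp(seq)], kmers.KmerSpace(16))
        assert t1.to_dict() == t2.to_dict()

    def test_multiple_sequences_batched(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(50)]
        table = kmers.count_kmers(seqs, kmers.KmerSpace(16))
        assert table.to_dict() == naive_kmer_count(seqs, 16)

    def test_errors(self):
        with pytest.raises(ValueError):
            kmers.count_kmers([], kmers.KmerSpace(4))
        with pytest.raises(ValueError):
            kmers.count_kmers(["ACG"], kmers.KmerSpace(16))

    def test_merge_tables(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(4)]
        merged = kmers.merge_tables([
            kmers.count_kmers([s], kmers.KmerSpace(8)) for s in seqs
        ])
        assert merged.to_dict() == naive_kmer_count(seqs, 8)


class TestErrorCutoff:
    def test_valley_between_error_and_signal(self):
        hist = {1: 1000, 2: 400, 3: 100, 4: 40, 5: 20, 6: 10, 7: 30, 10: 200,
                30: 5000, 31: 4000}
        assert kmers.select_error_cutoff(hist).cutoff == 6

    def test_monotone_decreasing_raises(self):
        hist = {1: 1000, 2: 500, 3: 200, 4: 50, 5: 10}
        with pytest.raises(kmers.InsufficientCoverageError):
            kmers.select_error_cutoff(hist)

    def test_valley_at_one_clamped_to_three(self):
        hist = {1: 10, 2: 50, 3: 80, 30: 500}
        assert kmers.select_error_cutoff(hist).cutoff == 3

    def test_no_peak_above_two_raises(self):
        hist = {1: 10, 2: 50}
        with pytest.raises(kmers.InsufficientCoverageError):
            kmers.select_error_cutoff(hist)

    def test_clamped_high(self):
        hist = {m: 1000 - m * 10 for m in range(1, 30)}
        hist[30] = 5000  # valley at 29
        assert kmers.select_error_cutoff(hist).cutoff == 15

    def test_cutoff_range_enforced(self):
        with pytest.raises(ValueError):
            kmers.ErrorCutoff("s", 2, {})


class TestCoverageCutoff:
    def test_scaled_from_peak(self):
        hist = {1: 1000, 2: 100, 60: 5000, 61: 4000}
        assert kmers.coverage_cutoff(hist).cutoff == 6

    def test_clamped_low(self):
        hist = {1: 1000, 2: 100, 20: 5000}
        assert kmers.coverage_cutoff(hist).cutoff == 3

    def test_clamped_high(self):
        hist = {1: 1000, 2: 100, 300: 5000}
        assert kmers.coverage_cutoff(hist).cutoff == 15

    def test_error_mode_ignored(self):
        hist = {1: 10**6, 2: 10**5, 40: 2000}
        assert kmers.coverage_cutoff(hist).cutoff == 4

    def test_no_signal_raises(self):
        with pytest.raises(kmers.InsufficientCoverageError):
            kmers.coverage_cutoff({1: 1000, 2: 100})


class TestSexSpecificSet:
    def test_basic_subtraction(self):
        focal = make_table({"AAAC": 10, "AACC": 10, "ACCC": 10}, 4)
        opposite = make_table({"AACC": 10}, 4)
        result = kmers.sex_specific_set(focal, opposite, 3, 1)
        assert result.kmers == {"AAAC", "ACCC"}

    def test_identical_tables_empty(self):
        t = make_table({"AAAC": 10, "AACC": 5}, 4)
        assert len(kmers.sex_specific_set(t, t, 3, 1)) == 0

    def test_cutoff_applied(self):
        focal = make_table({"AAAC": 2, "AACC": 10}, 4)
        result = kmers.sex_specific_set(focal, make_table({}, 4), 3, 1)
        assert result.kmers == {"AACC"}

    def test_opposite_presence_min(self):
        focal = make_table({"AAAC": 10, "AACC": 10}, 4)
        opposite = make_table({"AAAC": 1}, 4)
        strict = kmers.sex_specific_set(focal, opposite, 3, 1)
        tolerant = kmers.sex_specific_set(focal, opposite, 3, 2)
        assert strict.kmers == {"AACC"}
        assert tolerant.kmers == {"AAAC", "AACC"}

    def test_mismatched_k_raises(self):
        with pytest.raises(ValueError):
            kmers.sex_specific_set(make_table({"AAAC": 5}, 4),
                                   make_table({"AAACC": 5}, 5), 3)

    def test_subtraction_soundness(self, rng):
        focal = kmers.count_kmers(
            ["".join(rng.choice(list("ACGT"), size=400))], kmers.KmerSpace(8))
        opposite = kmers.count_kmers(
            ["".join(rng.choice(list("ACGT"), size=400))], kmers.KmerSpace(8))
        result = kmers.sex_specific_set(focal, opposite, 1, 1)
        for w in result.kmers:
            assert opposite.get(w) == 0


def _setf(words, k, species="sp", sex="male"):
    codes = np.unique(np.array(
        [dna.kmer_to_code(dna.canonical(w)) for w in words], dtype=np.uint64))
    return kmers.SexSpecificSet(species, sex, codes, k, 3, 1)


class TestSurvivalCurve:
    def test_identical_sets(self, rng):
        words = {"".join(rng.choice(list("ACGT"), size=8)) for _ in range(150)}
        sets = [_setf(words, 8, f"s{i}") for i in range(3)]
        n = len(sets[0].codes)
        assert list(kmers.survival_curve(sets).counts) == [n, n, n]

    def test_disjoint_sets(self):
        sets = [_setf({"AAAA"}, 4, "a"), _setf({"AACC"}, 4, "b"),
                _setf({"ACCC"}, 4, "c")]
        assert list(kmers.survival_curve(sets).counts) == [3, 0, 0]

    def test_mixed_sex_raises(self):
        with pytest.raises(ValueError):
            kmers.survival_curve([_setf({"AAAA"}, 4, sex="male"),
                                  _setf({"AAAA"}, 4, sex="female")])

    def test_needs_two_species(self):
        with pytest.raises(ValueError):
            kmers.survival_curve([_setf({"AAAA"}, 4)])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.sets(st.sampled_from(
        ["AAAA", "AACC", "ACCC", "AAGG", "ATAT", "CGCG", "AATT", "ACGT"])),
        min_size=2, max_size=6))
    def test_monotone_nonincreasing(self, word_sets):
        sets = [_setf(ws, 4, f"s{i}") for i, ws in enumerate(word_sets)]
        counts = kmers.survival_curve(sets).counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cumulative_order_mode(self):
        sets = [_setf({"AAAA", "AACC"}, 4, "a"), _setf({"AAAA"}, 4, "b"),
                _setf({"ACCC"}, 4, "c")]
        curve = kmers.survival_curve(sets, cumulative_order=True)
        assert list(curve.counts) == [2, 1, 0]


class TestGenusConserved:
    def test_intersection_minus_females(self):
        males = [_setf({"AAAA", "AACC", "ACCC"}, 4, "a"),
                 _setf({"AAAA", "AACC"}, 4, "b")]
        females = [make_table({"AACC": 1}, 4)]
        out = kmers.genus_conserved_set(males, females)
        assert out.tolist() == [dna.kmer_to_code("AAAA")]

    def test_female_without_male_sample_excludes(self):
        males = [_setf({"AAAA", "AACC"}, 4, "a")]
        females = [make_table({}, 4), make_table({"AAAA": 1}, 4)]
        out = kmers.genus_conserved_set(males, females)
        assert [dna.code_to_kmer(int(c), 4) for c in out] == ["AACC"]

    def test_presence_min_respected(self):
        males = [_setf({"AAAA"}, 4, "a")]
        females = [make_table({"AAAA": 1}, 4)]
        assert kmers.genus_conserved_set(males, females, 2).size == 1
        assert kmers.genus_conserved_set(males, females, 1).size == 0

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            kmers.genus_conserved_set([], [])


class TestSelectReads:
    def _reads(self, seqs):
        return [FastqRecord(f"r{i}", s, "I" * len(s))
                for i, s in enumerate(seqs)]

    def test_empty_kmer_set(self):
        reads = self._reads(["ACGTACGT"])
        assert list(kmers.select_reads_with_kmers(reads, set(), 4)) == []

    def test_all_from_block_selected(self, rng):
        block = "".join(rng.choice(list("ACGT"), size=200))
        reads = self._reads([block[i : i + 50] for i in range(0, 150, 10)])
        queries = {block[i : i + 16] for i in range(0, 180, 7)}
        kept = list(kmers.select_reads_with_kmers(reads, queries))
        assert kept == reads

    def test_matches_bruteforce_scan(self, rng):
        reads = self._reads(
            ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(200)])
        queries = {"".join(rng.choice(list("ACGT"), size=8))
                   for _ in range(300)}
        kept = {r.id for r in kmers.select_reads_with_kmers(reads, queries, 8)}
        expected = {r.id for r in reads
                    if naive_substring_hits(queries, r.seq, 8)}
        assert kept == expected

    def test_reverse_strand_match(self):
        reads = self._reads(["TTTTGGGG"])
        # query is the reverse complement of a read substring
        kept = list(kmers.select_reads_with_kmers(reads, {"CCCCAAAA"}, 8))
        assert len(kept) == 1

    def test_order_preserved(self, rng):
        reads = self._reads(
            ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(50)])
        queries = {reads[i].seq[:8] for i in (3, 10, 40)}
        kept = [r.id for r in kmers.select_reads_with_kmers(reads, queries, 8)]
        assert kept == sorted(kept, key=lambda x: int(x[1:]))

    def test_pair_selection_keeps_mates(self):
        r1 = [FastqRecord("a/1", "AAAATTTT", "I" * 8),
              FastqRecord("b/1", "CCCCGGGG", "I" * 8)]
        r2 = [FastqRecord("a/2", "GGGGGGGG", "I" * 8),
              FastqRecord("b/2", "TTTTTTTA", "I" * 8)]
        kept = list(kmers.select_read_pairs_with_kmers(
            zip(r1, r2), {"TTTTTTTA"}, 8))
        assert [p[0].id for p in kept] == ["b/1"]
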