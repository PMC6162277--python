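import math

import numpy as np
import pytest

from sexlink import dna, kmers
from sexlink.synthetic import (GenusModel, ReadSimSpec, genome_kmer_codes,
                               jc_branch_for_divergence, jc_divergence,
                               place_clustered_snps, simulate_genus,
                               simulate_reads, star_tree)

from oracles import naive_kmer_set


class TestGenusModel:
    def test_leaf_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="leaves"):
            GenusModel(species_tree=star_tree(3, 0.01), n_species=4,
                       autosome_length=1000, xy_shared_length=500,
                       y_specific_blocks=[("b", 100)])

    def test_block_longer_than_chromosome_raises(self):
        with pytest.raises(ValueError, match="longer"):
            GenusModel(species_tree=star_tree(2, 0.01), n_species=2,
                       autosome_length=1000, xy_shared_length=500,
                       y_specific_blocks=[("b", 600)])

    def test_snp_rate_bounds(self):
        with pytest.raises(ValueError):
            GenusModel(species_tree=star_tree(2, 0.01), n_species=2,
                       autosome_length=1000, xy_shared_length=500,
                       y_specific_blocks=[], snp_rate_target=0.3)

    def test_jc_roundtrip(self):
        for d in (0.01, 0.05, 1 / 16.5):
            assert jc_divergence(jc_branch_for_divergence(d)) == pytest.approx(d)


class TestZeroDivergence:
    def test_genomes_identical_except_y_block(self, zero_div_genus):
        samples, truth = zero_div_genus
        males = [s for s in samples if s.sex == "male"]
        females = [s for s in samples if s.sex == "female"]
        auto0 = males[0].haplotypes["autosome"][0]
        assert all(s.haplotypes["autosome"][0] == auto0 for s in samples)
        y0 = males[0].haplotypes["sex"][1]
        assert all(m.haplotypes["sex"][1] == y0 for m in males)
        x0 = females[0].haplotypes["sex"][0]
        assert all(f.haplotypes["sex"][0] == x0 for f in females)
        assert y0 != x0

    def test_truth_equals_block_unique_kmers(self, zero_div_genus):
        samples, truth = zero_div_genus
        male = next(s for s in samples if s.sex == "male")
        female = next(s for s in samples if s.sex == "female")
        male_set = naive_kmer_set([s for _, s in male.all_sequences()], 16)
        female_set = naive_kmer_set([s for _, s in female.all_sequences()], 16)
        assert truth.genus_kmers() == male_set - female_set

    def test_male_block_copy_counts(self, zero_div_genus):
        samples, _ = zero_div_genus
        for s in samples:
            n_blocks = len([b for b in s.blocks if b[0] == "blk"])
            assert n_blocks == (1 if s.sex == "male" else 0)


def test_empty_y_blocks_empty_truth():
    model = GenusModel(species_tree=star_tree(2, 0.01), n_species=2,
                       autosome_length=5000, xy_shared_length=2000,
                       y_specific_blocks=[], with_hermaphrodite=False, seed=3)
    _, truth = simulate_genus(model, k=16)
    assert truth.genus_codes.size == 0


def test_pairwise_divergence_matches_binomial_expectation():
    # branch lengths tuned for 1 SNP / 16.5 bp between any male pair
    L = 50_000
    rate = 1 / 16.5
    model = GenusModel(species_tree=star_tree(3, rate), n_species=3,
                       autosome_length=L, xy_shared_length=1000,
                       y_specific_blocks=[], with_hermaphrodite=False, seed=5)
    samples, _ = simulate_genus(model, k=16)
    males = [s for s in samples if s.sex == "male"]
    a = np.frombuffer(males[0].haplotypes["autosome"][0].encode(), np.uint8)
    b = np.frombuffer(males[1].haplotypes["autosome"][0].encode(), np.uint8)
    observed = int((a != b).sum())
    expected = L * rate
    sd = math.sqrt(L * rate * (1 - rate))
    assert abs(observed - expected) <= 3 * sd


def test_hermaphrodite_carries_two_block_copies(small_genus):
    samples, _ = small_genus
    herm = next(s for s in samples if s.sex == "hermaphrodite")
    assert len(herm.blocks) == 2
    for label, chrom, s, e in herm.blocks:
        seq = herm.haplotypes["sex"][int(chrom[-1])][s:e]
        assert len(seq) == e - s
    h0, h1 = herm.haplotypes["sex"]
    assert h0 == h1


def test_truth_soundness_exhaustive(small_genus):
    samples, truth = small_genus
    truth_codes = truth.genus_codes
    for s in samples:
        genome = genome_kmer_codes(s, 16)
        present = np.isin(truth_codes, genome, assume_unique=True)
        if s.sex == "male":
            assert present.all()
        elif s.sex == "female":
            assert not present.any()


def test_seeded_reproducibility():
    model = GenusModel.default(n_species=3, autosome_length=10_000,
                               xy_shared_length=3_000, y_block_length=1_000,
                               seed=9)
    s1, t1 = simulate_genus(model, k=16)
    s2, t2 = simulate_genus(model, k=16)
    assert [s.all_sequences() for s in s1] == [s.all_sequences() for s in s2]
    assert np.array_equal(t1.genus_codes, t2.genus_codes)


class TestSimulateReads:
    def test_error_free_reads_cover_all_kmers(self, rng):
        model = GenusModel(species_tree=star_tree(2, 0.01), n_species=2,
                           autosome_length=10_000, xy_shared_length=2_000,
                           y_specific_blocks=[], with_hermaphrodite=False,
                           seed=1)
        samples, _ = simulate_genus(model, k=16)
        sample = samples[0]
        spec = ReadSimSpec(read_length=100, coverage=30, error_rate=0.0, seed=2)
        reads = simulate_reads(sample, spec)
        read_set = naive_kmer_set([r.seq for r in reads], 16)
        genome_set = naive_kmer_set([s for _, s in sample.all_sequences()], 16)
        assert genome_set <= read_set

    def test_sparse_coverage_misses_kmers(self):
        model = GenusModel.default(n_species=2, autosome_length=20_000,
                                   xy_shared_length=2_000, y_block_length=500,
                                   with_hermaphrodite=False, seed=1)
        samples, _ = simulate_genus(model, k=16)
        spec = ReadSimSpec(read_length=100, coverage=0.01, error_rate=0.0,
                           seed=2)
        reads = simulate_reads(samples[0], spec)
        read_set = naive_kmer_set([r.seq for r in reads], 16)
        genome_set = naive_kmer_set(
            [s for _, s in samples[0].all_sequences()], 16)
        assert read_set < genome_set

    def test_same_seed_identical_fastq(self, small_genus):
        samples, _ = small_genus
        spec = ReadSimSpec(read_length=80, coverage=2, error_rate=0.01, seed=4)
        r1 = simulate_reads(samples[0], spec)
        r2 = simulate_reads(samples[0], spec)
        assert r1 == r2

    def test_read_length_exceeds_chromosome_raises(self, small_genus):
        samples, _ = small_genus
        spec = ReadSimSpec(read_length=50_000, coverage=1, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_reads(samples[0], spec)

    def test_paired_reads(self, small_genus):
        samples, _ = small_genus
        spec = ReadSimSpec(read_length=80, coverage=1, error_rate=0.0,
                           paired=True, insert_size=300, seed=4)
        reads = simulate_reads(samples[0], spec)
        assert len(reads) % 2 == 0
        assert reads[0].id.endswith("/1") and reads[1].id.endswith("/2")

    def test_depth_and_hemizygosity(self, small_genus):
        samples, _ = small_genus
        male = next(s for s in samples if s.sex == "male")
        spec = ReadSimSpec(read_length=100, coverage=30, error_rate=0.0, seed=6)
        reads = simulate_reads(male, spec)
        # depth proxy: exact-k-mer multiplicity from the sample's own genome
        table = kmers.count_kmers(reads, kmers.KmerSpace(16))
        label, chrom, s, e = male.blocks[0]
        block_seq = male.haplotypes["sex"][1][s:e]
        auto_seq = male.haplotypes["autosome"][0][10_000:20_000]
        block_depth = np.mean([table.get(block_seq[i : i + 16])
                               for i in range(0, len(block_seq) - 16, 7)])
        auto_depth = np.mean([table.get(auto_seq[i : i + 16])
                              for i in range(0, len(auto_seq) - 16, 7)])
        assert abs(block_depth / auto_depth - 0.5) < 0.1 * 0.5 + 0.05


class TestClusteredSnps:
    def test_fraction_recovered(self, rng):
        from sexlink.calibration import fraction_snps_within

        pos = place_clustered_snps(2_000_000, 5_000, 0.68, 16, rng)
        assert fraction_snps_within(pos, 16) == pytest.approx(0.68, abs=0.05)

    def test_zero_clustering(self, rng):
        from sexlink.calibration import fraction_snps_within

        pos = place_clustered_snps(2_000_000, 3_000, 0.0, 16, rng)
        assert fraction_snps_within(pos, 16) == 0.0

    def test_density_too_high_raises(self, rng):
        with pytest.raises(ValueError):
            place_clustered_snps(1_000, 500, 0.5, 16, rng)


def test_repeat_fraction_fills_prefix():
    model = GenusModel(species_tree=star_tree(2, 0.0), n_species=2,
                       autosome_length=10_000, xy_shared_length=2_000,
                       y_specific_blocks=[], repeat_fraction=0.2,
                       with_hermaphrodite=False, seed=8)
    samples, _ = simulate_genus(model, k=16)
    auto = samples[0].haplotypes["autosome"][0]
    motif = auto[:50]
    assert auto[50:100] == motif and auto[100:150] == motif
    assert auto[2000:2050] != motif or auto != motif * 200
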