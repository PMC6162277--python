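"""Synthetic dioecious genus: genomes, short reads and ground truth.

A genus is simulated by evolving ancestral autosomal and sex-chromosome
sequences along a species tree under site-wise uniform (Jukes–Cantor-like)
substitution, then assembling per-sample diploid genomes: males carry one
X-like and one Y-like haplotype with hemizygous Y-specific blocks inserted;
females carry two X-like haplotypes; an optional hermaphrodite outgroup
carries the Y-specific blocks on both haplotypes (a 2N control).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from . import dna
from .io import FastqRecord

AUTOSOME = "autosome"
SEXCHROM = "sex"


def jc_divergence(path_length: float) -> float:
    """Expected per-site difference after total branch path t under JC."""
    return 0.75 * (1.0 - math.exp(-4.0 * path_length / 3.0))


def jc_branch_for_divergence(d: float) -> float:
    """Branch length giving expected per-site difference d under JC."""
    if not 0 <= d < 0.75:
        raise ValueError("divergence must lie in [0, 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * d / 3.0)


def star_tree(n_species: int, pairwise_divergence: float) -> str:
    """Newick star tree whose leaf pairs differ at the given expected rate."""
    total = jc_branch_for_divergence(pairwise_divergence)
    b = total / 2.0
    leaves = ",".join(f"sp{i + 1}:{b:.10f}" for i in range(n_species))
    return f"({leaves});"


@dataclass
class GenusModel:
    """Parameters of the simulated genus."""

    species_tree: str
    n_species: int
    autosome_length: int
    xy_shared_length: int
    y_specific_blocks: list[tuple[str, int]]
    x_deletion_blocks: list[tuple[str, int]] = field(default_factory=list)
    repeat_fraction: float = 0.0
    snp_rate_target: float = 1.0 / 16.5
    snp_cluster_fraction: float = 0.0
    with_hermaphrodite: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if min(self.autosome_length, self.xy_shared_length) <= 0:
            raise ValueError("all lengths must be > 0")
        if any(l <= 0 for _, l in self.y_specific_blocks):
            raise ValueError("all lengths must be > 0")
        if any(l > self.xy_shared_length for _, l in self.y_specific_blocks):
            raise ValueError("y_specific block longer than the sex chromosome")
        if not 0 < self.snp_rate_target <= 0.25:
            raise ValueError("snp_rate_target must lie in (0, 0.25]")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must lie in [0, 1)")
        tree = self.tree()
        n_leaves = len(tree.leaf_nodes())
        if n_leaves != self.n_species:
            raise ValueError(
                f"tree has {n_leaves} leaves but n_species={self.n_species}"
            )
        total_del = sum(l for _, l in self.x_deletion_blocks)
        if total_del >= self.xy_shared_length:
            raise ValueError("x_deletion blocks longer than the shared region")

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.species_tree, schema="newick")

    @classmethod
    def default(cls, n_species: int = 6, autosome_length: int = 200_000,
                xy_shared_length: int = 10_000,
                y_block_length: int = 5_000, seed: int = 0, **kwargs) -> "GenusModel":
        """Genus on a star tree tuned to the default inter-male SNP spacing."""
        rate = kwargs.pop("snp_rate_target", 1.0 / 16.5)
        blocks = [("yblock1", y_block_length)] if y_block_length > 0 else []
        return cls(
            species_tree=star_tree(n_species, rate),
            n_species=n_species,
            autosome_length=autosome_length,
            xy_shared_length=xy_shared_length,
            y_specific_blocks=blocks,
            snp_rate_target=rate,
            seed=seed,
            **kwargs,
        )


@dataclass
class SampleGenome:
    """One diploid sample: two haplotypes per chromosome class."""

    species: str
    sex: str  # male | female | hermaphrodite
    haplotypes: dict[str, tuple[str, str]]
    blocks: list[tuple[str, str, int, int]]  # (label, "class/hapIndex", start, end)

    @property
    def name(self) -> str:
        return f"{self.species}_{self.sex}"

    def all_sequences(self) -> list[tuple[str, str]]:
        out = []
        for chrom, (h1, h2) in sorted(self.haplotypes.items()):
            out.append((f"{self.name}|{chrom}/0", h1))
            out.append((f"{self.name}|{chrom}/1", h2))
        return out

    def total_bases(self) -> int:
        return sum(len(h1) + len(h2) for h1, h2 in self.haplotypes.values())


@dataclass
class ReadSimSpec:
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.005
    paired: bool = False
    insert_size: int = 400
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must lie in [0, 0.1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        if self.paired and self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length for paired reads")


@dataclass
class TruthTable:
    """Ground-truth male-specific k-mers and planted block coordinates."""

    k: int
    per_species: dict[str, np.ndarray]  # species -> sorted canonical codes
    genus_codes: np.ndarray  # male-specific in every species
    blocks: list[tuple[str, str, int, int, str]]  # label, sample, chrom/hap, coords

    def genus_kmers(self) -> frozenset[str]:
        return frozenset(dna.code_to_kmer(int(c), self.k) for c in self.genus_codes)

    def block_bed(self) -> list[tuple[str, int, int, str]]:
        return [
            (f"{sample}|{chrom}", start, end, label)
            for label, sample, chrom, start, end in self.blocks
        ]


def _leaf_depth(leaf) -> float:
    d, node = 0.0, leaf
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def mutate(seq: np.ndarray, branch_length: float, rng: np.random.Generator
           ) -> np.ndarray:
    """Site-wise JC substitution along one branch (no indels)."""
    if branch_length <= 0:
        return seq.copy()
    p = jc_divergence(branch_length)
    hit = rng.random(seq.size) < p
    out = seq.copy()
    # shift by 1..3 mod 4: uniform over the three other bases
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)) % 4
    return out


def place_clustered_snps(length: int, n_snps: int, cluster_fraction: float,
                         d: int, rng: np.random.Generator) -> np.ndarray:
    """SNP positions where ~cluster_fraction of SNPs lie within d of another.

    Builds isolated singletons plus within-d pairs on a grid that keeps
    groups more than d apart; intended for low densities (n*(2d+2) << length).
    """
    if not 0 <= cluster_fraction <= 1:
        raise ValueError("cluster_fraction must lie in [0, 1]")
    n_pairs = int(round(cluster_fraction * n_snps / 2))
    n_singles = n_snps - 2 * n_pairs
    n_groups = n_pairs + n_singles
    slot = 2 * d + 2
    if n_groups * slot > length:
        raise ValueError("too many SNPs for clustered placement at this length")
    anchors = (np.sort(rng.choice(length // slot, size=n_groups, replace=False))
               * slot)
    rng.shuffle(kinds := np.array([True] * n_pairs + [False] * n_singles))
    positions = []
    for a, is_pair in zip(anchors, kinds):
        positions.append(a)
        if is_pair:
            positions.append(a + int(rng.integers(1, d + 1)))
    return np.unique(np.array(positions, dtype=np.int64))


def _evolve_along_tree(ancestor: np.ndarray, tree: dendropy.Tree,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Sequence at each leaf after substitution along every branch."""
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): ancestor}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            cur = ancestor
        else:
            parent = seqs[id(node.parent_node)]
            cur = mutate(parent, node.edge.length or 0.0, rng)
        seqs[id(node)] = cur
        if node.is_leaf():
            out[node.taxon.label.replace(" ", "_")] = cur
    return out


def _insert_blocks(base: np.ndarray, blocks: list[tuple[str, np.ndarray]]
                   ) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Insert blocks at evenly spaced anchors; returns sequence + coords."""
    if not blocks:
        return base, []
    anchors = np.linspace(0, base.size, num=len(blocks) + 2, dtype=np.int64)[1:-1]
    pieces, coords = [], []
    prev = 0
    offset = 0
    for (label, block), anchor in zip(blocks, anchors):
        pieces.append(base[prev:anchor])
        offset += anchor - prev
        coords.append((label, int(offset), int(offset + block.size)))
        pieces.append(block)
        offset += block.size
        prev = anchor
    pieces.append(base[prev:])
    return np.concatenate(pieces), coords


def _delete_blocks(base: np.ndarray, lengths: list[tuple[str, int]]
                   ) -> np.ndarray:
    if not lengths:
        return base
    total = sum(l for _, l in lengths)
    anchors = np.linspace(0, base.size - total, num=len(lengths) + 2,
                          dtype=np.int64)[1:-1]
    keep = np.ones(base.size, dtype=bool)
    shift = 0
    for (label, length), anchor in zip(lengths, anchors):
        start = int(anchor) + shift
        keep[start : start + length] = False
        shift += length
    return base[keep]


def _with_repeats(seq: np.ndarray, fraction: float, motif_len: int = 50
                  ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Overwrite a prefix-fraction of the sequence with an exact tandem motif."""
    if fraction <= 0:
        return seq, []
    n_rep = int(seq.size * fraction)
    motif = seq[:motif_len]
    tiled = np.tile(motif, n_rep // motif_len + 1)[:n_rep]
    out = seq.copy()
    out[:n_rep] = tiled
    return out, [(0, n_rep)]


def simulate_genus(model: GenusModel, k: int = 16
                   ) -> tuple[list[SampleGenome], TruthTable]:
    """Simulate the genus and compute the exhaustive ground-truth k-mer sets."""
    rng = np.random.default_rng(model.seed)
    tree = model.tree()

    anc_autosome = _random_seq(model.autosome_length, rng)
    anc_autosome, repeat_spans = _with_repeats(anc_autosome, model.repeat_fraction)
    anc_xy = _random_seq(model.xy_shared_length, rng)
    anc_blocks = [(label, _random_seq(length, rng))
                  for label, length in model.y_specific_blocks]

    # the shared X/Y background recombines, so within a species the male Y
    # equals the species X background; only the planted blocks evolve as a
    # non-recombining unit (along the same tree)
    auto_by_sp = _evolve_along_tree(anc_autosome, tree, np.random.default_rng(rng.integers(2**63)))
    xy_by_sp = _evolve_along_tree(anc_xy, tree, np.random.default_rng(rng.integers(2**63)))
    blocks_by_sp = {
        label: _evolve_along_tree(block, tree, np.random.default_rng(rng.integers(2**63)))
        for label, block in anc_blocks
    }

    species = sorted(auto_by_sp)
    samples: list[SampleGenome] = []
    truth_blocks: list[tuple[str, str, int, int, str]] = []
    block_coords: list[tuple[str, int, int]] = []
    for sp in species:
        auto = dna.decode(auto_by_sp[sp])
        x = dna.decode(_delete_blocks(xy_by_sp[sp], model.x_deletion_blocks))
        y_arr, block_coords = _insert_blocks(
            xy_by_sp[sp], [(label, blocks_by_sp[label][sp])
                           for label, _ in anc_blocks])
        y = dna.decode(y_arr)
        male = SampleGenome(
            species=sp, sex="male",
            haplotypes={AUTOSOME: (auto, auto), SEXCHROM: (x, y)},
            blocks=[(label, f"{SEXCHROM}/1", s, e) for label, s, e in block_coords],
        )
        female = SampleGenome(
            species=sp, sex="female",
            haplotypes={AUTOSOME: (auto, auto), SEXCHROM: (x, x)},
            blocks=[],
        )
        samples.extend([male, female])
        for label, s, e in block_coords:
            truth_blocks.append((label, male.name, f"{SEXCHROM}/1", s, e))

    if model.with_hermaphrodite:
        herm_rng = np.random.default_rng(rng.integers(2**63))
        max_depth = max(_leaf_depth(leaf) for leaf in tree.leaf_node_iter())
        outgroup_branch = 1.5 * max_depth if max_depth > 0 else 0.01
        auto_h = mutate(anc_autosome, outgroup_branch, herm_rng)
        y_h, herm_coords = _insert_blocks(
            mutate(anc_xy, outgroup_branch, herm_rng),
            [(label, mutate(block, outgroup_branch, herm_rng))
             for label, block in anc_blocks])
        # hemizygous blocks are untouched: present on BOTH haplotypes (2N control)
        y_h2 = y_h.copy()
        herm = SampleGenome(
            species="outgroup", sex="hermaphrodite",
            haplotypes={AUTOSOME: (dna.decode(auto_h), dna.decode(auto_h)),
                        SEXCHROM: (dna.decode(y_h), dna.decode(y_h2))},
            blocks=[(label, f"{SEXCHROM}/{i}", s, e)
                    for label, s, e in herm_coords for i in (0, 1)],
        )
        samples.append(herm)
        for label, s, e in block_coords:
            truth_blocks.append((label, herm.name, f"{SEXCHROM}/0", s, e))
            truth_blocks.append((label, herm.name, f"{SEXCHROM}/1", s, e))

    truth = _compute_truth(samples, k, truth_blocks)
    return samples, truth


def genome_kmer_codes(sample: SampleGenome, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a sample's full genome."""
    parts = [dna.sequence_kmer_codes(seq, k) for _, seq in sample.all_sequences()]
    return np.unique(np.concatenate(parts))


def _compute_truth(samples: list[SampleGenome], k: int,
                   blocks: list[tuple[str, str, int, int, str]]) -> TruthTable:
    female_union: np.ndarray | None = None
    male_codes: dict[str, np.ndarray] = {}
    for s in samples:
        if s.sex == "female":
            codes = genome_kmer_codes(s, k)
            female_union = codes if female_union is None else np.union1d(
                female_union, codes)
        elif s.sex == "male":
            male_codes[s.species] = genome_kmer_codes(s, k)
    if female_union is None:
        female_union = np.empty(0, dtype=np.uint64)
    per_species = {
        sp: codes[~np.isin(codes, female_union, assume_unique=True)]
        for sp, codes in male_codes.items()
    }
    genus: np.ndarray | None = None
    for codes in per_species.values():
        genus = codes if genus is None else np.intersect1d(
            genus, codes, assume_unique=True)
    if genus is None:
        genus = np.empty(0, dtype=np.uint64)
    # reorder stored block tuples to (label, sample, chrom, start, end)
    stored = [(label, sample, chrom, s, e) for label, sample, chrom, s, e in blocks]
    return TruthTable(k=k, per_species=per_species, genus_codes=genus, blocks=stored)


def simulate_reads(sample: SampleGenome, spec: ReadSimSpec) -> list[FastqRecord]:
    """Uniform-coverage short reads with i.i.d. substitution errors.

    Expected depth at a diploid locus equals ``spec.coverage``; hemizygous
    loci receive half. Deterministic for a given (sample, spec.seed).
    """
    rng = np.random.default_rng(spec.seed)
    seqs = sample.all_sequences()
    frag_len = spec.insert_size if spec.paired else spec.read_length
    for name, seq in seqs:
        if frag_len > len(seq):
            raise ValueError(
                f"fragment length {frag_len} exceeds sequence {name} "
                f"({len(seq)} bp)"
            )
    encoded = [dna.encode(seq) for _, seq in seqs]
    lengths = np.array([e.size for e in encoded], dtype=np.float64)
    n_starts = lengths - frag_len + 1
    haploid = lengths.sum() / 2.0
    bases_per_fragment = 2 * spec.read_length if spec.paired else spec.read_length
    n_fragments = int(round(spec.coverage * haploid / bases_per_fragment))
    hap_idx = rng.choice(len(encoded), size=n_fragments, p=lengths / lengths.sum())

    reads: list[FastqRecord] = []
    qual = "I" * spec.read_length
    for i in range(len(encoded)):
        mine = int((hap_idx == i).sum())
        if mine == 0:
            continue
        # extended range clipped to the boundary: terminal windows would
        # otherwise see far fewer admissible starts and drop out at any depth
        starts = np.clip(
            rng.integers(1 - frag_len, int(n_starts[i]) + frag_len - 1,
                         size=mine),
            0, int(n_starts[i]) - 1)
        windows = np.lib.stride_tricks.sliding_window_view(
            encoded[i], frag_len)[starts]
        fwd = windows[:, : spec.read_length]
        fwd = _apply_errors(fwd, spec.error_rate, rng)
        fwd_txt = dna.decode(fwd.ravel())
        if spec.paired:
            rev = windows[:, -spec.read_length :][:, ::-1]
            rev = (3 - rev) % 4
            rev = _apply_errors(np.ascontiguousarray(rev), spec.error_rate, rng)
            rev_txt = dna.decode(rev.ravel())
        rl = spec.read_length
        for j in range(mine):
            rid = f"{sample.name}:{i}:{int(starts[j])}:{j}"
            if spec.paired:
                reads.append(FastqRecord(rid + "/1", fwd_txt[j * rl : (j + 1) * rl], qual))
                reads.append(FastqRecord(rid + "/2", rev_txt[j * rl : (j + 1) * rl], qual))
            else:
                reads.append(FastqRecord(rid, fwd_txt[j * rl : (j + 1) * rl], qual))
    return reads


def _apply_errors(reads: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return reads
    out = reads.copy()
    hit = rng.random(out.shape) < error_rate
    n = int(hit.sum())
    out[hit] = (out[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out
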