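"""Counting-based synonymous/nonsynonymous rate estimation (NG86-style)
with Jukes–Cantor correction, per-gene summaries across species, and
relative clade-depth on ultrametric trees.

Conventions: per codon position, synonymous sites are (number of synonymous
single-base changes)/3 and nonsynonymous sites (nonsynonymous, non-stop
changes)/3, so changes to stop codons are excluded and S + N for a codon
equals 3 minus the stop adjustment. Pairwise differences are averaged
uniformly over minimal substitution pathways; pathways passing through a
stop codon are excluded unless all of them do.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

BASES = "ACGT"


class SaturationError(ValueError):
    """Raised when p >= 3/4 makes the Jukes–Cantor correction undefined."""


def standard_code() -> dict[str, str]:
    """Codon -> amino acid ('*' for stop), universal genetic code."""
    table = _BioCodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


_CODE = standard_code()


@dataclass(frozen=True)
class SiteCounts:
    label: str
    S: float
    N: float
    stop_adjustment: float


@dataclass
class PairwiseRates:
    pair: tuple[str, str]
    S_mean: float
    N_mean: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # nan when saturated
    dN: float
    omega: float  # nan when undefined (dS == 0 or saturated)
    saturated_s: bool = False
    saturated_n: bool = False


@dataclass
class GeneRateSummary:
    gene: str
    outgroup: str
    per_species: dict[str, PairwiseRates]
    mean_dS: float
    sd_dS: float
    mean_dN: float
    sd_dN: float
    mean_omega: float
    sd_omega: float


class CodonAlignment:
    """In-frame alignment; codon columns with gaps/ambiguity are dropped.

    A stop codon in the final column (in any sequence) causes the whole
    final column to be dropped; an internal stop is an error.
    """

    def __init__(self, sequences: Mapping[str, str],
                 code: Mapping[str, str] | None = None):
        if not sequences:
            raise ValueError("empty alignment")
        self.code = dict(code or _CODE)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must share one length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length must be a multiple of 3")
        seqs = {k: v.upper() for k, v in sequences.items()}
        n_cols = length // 3
        keep: list[int] = []
        self.dropped_columns: list[int] = []
        for col in range(n_cols):
            codons = [s[3 * col : 3 * col + 3] for s in seqs.values()]
            if all(all(b in BASES for b in c) for c in codons):
                keep.append(col)
            else:
                self.dropped_columns.append(col)
        if n_cols and keep:
            last = keep[-1]
            if any(self.code.get(s[3 * last : 3 * last + 3]) == "*"
                   for s in seqs.values()):
                self.dropped_columns.append(keep.pop())
        self.sequences = {
            name: "".join(s[3 * c : 3 * c + 3] for c in keep)
            for name, s in seqs.items()
        }
        for name, s in self.sequences.items():
            for col in range(len(s) // 3):
                if self.code[s[3 * col : 3 * col + 3]] == "*":
                    raise ValueError(f"internal stop codon in {name!r}")

    @property
    def labels(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3


@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str) -> tuple[float, float, float]:
    """(syn sites, nonsyn sites, stop adjustment) for one codon."""
    aa = _CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon}")
    syn = nonsyn = stop = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = _CODE[alt]
            if alt_aa == "*":
                stop += 1
            elif alt_aa == aa:
                syn += 1
            else:
                nonsyn += 1
    return syn / 3.0, nonsyn / 3.0, stop / 3.0


def codon_sites(sequence: str, label: str = "") -> SiteCounts:
    """Fractional synonymous/nonsynonymous site counts of a sequence."""
    seq = sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    S = N = adj = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if any(b not in BASES for b in codon):
            raise ValueError(
                f"non-ACGT codon {codon!r} at position {i}: drop the column first"
            )
        s, n, a = _codon_site_fractions(codon)
        S += s
        N += n
        adj += a
    return SiteCounts(label=label, S=S, N=N, stop_adjustment=adj)


@lru_cache(maxsize=None)
def pairwise_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over minimal substitution pathways."""
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if _CODE.get(c) is None:
            raise ValueError(f"invalid codon {c!r}")
        if _CODE[c] == "*":
            raise ValueError(f"stop codon {c!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = a
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _CODE[nxt] == "*":
                valid = False
            if _CODE[nxt] == _CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((valid, sd, nd))
    usable = [(s, n) for ok, s, n in paths if ok]
    if not usable:
        usable = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC distance from a proportion of differing sites; nan at saturation."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(alignment: CodonAlignment, pair: tuple[str, str],
         strict: bool = False) -> PairwiseRates:
    """Pairwise dS/dN for two sequences of an in-frame alignment.

    Saturation (p >= 3/4) yields nan rates with the corresponding flag set;
    with ``strict`` it raises :class:`SaturationError` instead.
    """
    a_label, b_label = pair
    try:
        sa = alignment.sequences[a_label]
        sb = alignment.sequences[b_label]
    except KeyError as exc:
        raise ValueError(f"pair member {exc} not in alignment") from exc
    sites_a = codon_sites(sa, a_label)
    sites_b = codon_sites(sb, b_label)
    S_mean = (sites_a.S + sites_b.S) / 2.0
    N_mean = (sites_a.N + sites_b.N) / 2.0
    Sd = Nd = 0.0
    for i in range(0, len(sa), 3):
        sd, nd = pairwise_differences(sa[i : i + 3], sb[i : i + 3])
        Sd += sd
        Nd += nd
    pS = Sd / S_mean if S_mean > 0 else 0.0
    pN = Nd / N_mean if N_mean > 0 else 0.0
    sat_s, sat_n = pS >= 0.75, pN >= 0.75
    if strict and (sat_s or sat_n):
        raise SaturationError(
            f"pair {pair}: p {'S' if sat_s else 'N'} >= 3/4, "
            "Jukes-Cantor correction undefined"
        )
    dS = jukes_cantor(pS) if not sat_s else float("nan")
    dN = jukes_cantor(pN) if not sat_n else float("nan")
    omega = dN / dS if (not math.isnan(dS) and not math.isnan(dN) and dS > 0) else (
        float("nan"))
    return PairwiseRates(pair=(a_label, b_label), S_mean=S_mean, N_mean=N_mean,
                         Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega,
                         saturated_s=sat_s, saturated_n=sat_n)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        return float("nan"), float("nan")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


def gene_summary(alignment: CodonAlignment, outgroup_label: str,
                 species_labels: Sequence[str] | None = None,
                 gene: str = "") -> GeneRateSummary:
    """Per-species rates against a designated outgroup, with mean/sample-SD."""
    if outgroup_label not in alignment.sequences:
        raise ValueError(f"outgroup {outgroup_label!r} not in alignment")
    if species_labels is None:
        species_labels = [l for l in alignment.labels if l != outgroup_label]
    per_species = {
        sp: ng86(alignment, (sp, outgroup_label)) for sp in species_labels
    }
    rates = list(per_species.values())
    if all(r.saturated_s for r in rates):
        raise SaturationError("all species saturated against the outgroup")
    mean_dS, sd_dS = _mean_sd([r.dS for r in rates])
    mean_dN, sd_dN = _mean_sd([r.dN for r in rates])
    mean_w, sd_w = _mean_sd([r.omega for r in rates])
    return GeneRateSummary(gene=gene, outgroup=outgroup_label,
                           per_species=per_species,
                           mean_dS=mean_dS, sd_dS=sd_dS,
                           mean_dN=mean_dN, sd_dN=sd_dN,
                           mean_omega=mean_w, sd_omega=sd_w)


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        tree.is_rooted = True
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick",
                             rooting="force-rooted")


def relative_clade_depth(tree, clade_leaves: Sequence[str],
                         eps: float = 1e-4) -> float:
    """Depth of a clade's MRCA as a fraction of root depth, in [0, 1].

    The tree must be ultrametric (relative leaf-depth spread <= eps) and the
    leaf set monophyletic.
    """
    t = _as_tree(tree)
    depths = {}
    for leaf in t.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    root_depth = max(depths.values())
    if root_depth <= 0:
        raise ValueError("tree has zero depth")
    if (max(depths.values()) - min(depths.values())) / root_depth > eps:
        raise ValueError("tree is not ultrametric within tolerance")
    want = {l.replace("_", " ") for l in clade_leaves} | set(clade_leaves)
    taxa = [tx for tx in t.taxon_namespace if tx.label in want]
    if len(taxa) != len(set(clade_leaves)):
        raise ValueError("clade leaves not all present in tree")
    mrca = t.mrca(taxa=taxa)
    under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if under != {tx.label for tx in taxa}:
        raise ValueError("clade leaf set is not monophyletic")
    d, node = 0.0, mrca
    while node.parent_node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
    mrca_root_dist = d
    mrca_age = root_depth - mrca_root_dist
    return mrca_age / root_depth


# --- simulation used for parameter-recovery checks -------------------------

def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free in-frame sequence."""
    codons = [c for c, aa in _CODE.items() if aa != "*"]
    idx = rng.integers(0, len(codons), size=n_codons)
    return "".join(codons[i] for i in idx)


def evolve_coding(seq: str, omega: float, n_proposals: int,
                  rng: np.random.Generator) -> str:
    """Propose random single-base changes; accept synonymous ones always,
    nonsynonymous ones with probability omega, changes to stops never."""
    s = list(seq)
    L = len(s)
    for _ in range(n_proposals):
        pos = int(rng.integers(0, L))
        codon_start = pos - pos % 3
        old = "".join(s[codon_start : codon_start + 3])
        alt_base = BASES[int(rng.integers(0, 4))]
        if alt_base == s[pos]:
            continue
        new = old[: pos - codon_start] + alt_base + old[pos - codon_start + 1 :]
        if _CODE[new] == "*":
            continue
        if _CODE[new] == _CODE[old] or rng.random() < omega:
            s[pos] = alt_base
    return "".join(s)


def simulate_coding_alignment(n_codons: int, n_species: int, omega: float,
                              proposals_per_site: float = 0.3,
                              seed: int = 0,
                              outgroup_label: str = "ancestor"
                              ) -> CodonAlignment:
    """Star-shaped divergence from a common ancestor at a target omega.

    The ancestor is included under ``outgroup_label`` so recovered rates can
    be read species-vs-ancestor.
    """
    rng = np.random.default_rng(seed)
    ancestor = random_coding_sequence(n_codons, rng)
    n_prop = int(round(proposals_per_site * 3 * n_codons))
    seqs = {outgroup_label: ancestor}
    for i in range(n_species):
        seqs[f"sp{i + 1}"] = evolve_coding(ancestor, omega, n_prop, rng)
    return CodonAlignment(seqs)
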