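"""Placing sex-specific k-mers onto contigs: exact match profiles,
coverage percentages, density tracks and phased-haplotype selection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import dna


@dataclass
class KmerMatchProfile:
    """Exact k-mer hits on one contig, both strands."""

    contig: str
    length: int
    k: int
    positions: np.ndarray  # 0-based start, sorted
    strands: np.ndarray  # '+' / '-' per hit (orientation of the match)
    support: np.ndarray  # species-support of the matched k-mer (0 if unknown)

    @property
    def n_hits(self) -> int:
        return int(self.positions.size)


@dataclass
class DensityTrack:
    """Per-window hit density stratified by minimum species support."""

    contig: str
    window: int
    thresholds: np.ndarray  # ascending support thresholds
    values: np.ndarray  # shape (n_thresholds, n_windows), k-mers/bp

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("densities must be >= 0")
        if np.any(np.diff(self.values, axis=0) > 1e-12):
            raise ValueError("densities must be non-increasing in support")


@dataclass
class HaplotypePair:
    scaffold: str
    hapA_kmer_count: int
    hapB_kmer_count: int
    selected: bool
    assigned_haplotype: str  # 'A' | 'B' | 'none'


@dataclass
class ConsensusSubstitution:
    """Reference sequence with SNP positions to replace by focal alleles."""

    reference: str
    substitutions: list[tuple[int, str, str]]  # (0-based pos, ref, alt)


def _prepare_query(kmers, k: int | None, support: Mapping[str, int] | None):
    if isinstance(kmers, np.ndarray):
        if k is None:
            raise ValueError("k required with a code array")
        codes = np.unique(kmers.astype(np.uint64))
        sup = np.zeros(codes.size, dtype=np.int64)
        return codes, sup, k
    words = [w.upper() for w in kmers]
    if not words:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64), k or 0
    if k is None:
        k = len(words[0])
    if any(len(w) != k for w in words):
        raise ValueError("query k-mers of mixed length")
    codes = np.array([dna.kmer_to_code(dna.canonical(w)) for w in words],
                     dtype=np.uint64)
    sup = np.array([(support or {}).get(w, 0) for w in words], dtype=np.int64)
    order = np.argsort(codes, kind="stable")
    codes, sup = codes[order], sup[order]
    uniq, idx = np.unique(codes, return_index=True)
    # on duplicate words keep the highest support
    keep_sup = np.maximum.reduceat(sup, idx)
    return uniq, keep_sup, k


def match_kmers(kmers, contigs: Mapping[str, str], k: int | None = None,
                support: Mapping[str, int] | None = None
                ) -> dict[str, KmerMatchProfile]:
    """Exact occurrences of the query set in each contig, both strands.

    A hit at position p is reported with strand '+' when the forward window
    equals its canonical form and '-' otherwise; a multi-site k-mer is
    reported at every site.
    """
    codes, sup, k = _prepare_query(kmers, k, support)
    out: dict[str, KmerMatchProfile] = {}
    for name, seq in contigs.items():
        win, valid = dna.kmer_codes(dna.encode(seq), k)
        canon = dna.canonical_codes(win, k) if win.size else win
        if codes.size and win.size:
            idx = np.searchsorted(codes, canon)
            idx[idx == codes.size] = 0
            hit = valid & (codes[np.minimum(idx, codes.size - 1)] == canon)
        else:
            hit = np.zeros(win.size, dtype=bool)
        positions = np.nonzero(hit)[0].astype(np.int64)
        strands = np.where(win[hit] == canon[hit], "+", "-") if positions.size else (
            np.empty(0, dtype="U1"))
        hit_sup = (sup[np.searchsorted(codes, canon[hit])]
                   if positions.size else np.empty(0, dtype=np.int64))
        out[name] = KmerMatchProfile(
            contig=name, length=len(seq), k=k, positions=positions,
            strands=strands, support=hit_sup,
        )
    return out


def coverage_percent(kmers_by_support: Mapping[int, object],
                     contigs: Mapping[str, str], k: int | None = None
                     ) -> dict[int, float]:
    """% of each >=n-species k-mer set with at least one hit in the contigs."""
    if not contigs:
        raise ValueError("empty contig set")
    contig_codes: np.ndarray | None = None
    out: dict[int, float] = {}
    for n, kmer_set in sorted(kmers_by_support.items()):
        codes, _, kk = _prepare_query(kmer_set, k, None)
        if contig_codes is None:
            parts = [dna.sequence_kmer_codes(seq, kk) for seq in contigs.values()]
            contig_codes = np.unique(np.concatenate(parts)) if parts else (
                np.empty(0, dtype=np.uint64))
        if codes.size == 0:
            out[n] = 0.0
            continue
        matched = np.isin(codes, contig_codes, assume_unique=True)
        out[n] = 100.0 * float(matched.mean())
    return out


def density_track(profile: KmerMatchProfile, window: int,
                  thresholds: Sequence[int] | None = None) -> DensityTrack:
    """K-mers/bp per tiled window, stratified by minimum species support."""
    if window <= 0:
        raise ValueError("window must be > 0")
    n_windows = max(profile.length // window, 1)
    if thresholds is None:
        top = int(profile.support.max()) if profile.support.size else 1
        thresholds = list(range(1, max(top, 1) + 1))
    thr = np.asarray(sorted(thresholds), dtype=np.int64)
    values = np.zeros((thr.size, n_windows), dtype=np.float64)
    if profile.positions.size:
        win_idx = np.minimum(profile.positions // window, n_windows - 1)
        for i, t in enumerate(thr):
            sel = profile.support >= t
            counts = np.bincount(win_idx[sel], minlength=n_windows)
            values[i] = counts / window
    return DensityTrack(contig=profile.contig, window=window,
                        thresholds=thr, values=values)


def select_haplotype_scaffolds(pairs: Sequence[tuple[str, int, int]],
                               min_kmers: int = 100, ratio_min: float = 6.0
                               ) -> list[HaplotypePair]:
    """Phased scaffolds with enough markers concentrated in one haplotype.

    Selected iff max(hapA, hapB) >= min_kmers and the max is at least
    ratio_min times the min (a zero min passes the ratio test). Exact ties
    are rejected: neither haplotype dominates.
    """
    out = []
    for scaffold, a, b in pairs:
        if a < 0 or b < 0:
            raise ValueError(f"{scaffold}: negative k-mer count")
        hi, lo = max(a, b), min(a, b)
        ratio_ok = lo == 0 or hi >= ratio_min * lo
        selected = hi >= min_kmers and ratio_ok and a != b
        assigned = "none"
        if selected:
            assigned = "A" if a > b else "B"
        out.append(HaplotypePair(scaffold, a, b, selected, assigned))
    return out


def apply_substitutions(cons: ConsensusSubstitution) -> str:
    """Replace reference bases with focal alleles at the listed positions."""
    seq = list(cons.reference)
    for pos, ref, alt in cons.substitutions:
        if pos < 0 or pos >= len(seq):
            raise ValueError(f"substitution position {pos} outside reference")
        if seq[pos] != ref:
            raise ValueError(
                f"reference mismatch at {pos}: expected {ref!r}, found {seq[pos]!r}"
            )
        seq[pos] = alt
    return "".join(seq)
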