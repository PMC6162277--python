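"""Copies-per-genome from read depth normalized to a diploid baseline,
plus the control-scaffold expression normalization.

Depth can be ingested from any aligner as mean-depth intervals, or computed
alignment-free as the mean per-position multiplicity of the region's exact
k-mers in a sample's read k-mer table (a faithful surrogate at desk scale,
since the normalization cancels the k-mer/base-depth factor)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import dna
from .kmers import KmerCountTable

LOW_CONFIDENCE_BP = 200


@dataclass
class RegionDepth:
    contig: str
    start: int
    end: int
    mean_depth: float

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.start < self.end:
            raise ValueError("intervals are 0-based half-open with start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DepthProfile:
    sample: str
    sex: str
    regions: list[RegionDepth]
    baseline_regions: list[RegionDepth]


@dataclass
class RegionCall:
    contig: str
    start: int
    end: int
    copies_raw: float
    copies_called: int
    low_confidence: bool


@dataclass
class CopyNumberProfile:
    sample: str
    sex: str
    baseline: float
    calls: list[RegionCall]


@dataclass
class ExpressionRecord:
    sample: str
    feature: str
    fragment_count: float
    feature_length_kb: float
    control_fragments_per_kb: float
    normalized_value: float


def baseline_depth(profile: DepthProfile) -> float:
    """Median of control (non-sex-linked) region mean depths."""
    if not profile.baseline_regions:
        raise ValueError("no control regions")
    return float(np.median([r.mean_depth for r in profile.baseline_regions]))


def call_copies(region_depth: float, baseline: float) -> tuple[float, int]:
    """Copies per genome relative to a 2N baseline.

    copies_raw = 2 * depth / baseline; the integer call uses half-integer
    band boundaries (raw in [n - 0.5, n + 0.5) -> n).
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    raw = 2.0 * region_depth / baseline
    called = int(np.floor(raw + 0.5))
    return raw, called


def profile_copy_number(profile: DepthProfile) -> CopyNumberProfile:
    base = baseline_depth(profile)
    calls = []
    for r in profile.regions:
        raw, called = call_copies(r.mean_depth, base)
        calls.append(RegionCall(r.contig, r.start, r.end, raw, called,
                                low_confidence=r.length < LOW_CONFIDENCE_BP))
    return CopyNumberProfile(profile.sample, profile.sex, base, calls)


def mean_male_copy(profiles: Sequence[CopyNumberProfile]) -> dict[tuple, float]:
    """Arithmetic mean of copies_raw per region across male profiles."""
    males = [p for p in profiles if p.sex == "male"]
    if not males:
        raise ValueError("no male profiles")
    keys = [(c.contig, c.start, c.end) for c in males[0].calls]
    out = {}
    for key in keys:
        vals = []
        for p in males:
            for c in p.calls:
                if (c.contig, c.start, c.end) == key:
                    vals.append(c.copies_raw)
        out[key] = float(np.mean(vals))
    return out


def kmer_region_depth(region_seq: str, table: KmerCountTable) -> float:
    """Mean multiplicity in the table of the region's k-mers, position-wise.

    Positions whose k-mer is absent contribute zero, so deleted or
    hemizygous regions read out proportionally lower.
    """
    k = table.space.k
    codes = dna.sequence_kmer_codes(region_seq, k)
    if codes.size == 0:
        raise ValueError(f"region shorter than k={k}")
    idx = np.searchsorted(table.codes, codes)
    idx_c = np.minimum(idx, max(table.codes.size - 1, 0))
    found = table.codes.size > 0
    depths = np.zeros(codes.size, dtype=np.float64)
    if found:
        hit = table.codes[idx_c] == codes
        depths[hit] = table.counts[idx_c[hit]]
    return float(depths.mean())


def depth_profile_from_kmers(sample: str, sex: str, table: KmerCountTable,
                             regions: Sequence[tuple[str, int, int, str]],
                             region_seqs: Sequence[str],
                             baseline_seqs: Sequence[tuple[str, str]]
                             ) -> DepthProfile:
    """Alignment-free DepthProfile: k-mer depth for regions and controls."""
    region_depths = [
        RegionDepth(chrom, start, end, kmer_region_depth(seq, table))
        for (chrom, start, end, _name), seq in zip(regions, region_seqs)
    ]
    baseline = [
        RegionDepth(name, 0, len(seq), kmer_region_depth(seq, table))
        for name, seq in baseline_seqs
    ]
    return DepthProfile(sample=sample, sex=sex, regions=region_depths,
                        baseline_regions=baseline)


def normalize_expression(sample: str, feature: str, fragment_count: float,
                         feature_length_kb: float,
                         control_fragments_per_kb: float) -> ExpressionRecord:
    """Fragments per kb of feature, per control fragments/kb."""
    if feature_length_kb <= 0:
        raise ValueError("feature length must be > 0")
    if control_fragments_per_kb <= 0:
        raise ValueError("control fragment density must be > 0")
    value = (fragment_count / feature_length_kb) / control_fragments_per_kb
    return ExpressionRecord(sample, feature, fragment_count, feature_length_kb,
                            control_fragments_per_kb, value)
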