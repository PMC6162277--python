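"""K-mer counting, error-cutoff selection and sex-specific subtraction.

Tables store canonical k-mer codes as sorted uint64 arrays with uint32
multiplicities (saturating; saturation is recorded on the table). All set
algebra is done on the sorted code arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from . import dna
from .io import FastqRecord

logger = logging.getLogger(__name__)

_U32_MAX = np.iinfo(np.uint32).max


class InsufficientCoverageError(ValueError):
    """Raised when a multiplicity histogram shows no coverage peak."""


@dataclass(frozen=True)
class KmerSpace:
    """Fixed word length plus the canonical strand convention."""

    k: int = 16
    strand_convention: str = "canonical"

    def __post_init__(self):
        if not 1 <= self.k <= dna.MAX_K:
            raise ValueError(f"k must be in [1, {dna.MAX_K}]")
        if self.strand_convention != "canonical":
            raise ValueError("only the canonical strand convention is supported")


class KmerCountTable:
    """Multiset of canonical k-mers for one sample."""

    def __init__(self, space: KmerSpace, codes: np.ndarray, counts: np.ndarray,
                 sample: str = "", source: str = "reads", saturated: int = 0):
        if codes.size != counts.size:
            raise ValueError("codes/counts length mismatch")
        self.space = space
        self.codes = codes
        self.counts = counts
        self.sample = sample
        self.source = source
        self.saturated = saturated

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def get(self, word: str) -> int:
        code = dna.kmer_to_code(dna.canonical(word.upper()))
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def __getitem__(self, word: str) -> int:
        return self.get(word)

    def __contains__(self, word: str) -> bool:
        return self.get(word) > 0

    def to_dict(self) -> dict[str, int]:
        k = self.space.k
        return {
            dna.code_to_kmer(int(c), k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    def histogram(self) -> dict[int, int]:
        """Multiplicity -> number of distinct k-mers at that multiplicity."""
        mults, freqs = np.unique(self.counts, return_counts=True)
        return {int(m): int(f) for m, f in zip(mults, freqs)}

    def codes_with_count_at_least(self, minimum: int) -> np.ndarray:
        if minimum <= 1:
            return self.codes
        return self.codes[self.counts >= minimum]


def _iter_sequences(source) -> Iterator[str]:
    for item in source:
        if isinstance(item, FastqRecord):
            yield item.seq
        elif isinstance(item, str):
            yield item
        else:  # Biopython SeqRecord or anything seq-like
            yield str(getattr(item, "seq", item))


def count_kmers(sequences, space: KmerSpace = KmerSpace(), sample: str = "",
                source: str = "reads") -> KmerCountTable:
    """Count canonical k-mers over an iterable of sequences/reads.

    Every A/C/G/T window of length k contributes one count to its canonical
    form; windows containing any other symbol are skipped.
    """
    # join sequences with 'N' separators: N-containing windows are skipped,
    # so bulk encoding preserves counts exactly while amortising call overhead
    chunks: list[np.ndarray] = []
    buf: list[str] = []
    buf_n = 0
    n_seen = 0

    def flush():
        nonlocal buf, buf_n
        if buf:
            codes = dna.sequence_kmer_codes("N".join(buf), space.k)
            if codes.size:
                chunks.append(codes)
            buf = []
            buf_n = 0

    for seq in _iter_sequences(sequences):
        n_seen += 1
        buf.append(seq)
        buf_n += len(seq)
        if buf_n >= 8_000_000:
            flush()
    flush()
    if n_seen == 0:
        raise ValueError("no input sequences")
    if not chunks:
        raise ValueError(f"no sequence of length >= k={space.k} in input")
    allcodes = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    codes, counts = np.unique(allcodes, return_counts=True)
    saturated = int((counts > _U32_MAX).sum())
    if saturated:
        logger.warning("%d k-mer counts saturated at uint32 max", saturated)
    counts = np.minimum(counts, _U32_MAX).astype(np.uint32)
    return KmerCountTable(space, codes.astype(np.uint64), counts, sample, source,
                          saturated)


def merge_tables(tables: Sequence[KmerCountTable]) -> KmerCountTable:
    """Sum multiplicities across tables sharing one KmerSpace."""
    if not tables:
        raise ValueError("no tables to merge")
    space = tables[0].space
    if any(t.space.k != space.k for t in tables):
        raise ValueError("mismatched k across tables")
    codes = np.concatenate([t.codes for t in tables])
    counts = np.concatenate([t.counts.astype(np.int64) for t in tables])
    order = np.argsort(codes, kind="stable")
    codes, counts = codes[order], counts[order]
    uniq, start = np.unique(codes, return_index=True)
    summed = np.add.reduceat(counts, start)
    saturated = int((summed > _U32_MAX).sum())
    return KmerCountTable(space, uniq, np.minimum(summed, _U32_MAX).astype(np.uint32),
                          tables[0].sample, tables[0].source, saturated)


@dataclass(frozen=True)
class ErrorCutoff:
    """Multiplicity below which k-mers are treated as sequencing error."""

    sample: str
    cutoff: int
    histogram: Mapping[int, int]

    def __post_init__(self):
        if not 3 <= self.cutoff <= 15:
            raise ValueError("cutoff must lie in [3, 15]")


def select_error_cutoff(histogram: Mapping[int, int], sample: str = "",
                        lo: int = 3, hi: int = 15) -> ErrorCutoff:
    """First local minimum between the error mode and the coverage peak.

    Scans multiplicities upward and takes the first one after which the
    histogram rises again (the error/signal valley), clamped to [lo, hi].
    A histogram with no rise, or with no peak above multiplicity 2, signals
    insufficient coverage.
    """
    if not histogram:
        raise ValueError("empty histogram")
    max_m = max(histogram)
    h = np.zeros(max_m + 2, dtype=np.int64)
    for m, c in histogram.items():
        if m < 1 or c < 0:
            raise ValueError("histogram multiplicities must be >= 1, counts >= 0")
        h[m] = c
    valley = None
    for m in range(1, max_m):
        if h[m] < h[m + 1]:
            valley = m
            break
    if valley is None:
        raise InsufficientCoverageError(
            "monotone-decreasing multiplicity histogram: no coverage peak"
        )
    peak = valley + 1 + int(np.argmax(h[valley + 1 :]))
    if peak <= 2:
        raise InsufficientCoverageError(
            f"coverage peak at multiplicity {peak} <= 2: insufficient coverage"
        )
    cutoff = min(max(valley, lo), hi)
    return ErrorCutoff(sample=sample, cutoff=cutoff, histogram=dict(histogram))


def coverage_cutoff(histogram: Mapping[int, int], sample: str = "",
                    per_unit: float = 10.0, lo: int = 3, hi: int = 15
                    ) -> ErrorCutoff:
    """Coverage-scaled cutoff: k-mer coverage is read off the most prominent
    multiplicity peak above the error mode (multiplicity > 2), then divided
    by ``per_unit`` and clamped to [lo, hi].

    Preferable to the valley rule when hemizygous (half-depth) signal would
    otherwise overlap the error/signal valley.
    """
    if not histogram:
        raise ValueError("empty histogram")
    signal = {m: c for m, c in histogram.items() if m > 2}
    if not signal:
        raise InsufficientCoverageError(
            "no k-mers above multiplicity 2: insufficient coverage"
        )
    peak = max(signal, key=lambda m: signal[m])
    if peak <= 2:
        raise InsufficientCoverageError("coverage peak at multiplicity <= 2")
    cutoff = min(max(int(round(peak / per_unit)), lo), hi)
    return ErrorCutoff(sample=sample, cutoff=cutoff, histogram=dict(histogram))


@dataclass
class SexSpecificSet:
    """K-mers present in one sex and absent from the other, for one species."""

    species: str
    focal_sex: str
    codes: np.ndarray  # sorted canonical codes
    k: int
    cutoff: int
    opposite_presence_min: int

    @property
    def kmers(self) -> frozenset[str]:
        return frozenset(dna.code_to_kmer(int(c), self.k) for c in self.codes)

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, word: str) -> bool:
        code = np.uint64(dna.kmer_to_code(dna.canonical(word.upper())))
        i = np.searchsorted(self.codes, code)
        return bool(i < self.codes.size and self.codes[i] == code)


def sex_specific_set(focal: KmerCountTable, opposite: KmerCountTable,
                     cutoff: ErrorCutoff | int, opposite_presence_min: int = 1,
                     species: str = "", focal_sex: str = "male") -> SexSpecificSet:
    """K-mers with focal count >= cutoff and opposite count < presence min."""
    if focal.space.k != opposite.space.k:
        raise ValueError("mismatched k between focal and opposite tables")
    cut = cutoff.cutoff if isinstance(cutoff, ErrorCutoff) else int(cutoff)
    kept = focal.codes_with_count_at_least(cut)
    present = opposite.codes_with_count_at_least(opposite_presence_min)
    mask = ~np.isin(kept, present, assume_unique=True)
    return SexSpecificSet(
        species=species or focal.sample,
        focal_sex=focal_sex,
        codes=kept[mask].copy(),
        k=focal.space.k,
        cutoff=cut,
        opposite_presence_min=opposite_presence_min,
    )


@dataclass
class SurvivalCurve:
    """#k-mers sex-specific in at least n species, for n = 1..n_species."""

    direction: str
    counts: np.ndarray  # counts[i] = #k-mers in >= i+1 sets

    def __post_init__(self):
        if np.any(np.diff(self.counts) > 0):
            raise ValueError("survival counts must be non-increasing")

    def as_dict(self) -> dict[int, int]:
        return {n + 1: int(c) for n, c in enumerate(self.counts)}


def survival_curve(sets: Sequence[SexSpecificSet],
                   cumulative_order: bool = False) -> SurvivalCurve:
    """Survival of sex-specificity across species.

    Default semantics are order-free: counts[n] = #k-mers sex-specific in at
    least n of the per-species sets. With ``cumulative_order`` the sets are
    intersected in the given order instead (counts[n] = size of the running
    intersection of the first n sets).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 species")
    direction = sets[0].focal_sex
    if any(s.focal_sex != direction for s in sets):
        raise ValueError("mixed focal_sex across sets")
    if cumulative_order:
        counts = []
        running = sets[0].codes
        counts.append(running.size)
        for s in sets[1:]:
            running = np.intersect1d(running, s.codes, assume_unique=True)
            counts.append(running.size)
        arr = np.array(counts, dtype=np.int64)
    else:
        allcodes = np.concatenate([s.codes for s in sets])
        _, occ = np.unique(allcodes, return_counts=True)
        n = len(sets)
        arr = np.array([(occ >= i).sum() for i in range(1, n + 1)], dtype=np.int64)
    return SurvivalCurve(direction=f"{direction}-specific", counts=arr)


def genus_conserved_set(male_sets: Sequence[SexSpecificSet],
                        female_tables: Sequence[KmerCountTable],
                        opposite_presence_min: int | Sequence[int] = 1
                        ) -> np.ndarray:
    """Intersection of all per-species male-specific sets, minus any k-mer
    present in any female table (including species without a male sample).

    ``opposite_presence_min`` may be one threshold for all female tables or
    a per-table sequence (e.g. each table's own error cutoff, to ignore
    female sequencing-error k-mers). Returns sorted canonical codes.
    """
    if not male_sets or not female_tables:
        raise ValueError("need at least one male set and one female table")
    if isinstance(opposite_presence_min, int):
        minima = [opposite_presence_min] * len(female_tables)
    else:
        minima = list(opposite_presence_min)
        if len(minima) != len(female_tables):
            raise ValueError("one presence threshold per female table required")
    conserved = male_sets[0].codes
    for s in male_sets[1:]:
        conserved = np.intersect1d(conserved, s.codes, assume_unique=True)
    for table, minimum in zip(female_tables, minima):
        present = table.codes_with_count_at_least(minimum)
        conserved = conserved[~np.isin(conserved, present, assume_unique=True)]
    return conserved


def read_matches_kmers(seq: str, k: int, sorted_codes: np.ndarray) -> bool:
    codes = dna.sequence_kmer_codes(seq, k)
    if codes.size == 0:
        return False
    idx = np.searchsorted(sorted_codes, codes)
    idx = np.minimum(idx, sorted_codes.size - 1) if sorted_codes.size else idx
    return bool(sorted_codes.size and np.any(sorted_codes[idx] == codes))


def select_reads_with_kmers(reads: Iterable[FastqRecord], kmers, k: int | None = None
                            ) -> Iterator[FastqRecord]:
    """Yield reads containing at least one query k-mer on either strand."""
    sorted_codes, k = _as_code_array(kmers, k)
    for rec in reads:
        if read_matches_kmers(rec.seq, k, sorted_codes):
            yield rec


def select_read_pairs_with_kmers(pairs: Iterable[tuple[FastqRecord, FastqRecord]],
                                 kmers, k: int | None = None
                                 ) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Yield read pairs where either mate contains a query k-mer."""
    sorted_codes, k = _as_code_array(kmers, k)
    for r1, r2 in pairs:
        if (read_matches_kmers(r1.seq, k, sorted_codes)
                or read_matches_kmers(r2.seq, k, sorted_codes)):
            yield r1, r2


def _as_code_array(kmers, k: int | None) -> tuple[np.ndarray, int]:
    if isinstance(kmers, np.ndarray):
        if k is None:
            raise ValueError("k required with a code array")
        return np.sort(kmers), k
    words = [w.upper() for w in kmers]
    if not words:
        return np.empty(0, dtype=np.uint64), k or 0
    if k is None:
        k = len(words[0])
    if any(len(w) != k for w in words):
        raise ValueError("k-mers of mixed length")
    codes = np.array([dna.kmer_to_code(dna.canonical(w)) for w in words],
                     dtype=np.uint64)
    return np.unique(codes), k
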