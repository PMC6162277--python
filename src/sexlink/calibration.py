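"""Word-length calibration: SNP spacing, clustering, window scans and the
empirical miss-probability bound for the conserved-site screen."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class SnpTrack:
    """SNP positions (0-based) plus excluded positions on one scaffold."""

    scaffold: str
    length: int
    snp_positions: np.ndarray
    mask: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        self.snp_positions = np.unique(np.asarray(self.snp_positions, dtype=np.int64))
        self.mask = np.unique(np.asarray(self.mask, dtype=np.int64))
        if self.snp_positions.size and (
            self.snp_positions[0] < 0 or self.snp_positions[-1] >= self.length
        ):
            raise ValueError(f"{self.scaffold}: SNP position outside [0, length)")
        if self.mask.size and (self.mask[0] < 0 or self.mask[-1] >= self.length):
            raise ValueError(f"{self.scaffold}: mask position outside [0, length)")


@dataclass
class WindowScanResult:
    window: int
    step: int
    k: int
    min_sites: int
    both_strands: bool
    n_windows: int
    n_failing: int
    site_counts: np.ndarray  # per tiled window, in scan order

    def __post_init__(self):
        if self.n_failing > self.n_windows:
            raise ValueError("n_failing exceeds n_windows")


@dataclass
class MissProbability:
    value: float
    is_bound: bool  # True when n_failing = 0 and value = 1/n_windows


@dataclass
class CalibrationReport:
    total_nonrep_bp: int
    n_snps: int
    bp_per_snp: float
    frac_within_d: float | None
    windows: WindowScanResult
    miss: MissProbability


def snp_spacing(total_nonrep_bp: int, n_snps: int) -> float:
    """Mean spacing in bp per SNP over non-repetitive sequence."""
    if n_snps <= 0:
        raise ValueError("n_snps must be > 0")
    return total_nonrep_bp / n_snps


def fraction_snps_within(snp_positions: Sequence[int] | np.ndarray, d: int) -> float:
    """Fraction of SNPs whose nearest neighbouring SNP lies <= d bp away."""
    pos = np.unique(np.asarray(snp_positions, dtype=np.int64))
    if pos.size < 2:
        raise ValueError("need at least 2 SNP positions")
    gaps = np.diff(pos)
    near = np.zeros(pos.size, dtype=bool)
    near[:-1] |= gaps <= d
    near[1:] |= gaps <= d
    return float(near.mean())


def window_scan(tracks: SnpTrack | Sequence[SnpTrack], window: int = 500,
                step: int = 250, k: int = 16, min_sites: int = 20,
                both_strands: bool = False) -> WindowScanResult:
    """Count fully conserved k-mer start sites in tiled windows.

    A site is a start position p such that [p, p+k) contains no SNP and no
    masked base and lies inside the window. Windows are tiled per scaffold
    from 0 with the given step; the final partial window is dropped, so no
    window spans a scaffold boundary. ``both_strands`` doubles site counts.
    A window fails when its (possibly doubled) count is below ``min_sites``.
    """
    if window < k:
        raise ValueError("window must be >= k")
    if step <= 0:
        raise ValueError("step must be > 0")
    if isinstance(tracks, SnpTrack):
        tracks = [tracks]
    per_window: list[int] = []
    for track in tracks:
        bad = np.zeros(track.length, dtype=np.int64)
        bad[track.snp_positions] = 1
        bad[track.mask] = 1
        cs = np.concatenate([[0], np.cumsum(bad)])
        n_k = track.length - k + 1
        if n_k <= 0:
            continue
        clean = (cs[k:] - cs[:-k]) == 0  # per k-window start
        clean_cs = np.concatenate([[0], np.cumsum(clean)])
        start = 0
        sites_per_win = window - k + 1
        while start + window <= track.length:
            n_sites = int(clean_cs[start + sites_per_win] - clean_cs[start])
            per_window.append(2 * n_sites if both_strands else n_sites)
            start += step
    counts = np.array(per_window, dtype=np.int64)
    return WindowScanResult(
        window=window, step=step, k=k, min_sites=min_sites,
        both_strands=both_strands, n_windows=counts.size,
        n_failing=int((counts < min_sites).sum()), site_counts=counts,
    )


def miss_probability(scan: WindowScanResult | None = None, *,
                     n_windows: int | None = None,
                     n_failing: int | None = None) -> MissProbability:
    """Empirical probability that the k-mer screen misses a window-sized
    sex-unique fragment: 1/n_windows as an upper bound when no window fails,
    otherwise the observed failing fraction."""
    if scan is not None:
        n_windows, n_failing = scan.n_windows, scan.n_failing
    if n_windows is None or n_failing is None:
        raise ValueError("provide a scan result or n_windows and n_failing")
    if n_windows <= 0:
        raise ValueError("n_windows must be > 0")
    if n_failing == 0:
        return MissProbability(value=1.0 / n_windows, is_bound=True)
    return MissProbability(value=n_failing / n_windows, is_bound=False)


def calibrate(tracks: SnpTrack | Sequence[SnpTrack], window: int = 500,
              step: int = 250, k: int = 16, min_sites: int = 20,
              both_strands: bool = False, neighbour_d: int = 16
              ) -> CalibrationReport:
    """Full calibration report for a set of SNP tracks."""
    if isinstance(tracks, SnpTrack):
        tracks = [tracks]
    total_bp = sum(t.length - t.mask.size for t in tracks)
    n_snps = sum(int(t.snp_positions.size) for t in tracks)
    frac = None
    all_pos = [t.snp_positions for t in tracks if t.snp_positions.size >= 2]
    if all_pos:
        fracs = [fraction_snps_within(p, neighbour_d) for p in all_pos]
        weights = [p.size for p in all_pos]
        frac = float(np.average(fracs, weights=weights))
    scan = window_scan(tracks, window=window, step=step, k=k,
                       min_sites=min_sites, both_strands=both_strands)
    return CalibrationReport(
        total_nonrep_bp=total_bp, n_snps=n_snps,
        bp_per_snp=snp_spacing(total_bp, n_snps) if n_snps else float("nan"),
        frac_within_d=frac, windows=scan, miss=miss_probability(scan),
    )
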