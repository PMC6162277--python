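"""End-to-end orchestration: simulate a genus, identify conserved
male-specific k-mers, localize them, call copy number, and summarise.

All randomness derives from one root seed, split per stage and per sample,
so stage-level reruns are stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import copynumber, io, kmers, localization, molevol
from .synthetic import (GenusModel, ReadSimSpec, SampleGenome, TruthTable,
                        simulate_genus, simulate_reads)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_species: int = 6
    autosome_length: int = 200_000
    xy_shared_length: int = 10_000
    y_block_length: int = 5_000
    repeat_fraction: float = 0.0
    snp_rate_target: float = 1.0 / 16.5
    with_hermaphrodite: bool = True
    k: int = 16
    cutoff: str | int = "coverage"  # 'coverage' | 'auto' (valley) | integer
    # 'cutoff' = test opposite-sex presence against error-filtered tables
    # (threshold = that sample's error cutoff); an integer is used as-is
    opposite_presence_min: int | str = "cutoff"
    read_length: int = 250
    coverage: float = 30.0
    error_rate: float = 0.005
    paired: bool = False
    insert_size: int = 400
    window: int = 500
    step: int = 250
    min_sites: int = 20
    min_kmers: int = 100
    ratio_min: float = 6.0
    molevol_omega: float = 0.2
    molevol_codons: int = 500
    molevol_species: int = 10
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    conserved_size: int
    truth_size: int
    truth_recovered_fraction: float
    false_kmers_in_females: int
    survival_male: dict[int, int]
    survival_female: dict[int, int]
    cutoffs: dict[str, int]
    localized_hits: int
    localized_in_truth_fraction: float
    coverage_percent: dict[int, float]
    copy_calls: dict[str, dict[str, float | int]]
    mean_male_copy: float | None
    molevol_mean_omega: float | None
    manifest: dict = field(default_factory=dict)


def _sample_seed(root: np.random.SeedSequence, *key: int) -> int:
    return int(np.random.SeedSequence((root.entropy, *key)).generate_state(1)[0])


def block_regions(sample: SampleGenome) -> list[tuple[str, str, int, int]]:
    """(label, chrom/hap, start, end) for every planted block of a sample."""
    return [(label, chrom, s, e) for label, chrom, s, e in sample.blocks]


def _region_sequence(sample: SampleGenome, chrom_hap: str, start: int,
                     end: int) -> str:
    chrom, hap = chrom_hap.rsplit("/", 1)
    return sample.haplotypes[chrom][int(hap)][start:end]


def _control_windows(sample: SampleGenome, n: int = 5, width: int = 2_000
                     ) -> list[tuple[str, str]]:
    """Control windows from the back half of the autosome (repeat-free)."""
    auto = sample.haplotypes["autosome"][0]
    half = len(auto) // 2
    span = len(auto) - half - width
    if span <= 0:
        return [("control0", auto)]
    starts = np.linspace(half, half + span, num=n, dtype=np.int64)
    return [(f"control{i}", auto[s : s + width]) for i, s in enumerate(starts)]


def run_pipeline(config: PipelineConfig) -> RunReport:
    t0 = time.time()
    root = np.random.SeedSequence(config.seed)
    model = GenusModel.default(
        n_species=config.n_species,
        autosome_length=config.autosome_length,
        xy_shared_length=config.xy_shared_length,
        y_block_length=config.y_block_length,
        repeat_fraction=config.repeat_fraction,
        snp_rate_target=config.snp_rate_target,
        with_hermaphrodite=config.with_hermaphrodite,
        seed=_sample_seed(root, 0),
    )
    logger.info("simulating genus (%d species)", config.n_species)
    samples, truth = simulate_genus(model, k=config.k)

    space = kmers.KmerSpace(k=config.k)
    tables: dict[str, kmers.KmerCountTable] = {}
    reads_by_sample: dict[str, list] = {}
    for i, sample in enumerate(samples):
        spec = ReadSimSpec(
            read_length=config.read_length, coverage=config.coverage,
            error_rate=config.error_rate, paired=config.paired,
            insert_size=config.insert_size, seed=_sample_seed(root, 1, i),
        )
        reads = simulate_reads(sample, spec)
        reads_by_sample[sample.name] = reads
        tables[sample.name] = kmers.count_kmers(reads, space, sample=sample.name)
        logger.info("counted %s: %d distinct k-mers", sample.name,
                    tables[sample.name].n_distinct)

    cutoffs: dict[str, int] = {}
    for name, table in tables.items():
        if config.cutoff == "auto":
            cutoffs[name] = kmers.select_error_cutoff(
                table.histogram(), sample=name).cutoff
        elif config.cutoff == "coverage":
            cutoffs[name] = kmers.coverage_cutoff(
                table.histogram(), sample=name).cutoff
        else:
            cutoffs[name] = int(config.cutoff)

    species = sorted({s.species for s in samples if s.sex in ("male", "female")})

    def opp_min(name: str) -> int:
        if config.opposite_presence_min == "cutoff":
            return cutoffs[name]
        return int(config.opposite_presence_min)

    male_sets, female_sets = [], []
    female_tables = []
    for sp in species:
        m, f = f"{sp}_male", f"{sp}_female"
        male_sets.append(kmers.sex_specific_set(
            tables[m], tables[f], cutoffs[m], opp_min(f),
            species=sp, focal_sex="male"))
        female_sets.append(kmers.sex_specific_set(
            tables[f], tables[m], cutoffs[f], opp_min(m),
            species=sp, focal_sex="female"))
        female_tables.append(tables[f])

    surv_m = kmers.survival_curve(male_sets)
    surv_f = kmers.survival_curve(female_sets)
    conserved = kmers.genus_conserved_set(
        male_sets, female_tables,
        [opp_min(f"{sp}_female") for sp in species])

    recovered = np.isin(truth.genus_codes, conserved, assume_unique=True)
    truth_frac = float(recovered.mean()) if truth.genus_codes.size else 1.0
    # exhaustive soundness check: conserved k-mers present in a female genome
    false_in_female = 0
    from .synthetic import genome_kmer_codes

    for sample in samples:
        if sample.sex == "female":
            fg = genome_kmer_codes(sample, config.k)
            false_in_female += int(np.isin(conserved, fg, assume_unique=True).sum())

    # localization against the first male's Y haplotype plus an autosome decoy
    first_male = next(s for s in samples if s.sex == "male")
    contigs = {
        f"{first_male.name}|sex/1": first_male.haplotypes["sex"][1],
        f"{first_male.name}|autosome/0": first_male.haplotypes["autosome"][0],
    }
    support = _conserved_support(conserved, male_sets)
    profiles = localization.match_kmers(conserved, contigs, k=config.k)
    n_hits = sum(p.n_hits for p in profiles.values())
    in_truth = _hits_in_truth(profiles, first_male, config.k)
    cov_pct = localization.coverage_percent(
        {n: codes for n, codes in support.items()}, contigs, k=config.k)

    # copy number per sample over its own planted blocks
    copy_calls: dict[str, dict[str, float | int]] = {}
    cn_profiles = []
    for sample in samples:
        regions = block_regions(sample)
        if not regions:
            continue
        region_seqs = [_region_sequence(sample, chrom, s, e)
                       for _, chrom, s, e in regions]
        dp = copynumber.depth_profile_from_kmers(
            sample.name, sample.sex, tables[sample.name],
            [(chrom, s, e, label) for label, chrom, s, e in regions],
            region_seqs, _control_windows(sample))
        prof = copynumber.profile_copy_number(dp)
        cn_profiles.append(prof)
        for call in prof.calls:
            copy_calls[f"{sample.name}:{call.contig}:{call.start}-{call.end}"] = {
                "raw": round(call.copies_raw, 4), "called": call.copies_called,
            }
    mean_copy = None
    male_profiles = [p for p in cn_profiles if p.sex == "male"]
    if male_profiles:
        mm = copynumber.mean_male_copy(male_profiles)
        mean_copy = float(np.mean(list(mm.values())))

    mol_mean_omega = None
    if config.molevol_codons > 0:
        aln = molevol.simulate_coding_alignment(
            config.molevol_codons, config.molevol_species, config.molevol_omega,
            seed=_sample_seed(root, 2))
        summ = molevol.gene_summary(aln, "ancestor")
        mol_mean_omega = summ.mean_omega

    report = RunReport(
        conserved_size=int(conserved.size),
        truth_size=int(truth.genus_codes.size),
        truth_recovered_fraction=truth_frac,
        false_kmers_in_females=false_in_female,
        survival_male=surv_m.as_dict(),
        survival_female=surv_f.as_dict(),
        cutoffs=cutoffs,
        localized_hits=int(n_hits),
        localized_in_truth_fraction=in_truth,
        coverage_percent=cov_pct,
        copy_calls=copy_calls,
        mean_male_copy=mean_copy,
        molevol_mean_omega=mol_mean_omega,
    )
    report.manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "n_samples": len(samples),
        "elapsed_s": round(time.time() - t0, 2),
    }
    if config.outdir:
        _write_outputs(Path(config.outdir), config, samples, truth, conserved,
                       report, reads_by_sample)
    return report


def _conserved_support(conserved: np.ndarray,
                       male_sets: Sequence[kmers.SexSpecificSet]
                       ) -> dict[int, np.ndarray]:
    """Conserved codes bucketed by >=n-species male-specific support."""
    if conserved.size == 0:
        return {len(male_sets): conserved}
    occ = np.zeros(conserved.size, dtype=np.int64)
    for s in male_sets:
        occ += np.isin(conserved, s.codes, assume_unique=True)
    return {n: conserved[occ >= n] for n in range(1, len(male_sets) + 1)}


def _hits_in_truth(profiles: dict[str, localization.KmerMatchProfile],
                   male: SampleGenome, k: int) -> float:
    total = inside = 0
    blocks_by_contig: dict[str, list[tuple[int, int]]] = {}
    for label, chrom, s, e in male.blocks:
        blocks_by_contig.setdefault(f"{male.name}|{chrom}", []).append((s, e))
    for name, prof in profiles.items():
        total += prof.n_hits
        for s, e in blocks_by_contig.get(name, []):
            inside += int(((prof.positions + k > s) & (prof.positions < e)).sum())
    return inside / total if total else 1.0


def _write_outputs(outdir: Path, config: PipelineConfig,
                   samples: Sequence[SampleGenome], truth: TruthTable,
                   conserved: np.ndarray, report: RunReport,
                   reads_by_sample: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        io.write_fasta(outdir / f"{sample.name}.fasta", sample.all_sequences())
        io.write_fastq(outdir / f"{sample.name}.fastq", reads_by_sample[sample.name])
    io.write_bed(outdir / "truth_blocks.bed", truth.block_bed())
    io.write_kmer_set(outdir / "conserved_kmers.txt", conserved, config.k)
    io.write_kmer_set(outdir / "truth_kmers.txt", truth.genus_codes, config.k)
    io.write_tsv(outdir / "survival.tsv", ["n_species", "male", "female"],
                 [(n, report.survival_male[n], report.survival_female[n])
                  for n in sorted(report.survival_male)])
    io.write_tsv(outdir / "copy_number.tsv",
                 ["region", "copies_raw", "copies_called"],
                 [(key, v["raw"], v["called"])
                  for key, v in sorted(report.copy_calls.items())])
    manifest = dict(report.manifest)
    manifest["checksums"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    io.write_json(outdir / "manifest.json", manifest)


def report_to_json(report: RunReport) -> str:
    return json.dumps(asdict(report), indent=2, sort_keys=True, default=str)
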