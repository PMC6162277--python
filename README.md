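# sexlink

Discovery of sex-linked genome regions by calibrated sex-specific k-mer
subtraction across the species of a dioecious genus, with downstream
localization, copy-number inference and synonymous/nonsynonymous rate
summaries. The package ships its own synthetic-genus simulator so the whole
pipeline is testable end to end without any external data.

## What it does

- **`sexlink.synthetic`** — simulates a dioecious genus on a species tree:
  diploid genomes with a shared X/Y region, hemizygous Y-specific blocks
  (1N in males, absent in females, 2N in a hermaphrodite outgroup control),
  optional X deletions and repeats, error-bearing short reads at a chosen
  coverage, and an exhaustively enumerated ground-truth k-mer set.
- **`sexlink.kmers`** — canonical k-mer counting (2-bit packed, numpy),
  per-genome error-cutoff selection (histogram-valley and coverage-scaled
  policies), per-species sex-specific subtraction, cross-species survival
  curves, the genus-conserved male-specific set, and read selection by
  k-mer content.
- **`sexlink.calibration`** — SNP spacing (bp/SNP), SNP clustering
  fraction, the 500 bp / 250 bp sliding-window scan for fully conserved
  k-mer sites, and the empirical miss-probability bound.
- **`sexlink.localization`** — exact k-mer matching onto contigs (both
  strands), coverage percentages by species support, per-window density
  tracks, phased-haplotype scaffold selection, and consensus substitution.
- **`sexlink.copynumber`** — copies-per-genome from read depth normalized
  to a diploid (2N) baseline, alignment-free k-mer depth mode, and
  control-scaffold expression normalization.
- **`sexlink.molevol`** — Nei–Gojobori-style dS/dN with Jukes–Cantor
  correction (fractional site counts, pathway-averaged differences,
  stop-exclusion), per-gene cross-species summaries, and relative
  clade-depth fractions on ultrametric trees.
- **`sexlink.pipeline`** — seeded end-to-end orchestration with a JSON
  manifest and TSV/FASTA/FASTQ/BED artifacts.

## CLI

Every stage is a subcommand of the `sexlink` entry point:

```sh
sexlink simulate --species 6 --y-block 5000 --coverage 30 --seed 1 --out sim/
sexlink count sim/sp1_male.fastq --k 16 --out sp1_male.counts.tsv
sexlink subtract --focal sp1_male.counts.tsv --opposite sp1_female.counts.tsv \
    --cutoff auto --opp-min 1 --out sp1_male_specific.txt
sexlink survive sp*_male_specific.txt --out survival.tsv
sexlink conserved --male-set sp1_male_specific.txt --male-set sp2_male_specific.txt \
    --female-table sp1_female.counts.tsv --female-table sp2_female.counts.tsv \
    --out conserved.txt
sexlink selreads --reads sim/sp1_male.fastq --kmers conserved.txt --out kept.fastq
sexlink calibrate --snps snps.tsv --lengths lengths.tsv \
    --window 500 --step 250 --k 16 --min-sites 20 --out calibration.tsv
sexlink localize --kmers conserved.txt --contigs contigs.fasta --out hits.tsv
sexlink selhap --counts hap_counts.tsv --min-kmers 100 --ratio 6 --out selected.tsv
sexlink copynum --depths depths.tsv --out copynumber.tsv
sexlink ng86 --alignment cds.fasta --out rates.tsv
sexlink genesummary --alignment cds.fasta --outgroup outsp --out summary.tsv
sexlink cladedepth --tree tree.nwk --leaves spA,spB
sexlink run-all --seed 1 --out run/
```

`run-all` simulates a genus (defaults: 6 species, 200 kb autosome, 10 kb
X/Y region with one 5 kb Y-specific block, divergence tuned to 1 SNP per
16.5 bp, 30x single-end reads at 0.5% error), runs counting, subtraction,
survival, conserved-set construction, localization and copy-number calling,
and prints a JSON report; all randomness derives from the one seed.

## Notable conventions

- K-mers are stored canonically (lexicographic minimum of word and reverse
  complement); windows containing non-ACGT symbols are skipped.
- Coordinates are 0-based, half-open everywhere.
- Copy-number calls use half-integer band boundaries around
  `2 * depth / baseline`.
- Codon-level rates drop whole codon columns containing gaps or ambiguity,
  exclude substitutions to stop codons from site denominators, and flag
  (rather than clip) Jukes–Cantor saturation.
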