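# rohkit

Runs-of-homozygosity (ROH) analysis for diploid SNP genotype data:
detection, genomic inbreeding coefficients, ROH islands (selection-signature
candidate regions), linkage-disequilibrium decay and LD-based effective
population size — the analysis chain used in livestock resequencing studies
(sheep, cattle, goats), built as a tested, reusable Python library with a
seeded simulator that provides ground truth for every stage.

## Who this is for

Population geneticists working from a multi-sample VCF of biallelic SNPs
plus a sample-to-breed table, who want ROH-based inbreeding and hotspot
analyses without stitching together PLINK, spreadsheets and ad-hoc scripts —
and who want every step verifiable against known truth.

## The quantities computed

**ROH detection.** A window of `w = 50` SNPs slides along each chromosome;
a window is homozygous-compatible if it has ≤ 2 heterozygous and ≤ 5 missing
calls. Each SNP receives the fraction of covering windows that are
compatible; SNPs at fraction ≥ 0.05 seed candidate runs, which are split at
inter-SNP gaps > 1000 kb, trimmed to their outermost confidently homozygous
SNP, and kept if they span ≥ 100 SNPs, ≥ 500 kb, and ≤ 50 kb/SNP. Segments
are classed as 0.5–1.0, 1.0–1.5, 1.5–2.0 or > 2.0 Mb; under a 1 cM/Mb map a
segment coalescing *g* generations back has expected length 1/(2*g*)
Morgans, so these classes correspond to ≈ 100–50, 50–33.3, 33.3–25 and < 25
generations of inbreeding.

**Inbreeding.** Per individual,

    F_ROH = L_ROH / L_au

with `L_ROH` the summed ROH length and `L_au` the autosomal length covered
by SNPs; and the excess-homozygosity coefficient

    F_HOM = (O_hom − E_hom) / (N_sites − E_hom),  E_hom = Σ_site [1 − 2pq·n/(n−1)]

with cohort allele frequencies *p*, *q* and *n* non-missing alleles at the
site. Their Pearson correlation is reported per breed.

**ROH islands.** Per group, each SNP's *occurrence* is the fraction of
individuals whose ROH cover it; SNPs in the top 0.5 % (empirical quantile,
ties included) are merged — strictly adjacent SNPs only — into islands,
which are annotated with overlapping genes from a GTF/GFF file.

**LD and Ne.** r² is the squared Pearson correlation of genotype dosages;
binned against distance it gives the decay curve, and the Sved relation
`E[r²] = 1/(α + 4Nc)` (with the 1/(2n) sample-size adjustment) is inverted
per bin to estimate Ne at `t = 1/(2c)` generations ago.

**Simulator.** Plants autozygous tracts (exponential lengths, mean 1/(2g)
Morgans) into a Hardy–Weinberg background at per-individual target F*, with
optional group-shared island loci and configurable het/missing noise, and
emits the exact truth for recall/precision testing.

## Worked example

```python
from rohkit import (SimConfig, simulate_population, call_roh, inbreeding_table,
                    summarize_individual, find_islands, generations_from_length)
from rohkit.synthetic_data import IslandSpec

cfg = SimConfig(
    seed=11, n_individuals=20,
    chrom_lengths_bp=(50_000_000,) * 4,       # four 50-Mb autosomes
    snp_density_per_mb=200,
    target_f=0.08, generations=40, min_tract_bp=750_000,
    islands=(IslandSpec("chr2", 10_000_000, 12_000_000, "pop1", 0.8),),
)
gm, truth = simulate_population(cfg)
segments = call_roh(gm)
records = inbreeding_table(gm, segments, L_au_mb=cfg.genome_bp / 1e6)
track, thr, islands = find_islands(segments, gm, cfg.metadata(), "pop1")
```

prints, via the obvious summaries:

```
40000 SNPs x 20 individuals
164 ROH segments detected
ind001: 10 ROH totalling 16.8 Mb
ind001: F_ROH = 0.0840 (true 0.0821), F_HOM = 0.0807
occurrence threshold 0.80; islands: [('chr2', 10020826, 12009404)]
a 1.25-Mb ROH points to inbreeding ~40 generations back
```

Reading: the detector recovers the planted inbreeding level to the third
decimal (F_ROH 0.084 vs true 0.082), F_HOM agrees closely, and the single
island called for the group is the 2-Mb locus planted in 80 % of
individuals at chr2:10–12 Mb. The same stages are available from the shell:

```bash
rohkit simulate --seed 11 --out-dir sim/
rohkit filter --vcf sim/sim.vcf --out filtered.vcf
rohkit detect --vcf filtered.vcf --out roh.tsv
rohkit inbreeding --roh roh.tsv --vcf filtered.vcf --out inb.tsv
rohkit islands --roh roh.tsv --vcf filtered.vcf --groups sim/groups.tsv \
    --group pop1 --out islands.tsv
rohkit run-all --config run.toml        # whole pipeline + manifest
```

## Layout

- `rohkit.genotype_io` — VCF I/O, genotype codes, missing-rate/MAF filters
- `rohkit.roh_detect` — sliding-window detector plus brute-force oracle
- `rohkit.roh_stats` — individual/breed/chromosome summaries, length classes
- `rohkit.inbreeding` — F_ROH, F_HOM, correlations
- `rohkit.islands` — occurrence track, top-quantile threshold, merging, gene annotation
- `rohkit.popgen_ld_ne` — dosage r², LD decay, Sved Ne estimation
- `rohkit.synthetic_data` — ground-truth simulator and end-to-end harness
- `rohkit.cli`, `rohkit.cli_pipeline` — command-line interface and orchestration

See `docs/methods.md` for the modelling choices, defaults and limitations.
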