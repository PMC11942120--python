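# Methods

This note records the models, conventions and design choices behind rohkit,
in the spirit of a methods appendix: what each stage assumes, which knobs
matter, and what the synthetic validation does and does not demonstrate.

## Genotype representation and site filters

Genotypes are unphased diploid calls coded `HOM_REF = 0, HET = 1,
HOM_ALT = 2, MISSING = −1` in an int8 sites × samples matrix. Only
biallelic SNPs are loaded; indels and multiallelic records are dropped at
read time, and half-calls (`./1`) are conservatively treated as missing.
Coordinates are 1-based inclusive internally (VCF convention); BED exports
are 0-based half-open. Chromosome order comes from the VCF header contig
lines; non-autosomal contigs can be excluded with an allow-list, since the
inbreeding denominator is autosomal.

Site filters remove SNPs with missing rate ≥ 0.1 (strict: a site at exactly
0.1 is removed) or minor allele frequency < 0.05 (a site at exactly 0.05 is
retained). MAF uses non-missing calls only, denominator 2 × (non-missing
genotypes). These thresholds are the conventional post-variant-calling
hygiene for resequencing panels; the filter is global across samples (a
per-group mode would be a straightforward extension but changes the site
set per analysis, so it is not the default). The filter is idempotent.

## ROH detection

The detector reproduces the PLINK `--homozyg` sliding-window family:

| parameter | default | meaning |
| --- | --- | --- |
| `window_snps` | 50 | SNPs per scanning window |
| `max_het_per_window` | 2 | heterozygous calls tolerated per window |
| `max_missing_per_window` | 5 | missing calls tolerated per window |
| `hit_proportion` | 0.05 | min fraction of compatible covering windows for a SNP to seed a run |
| `min_snps` | 100 | min SNPs per reported segment |
| `min_length_kb` | 500 | min segment length |
| `max_density_kb_per_snp` | 50 | max average spacing inside a segment |
| `max_gap_kb` | 1000 | split a run when consecutive SNPs are farther apart |

`hit_proportion` is not part of the six headline rules of this detector
family but is required to turn window verdicts into per-SNP calls; 0.05 is
the PLINK default and is exposed as a parameter.

Edge conventions, stated because tools differ: SNPs near chromosome ends
are scored over the full windows that exist; a chromosome with fewer SNPs
than one window is scored with a single truncated window. A gap of exactly
`max_gap_kb` does **not** split (strict `>`). Segment length is
`end − start + 1` bp between the first and last SNP of the run. Runs are
trimmed at both ends to the outermost non-heterozygous, non-missing SNP, so
segments never start or end on a HET or MISSING call. There is no
segment-level heterozygote cap beyond the window rule.

Correctness is established against `brute_force_roh`, an independent
re-derivation of the same contract by direct enumeration of every window
and run (no rolling sums); the suite asserts exact segment-set equality on
hundreds of randomized instances with planted runs, noise, and randomized
parameters.

## Length classes and generations

Classes 0.5–1.0, 1.0–1.5, 1.5–2.0, > 2.0 Mb use half-open `[a, b)`
boundaries, so a 1.0-Mb segment is in the second class (the conventional
printed bounds overlap at the edges; half-open removes the ambiguity).
The time mapping assumes tract length ~ Exponential(mean 1/(2g) Morgans)
for an ancestor g generations back, and a uniform 1 cM/Mb map unless a
different scale is supplied, giving `g = 1/(2 L_Morgan)`: 0.5 Mb ↔ 100
generations, 2.0 Mb ↔ 25 generations. The longest class (> 2.0 Mb) thus
corresponds to the most recent inbreeding (< 25 generations).

Breed summaries: MN_ROH is the mean segment count per individual, AL_ROH
the mean length per segment; the per-class "mean sum" sums all segments of
the class over the group and divides by the group size.

## Inbreeding coefficients

`F_ROH = L_ROH / L_au`. By default `L_au` is the summed first-to-last-SNP
span per autosome of the input matrix — the "autosomal length covered by
SNPs" — and can be overridden with a published constant for comparability
across studies. `F_HOM` is the method-of-moments excess-homozygosity
estimator with the small-sample correction `n/(n−1)` on `2pq` (the
`--het`-style convention); sites missing in a sample are excluded from both
its observed and expected counts, and the coefficient is undefined
(reported NaN) when `N_sites = E_hom`. F_HOM ≥ F_ROH is an empirical
tendency in real panels, not an identity, and is deliberately not asserted
anywhere. F_HOM is computed on the same filtered site set used for ROH.

## ROH islands

Occurrence is per-SNP and per-group: the fraction of individuals with at
least one ROH covering the position (an individual counts once however many
segments cover it). The threshold is the empirical `1 − 0.005` quantile of
the occurrence track, with ties included (occurrence is discrete in
multiples of 1/n, so a strict cut could retain nothing); since a SNP inside
no ROH cannot be part of a homozygosity hotspot, the threshold is floored
at the smallest positive occurrence when the quantile lands on zero, and
constant tracks (including all-zero) yield no islands at all. Islands are
maximal runs of strictly adjacent retained SNPs (an intervening
below-threshold SNP breaks the island; an optional bp bridge exists but is
off by default), and singleton islands are suppressed by default
(`min_island_snps = 2`) to avoid isolated-SNP artifacts. Gene annotation
assigns a gene to an island iff their intervals overlap by ≥ 1 bp, strand
ignored; islands with zero genes are legitimate output.

## LD and effective population size

r² is the squared Pearson correlation of 0/1/2 dosages over individuals
non-missing at both sites (composite LD — appropriate because the package
never phases). Defaults: pairs within 1 Mb, 50-kb bins; both configurable.
Ne uses the Sved relation with `alpha = 1`, the `1/(2n)` sample-size
adjustment floored at 1e−12, a uniform 1 cM/Mb map for `c`, and reports
each bin at `t = 1/(2c)` generations; estimates driven negative by sampling
noise are floored at 0 with a warning. This is a self-contained
re-implementation of the standard LD–Ne estimator, not a replica of any
particular tool's mutation or recombination corrections; absolute Ne values
therefore depend on these stated constants, while the suite verifies exact
inversion of the forward map and the relative ordering of populations with
different planted LD strength.

## Synthetic data

The simulator is a direct-planting (copying) model chosen over
forward-in-time pedigree simulation because it yields exact, unambiguous
truth at interactive speed. Defaults describe the desk-scale stand-in for a
livestock resequencing panel: 20 individuals; five 100-Mb autosomes
(~500 Mb); 100 SNPs/Mb (~50k sites); background minor-allele frequencies
uniform on [0.05, 0.5] with Hardy–Weinberg genotypes; tract lengths
exponential with mean 1/(2g) Morgans at g = 50 (mean 1 Mb), truncated below
100 kb; heterozygote and missing noise 0.002 inside tracts and 0.002
missingness outside. Tracts accumulate toward each individual's target F*
(dropping the final tract when that leaves the total closer to the target)
and are placed uniformly without per-individual overlap by rejection;
island loci are planted first with identical coordinates in the chosen
carrier subset. All randomness flows through one seeded generator, and the
seed is recorded in the emitted VCF header, so output is bit-reproducible.

Validation configs that measure detector *recovery* (rather than detector
limits) raise SNP density to 200/Mb and the minimum tract length to
~750 kb so that every planted tract exceeds the detection thresholds
(≥ 100 SNPs, ≥ 500 kb); recovery numbers under those configs measure the
pipeline's bookkeeping, boundary trimming and threshold logic, not its
power on marginal tracts. The harness sizes (500-Mb genomes, 20–40
individuals, 25–50 replicates) were chosen as the smallest designs whose
sampling noise is well below the asserted tolerances.

What the background does **not** model: linkage disequilibrium (sites are
independent by default — the optional block-haplotype mode adds orderable
but unrealistic LD), allele-frequency spectra from real demography,
genotyping error correlated with depth, sex chromosomes, and selection.
Passing tests therefore certify the algorithms' contracts and statistical
behaviour under known truth, not concordance with any particular empirical
panel.

## Numerical and degenerate-input conventions

- Boundary comparisons (missing rate ≥ cutoff removes, MAF ≥ cutoff
  retains) are exact on IEEE doubles since both sides are small-integer
  ratios.
- Empty matrices and empty segment lists flow through as empty results;
  zero-variance correlation inputs and degenerate F_HOM denominators
  return NaN rather than raising.
- The generations↔length mapping is strictly monotone and round-trips to
  1e−12.
- Pipeline stages are individually re-runnable and skip when their outputs
  exist; the run manifest records parameters and input checksums
  sufficient to reproduce every output byte-identically.

## Known limitations

No HMM/likelihood-based ROH calling, no phased/IBD-segment methods, no
pedigree inbreeding, no X-chromosome handling, no GO/pathway enrichment of
island genes, and no replication of any specific published panel's absolute
numbers — the package's claims are the tested contracts above.
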