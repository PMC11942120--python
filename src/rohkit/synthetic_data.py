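"""Seeded simulator of diploid genotype matrices with known autozygosity.

The simulator plants autozygous tracts directly into an otherwise
Hardy-Weinberg background (a copying model, not a forward-in-time pedigree
simulation): background allele frequencies are drawn from a configurable
law (default: minor-allele frequency uniform on [0.05, 0.5]), tract lengths
follow the exponential law with mean 1/(2g) Morgans for inbreeding g
generations back (truncated below a minimum length), tracts are placed
uniformly without overlap per individual, and genotypes inside tracts are
forced homozygous with the allele drawn by local frequency, then perturbed
by configurable heterozygote/missing noise. Group-shared tracts at chosen
loci emulate ROH islands. Everything is driven by one seeded generator, so
identical configs give bit-identical output.

An optional block-LD background (shared haplotype pools per block) exists
solely to give the LD/Ne stage orderable LD strength; the default
background is site-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from rohkit.genotype_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from rohkit.inbreeding import inbreeding_table
from rohkit.islands import find_islands
from rohkit.roh_detect import ROHParams, ROHSegment, call_roh


@dataclass(frozen=True)
class IslandSpec:
    """A group-shared autozygous locus (1-based inclusive bp interval)."""

    chrom: str
    start_bp: int
    end_bp: int
    group: str
    carrier_fraction: float = 0.8


@dataclass(frozen=True)
class PlantedTract:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SimConfig:
    """Study conditions for one simulated population.

    Defaults describe the desk-scale stand-in for a livestock resequencing
    panel: 20 individuals, five 100-Mb autosomes (~500 Mb), 100 SNPs/Mb
    (~50k sites), MAF uniform on [0.05, 0.5], inbreeding ~50 generations
    back (mean tract 1/(2*50) Morgans = 1 Mb at 1 cM/Mb), and low
    genotyping noise.
    """

    seed: int
    n_individuals: int = 20
    chrom_lengths_bp: tuple[int, ...] = (100_000_000,) * 5
    snp_density_per_mb: float = 100.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_f: float | Sequence[float] = 0.05
    generations: float = 50.0  # tract length ~ Exp(mean 1/(2g) Morgans)
    fixed_tract_lengths_bp: tuple[int, ...] | None = None  # overrides the length law
    min_tract_bp: int = 100_000
    cm_per_mb: float = 1.0
    islands: tuple[IslandSpec, ...] = ()
    groups: Sequence[str] | None = None  # per-individual labels; default one group
    het_noise_rate: float = 0.002  # inside tracts
    tract_missing_rate: float = 0.002
    background_missing_rate: float = 0.002
    ld_block_bp: int | None = None  # block-LD background (optional)
    ld_n_haplotypes: int = 20  # haplotype pool size per block (smaller = more LD)

    def __post_init__(self) -> None:
        for rate in (self.het_noise_rate, self.tract_missing_rate,
                     self.background_missing_rate):
            if not (0 <= rate <= 1):
                raise ValueError("noise rates must lie in [0, 1]")
        f = np.atleast_1d(np.asarray(self.target_f, dtype=float))
        if np.any((f < 0) | (f >= 1)):
            raise ValueError("target F* must lie in [0, 1)")
        if min(self.chrom_lengths_bp) <= 0 or self.min_tract_bp <= 0:
            raise ValueError("lengths must be positive")

    @property
    def genome_bp(self) -> int:
        return int(sum(self.chrom_lengths_bp))

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths_bp))]

    @property
    def sample_ids(self) -> list[str]:
        return [f"ind{i + 1:03d}" for i in range(self.n_individuals)]

    def per_individual_f(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.target_f, dtype=float))
        if f.size == 1:
            return np.full(self.n_individuals, float(f[0]))
        if f.size != self.n_individuals:
            raise ValueError("target_f length must equal n_individuals")
        return f

    def group_labels(self) -> list[str]:
        if self.groups is None:
            return ["pop1"] * self.n_individuals
        if len(self.groups) != self.n_individuals:
            raise ValueError("groups length must equal n_individuals")
        return list(self.groups)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.group_labels()}
        )


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated matrix."""

    tracts: list[PlantedTract]
    islands: list[IslandSpec]
    island_carriers: dict[int, list[str]]  # island index -> carrier sample ids
    f_true: dict[str, float]  # realized planted length / genome length

    def tracts_of(self, sample_id: str) -> list[PlantedTract]:
        return [t for t in self.tracts if t.sample_id == sample_id]


def _draw_tract_length(cfg: SimConfig, rng: np.random.Generator, counter: int) -> int:
    if cfg.fixed_tract_lengths_bp is not None:
        return int(cfg.fixed_tract_lengths_bp[counter % len(cfg.fixed_tract_lengths_bp)])
    mean_morgans = 1.0 / (2.0 * cfg.generations)
    bp_per_morgan = 100.0 / cfg.cm_per_mb * 1e6
    for _ in range(10_000):  # truncation by rejection
        length = rng.exponential(mean_morgans) * bp_per_morgan
        if length >= cfg.min_tract_bp:
            return int(round(length))
    raise RuntimeError("tract length law cannot reach the minimum tract length")


def _place_tract(
    length_bp: int,
    existing: list[tuple[str, int, int]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Uniform placement without per-individual overlap (rejection sampling)."""
    lengths = np.asarray(cfg.chrom_lengths_bp, dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(1000):
        ci = int(rng.choice(len(lengths), p=probs))
        chrom_len = cfg.chrom_lengths_bp[ci]
        if length_bp > chrom_len:
            continue
        start = int(rng.integers(1, chrom_len - length_bp + 2))
        end = start + length_bp - 1
        chrom = cfg.chrom_names[ci]
        if any(c == chrom and s <= end and start <= e for c, s, e in existing):
            continue
        return chrom, start, end
    raise RuntimeError(
        "target F* unreachable: could not place a tract without overlap "
        "(genome too small for the requested autozygosity)"
    )


def _snp_positions(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Sorted unique 1-based SNP positions per chromosome."""
    out: dict[str, np.ndarray] = {}
    for chrom, length in zip(cfg.chrom_names, cfg.chrom_lengths_bp):
        n = int(round(length / 1e6 * cfg.snp_density_per_mb))
        pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.05) + 8))
        if pos.size > n:
            pos = np.sort(rng.choice(pos, size=n, replace=False))
        out[chrom] = pos
    return out


def _background_calls(
    p_alt: np.ndarray, n_ind: int, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg genotypes, sites x individuals, int8 codes."""
    return rng.binomial(2, p_alt[:, None], size=(p_alt.size, n_ind)).astype(np.int8)


def _background_calls_block_ld(
    pos: np.ndarray,
    p_alt: np.ndarray,
    n_ind: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Block-LD background: per block, individuals draw 2 haplotypes from a
    shared pool of ``ld_n_haplotypes``; smaller pools give stronger LD."""
    calls = np.empty((pos.size, n_ind), dtype=np.int8)
    block_idx = pos // cfg.ld_block_bp
    for b in np.unique(block_idx):
        sel = block_idx == b
        k = cfg.ld_n_haplotypes
        haps = (rng.random((int(sel.sum()), k)) < p_alt[sel, None]).astype(np.int8)
        pick = rng.integers(0, k, size=(2, n_ind))
        calls[sel] = haps[:, pick[0]] + haps[:, pick[1]]
    return calls


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate a genotype matrix plus ground truth under ``cfg``.

    Island tracts are planted first (identical coordinates in the chosen
    carrier subset of each group); per-individual random tracts then
    accumulate toward the target F*, dropping the final tract when that
    leaves the realized total closer to the target. Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.sample_ids
    groups = cfg.group_labels()
    positions = _snp_positions(cfg, rng)

    # background matrix
    site_frames = []
    call_blocks = []
    p_alt_blocks = []
    bases = np.array(list("ACGT"))
    for chrom in cfg.chrom_names:
        pos = positions[chrom]
        p_alt = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=pos.size)
        ref_i = rng.integers(0, 4, size=pos.size)
        alt_i = (ref_i + rng.integers(1, 4, size=pos.size)) % 4
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": bases[ref_i],
                    "alt": bases[alt_i],
                    "id": None,
                }
            )
        )
        if cfg.ld_block_bp:
            call_blocks.append(
                _background_calls_block_ld(pos, p_alt, cfg.n_individuals, cfg, rng)
            )
        else:
            call_blocks.append(_background_calls(p_alt, cfg.n_individuals, rng))
        p_alt_blocks.append(p_alt)
    sites = pd.concat(site_frames, ignore_index=True)
    calls = np.vstack(call_blocks)
    p_alt_all = np.concatenate(p_alt_blocks)

    # plan tracts: islands first, then random fill toward per-individual F*
    tracts_by_ind: dict[str, list[tuple[str, int, int]]] = {s: [] for s in samples}
    island_carriers: dict[int, list[str]] = {}
    for k, isl in enumerate(cfg.islands):
        members = [s for s, g in zip(samples, groups) if g == isl.group]
        if not members:
            raise ValueError(f"island {k}: no individuals in group {isl.group!r}")
        n_carriers = int(round(isl.carrier_fraction * len(members)))
        carriers = [members[i] for i in rng.permutation(len(members))[:n_carriers]]
        island_carriers[k] = sorted(carriers)
        for s in carriers:
            tracts_by_ind[s].append((isl.chrom, isl.start_bp, isl.end_bp))

    f_targets = cfg.per_individual_f()
    genome_bp = cfg.genome_bp
    counter = 0
    for s, f_star in zip(samples, f_targets):
        existing = tracts_by_ind[s]
        total = sum(e - st + 1 for _, st, e in existing)
        target = f_star * genome_bp
        added: list[tuple[str, int, int]] = []
        while total < target:
            length = _draw_tract_length(cfg, rng, counter)
            counter += 1
            tract = _place_tract(length, existing, cfg, rng)
            existing.append(tract)
            added.append(tract)
            total += length
        if added:
            last_len = added[-1][2] - added[-1][1] + 1
            if (total - target) > (target - (total - last_len)):
                existing.remove(added[-1])

    # stamp tracts onto the matrix
    chrom_offsets: dict[str, int] = {}
    off = 0
    for chrom in cfg.chrom_names:
        chrom_offsets[chrom] = off
        off += positions[chrom].size
    truth_tracts: list[PlantedTract] = []
    for j, s in enumerate(samples):
        for chrom, start, end in sorted(tracts_by_ind[s]):
            truth_tracts.append(PlantedTract(s, chrom, start, end))
            pos = positions[chrom]
            lo = chrom_offsets[chrom] + int(np.searchsorted(pos, start, side="left"))
            hi = chrom_offsets[chrom] + int(np.searchsorted(pos, end, side="right"))
            if hi <= lo:
                continue
            p = p_alt_all[lo:hi]
            hom = np.where(rng.random(hi - lo) < p, HOM_ALT, HOM_REF).astype(np.int8)
            u = rng.random(hi - lo)
            hom[u < cfg.het_noise_rate] = HET
            hom[(u >= cfg.het_noise_rate)
                & (u < cfg.het_noise_rate + cfg.tract_missing_rate)] = MISSING
            calls[lo:hi, j] = hom

    # background missingness (outside tracts only: applied before would be
    # overwritten anyway, so apply to non-tract cells now)
    if cfg.background_missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.background_missing_rate
        in_tract = np.zeros(calls.shape, dtype=bool)
        for t in truth_tracts:
            j = samples.index(t.sample_id)
            pos = positions[t.chrom]
            lo = chrom_offsets[t.chrom] + int(np.searchsorted(pos, t.start_bp, "left"))
            hi = chrom_offsets[t.chrom] + int(np.searchsorted(pos, t.end_bp, "right"))
            in_tract[lo:hi, j] = True
        calls[miss & ~in_tract] = MISSING

    gm = GenotypeMatrix(
        sites=sites,
        samples=list(samples),
        calls=calls,
        chrom_order=list(cfg.chrom_names),
        contig_lengths=dict(zip(cfg.chrom_names, cfg.chrom_lengths_bp)),
    )
    f_true = {
        s: sum(t.length_bp for t in truth_tracts if t.sample_id == s) / genome_bp
        for s in samples
    }
    truth = SimTruth(
        tracts=truth_tracts,
        islands=list(cfg.islands),
        island_carriers=island_carriers,
        f_true=f_true,
    )
    return gm, truth


# --------------------------------------------------------------------------
# end-to-end harness


@dataclass
class EndToEndReport:
    tract_recall: float
    tract_precision: float
    f_roh: dict[str, float]
    f_true: dict[str, float]
    mean_abs_f_error: float
    islands_found: dict[int, int]  # truth island index -> overlapping islands
    islands_total: dict[str, int]  # group -> total islands called


def _overlap_fraction(seg_like, tracts: Sequence[PlantedTract]) -> float:
    covered = 0
    for t in tracts:
        if t.chrom != seg_like.chrom:
            continue
        covered += max(
            0, min(seg_like.end_pos, t.end_bp) - max(seg_like.start_pos, t.start_bp) + 1
        )
    return covered / seg_like.length_bp


def end_to_end_check(
    cfg: SimConfig,
    params: ROHParams | None = None,
    top_fraction: float = 0.005,
) -> EndToEndReport:
    """Simulate, run detect -> inbreeding -> islands, compare to truth.

    A planted tract counts as recovered when detected segments of the same
    individual cover >= 50% of it; a detected segment counts as a true
    positive when planted tracts cover >= 50% of it.
    """
    params = params or ROHParams()
    gm, truth = simulate_population(cfg)
    segments = call_roh(gm, params)

    n_rec = 0
    for t in truth.tracts:
        segs = [s for s in segments if s.sample_id == t.sample_id and s.chrom == t.chrom]
        covered = sum(s.overlap_bp(t.start_bp, t.end_bp) for s in segs)
        if covered >= 0.5 * t.length_bp:
            n_rec += 1
    recall = n_rec / len(truth.tracts) if truth.tracts else float("nan")

    n_tp = 0
    for seg in segments:
        tracts = [t for t in truth.tracts if t.sample_id == seg.sample_id]
        if _overlap_fraction(seg, tracts) >= 0.5:
            n_tp += 1
    precision = n_tp / len(segments) if segments else float("nan")

    records = inbreeding_table(gm, segments, L_au_mb=cfg.genome_bp / 1e6)
    f_roh = {r.sample_id: r.F_ROH for r in records}
    errors = [abs(f_roh[s] - truth.f_true[s]) for s in gm.samples]

    metadata = cfg.metadata()
    islands_found: dict[int, int] = {}
    islands_total: dict[str, int] = {}
    for group in sorted(set(cfg.group_labels())):
        _, _, islands = find_islands(
            segments, gm, metadata, group, top_fraction=top_fraction
        )
        islands_total[group] = len(islands)
        for k, isl in enumerate(cfg.islands):
            if isl.group != group:
                continue
            islands_found[k] = sum(
                1 for i in islands
                if i.chrom == isl.chrom and i.overlaps(isl.start_bp, isl.end_bp)
            )
    return EndToEndReport(
        tract_recall=recall,
        tract_precision=precision,
        f_roh=f_roh,
        f_true=dict(truth.f_true),
        mean_abs_f_error=float(np.mean(errors)),
        islands_found=islands_found,
        islands_total=islands_total,
    )
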