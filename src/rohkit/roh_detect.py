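"""Runs-of-homozygosity detection by sliding-window scanning.

The scanning rule mirrors the PLINK ``--homozyg`` family of detectors: a
fixed-size window (default 50 SNPs) slides along each chromosome, a window
is *homozygous-compatible* if it contains at most ``max_het_per_window``
heterozygous and ``max_missing_per_window`` missing calls, each SNP receives
the fraction of windows covering it that are compatible, and SNPs whose
fraction reaches ``hit_proportion`` seed candidate runs. Candidate runs are
split at inter-SNP gaps above ``max_gap_kb``, trimmed to their outermost
confidently homozygous SNP, and kept only if they satisfy the minimum SNP
count, minimum length, and maximum kb-per-SNP density rules.

``brute_force_roh`` re-derives the same contract by direct enumeration of
every window and run, with no incremental optimisation; it exists as an
independent oracle for testing and refuses large inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rohkit.genotype_io import HET, MISSING, GenotypeMatrix


@dataclass(frozen=True)
class ROHParams:
    """Detection parameters (defaults: 50-SNP windows allowing 2 het and 5
    missing calls; runs of >= 100 SNPs, >= 500 kb, <= 50 kb/SNP density,
    split at gaps > 1000 kb; window-hit threshold 0.05)."""

    window_snps: int = 50
    max_het_per_window: int = 2
    max_missing_per_window: int = 5
    min_snps: int = 100
    min_length_kb: float = 500.0
    max_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    hit_proportion: float = 0.05

    def __post_init__(self) -> None:
        if min(self.window_snps, self.max_het_per_window,
               self.max_missing_per_window, self.min_snps) < 0:
            raise ValueError("counts must be >= 0")
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if self.min_length_kb <= 0:
            raise ValueError("min_length_kb must be > 0")
        if not (0 < self.hit_proportion <= 1):
            raise ValueError("hit_proportion must be in (0, 1]")


@dataclass(frozen=True, order=True)
class ROHSegment:
    """One homozygous run: 1-based inclusive bp span of its first/last SNP."""

    sample_id: str
    chrom: str
    start_pos: int
    end_pos: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    def overlap_bp(self, start: int, end: int) -> int:
        """Overlap in bp with another 1-based inclusive interval."""
        return max(0, min(self.end_pos, end) - max(self.start_pos, start) + 1)


def _window_pass(het: np.ndarray, miss: np.ndarray, params: ROHParams) -> np.ndarray:
    """Compatibility of each full window (rolling-sum implementation)."""
    w = params.window_snps
    het_cs = np.concatenate(([0], np.cumsum(het)))
    miss_cs = np.concatenate(([0], np.cumsum(miss)))
    het_sum = het_cs[w:] - het_cs[:-w]
    miss_sum = miss_cs[w:] - miss_cs[:-w]
    return (het_sum <= params.max_het_per_window) & (miss_sum <= params.max_missing_per_window)


def _hit_fractions_chrom(geno: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP fraction of compatible covering windows for one chromosome.

    Chromosomes shorter than one window are scored with a single truncated
    window spanning the whole chromosome.
    """
    m = geno.size
    het = (geno == HET).astype(np.int64)
    miss = (geno == MISSING).astype(np.int64)
    w = params.window_snps
    if m < w:
        ok = (het.sum() <= params.max_het_per_window) and (
            miss.sum() <= params.max_missing_per_window
        )
        return np.full(m, 1.0 if ok else 0.0)
    passed = _window_pass(het, miss, params)
    pass_cs = np.concatenate(([0], np.cumsum(passed)))
    idx = np.arange(m)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, m - w)
    n_pass = pass_cs[hi + 1] - pass_cs[lo]
    return n_pass / (hi - lo + 1)


def window_scan(gm: GenotypeMatrix, sample: str, params: ROHParams | None = None) -> np.ndarray:
    """Per-SNP window hit fraction for one sample across all chromosomes.

    Returns an array aligned with ``gm.sites``.
    """
    params = params or ROHParams()
    col = gm.calls[:, gm.sample_index(sample)]
    out = np.empty(gm.n_sites, dtype=float)
    for chrom in gm.chromosomes():
        sl = gm.chrom_slice(chrom)
        out[sl] = _hit_fractions_chrom(col[sl], params)
    return out


def _runs_from_candidates(
    cand: np.ndarray,
    pos: np.ndarray,
    geno: np.ndarray,
    params: ROHParams,
    sample: str,
    chrom: str,
) -> list[ROHSegment]:
    """Assemble, split, trim and filter candidate runs on one chromosome."""
    max_gap_bp = params.max_gap_kb * 1000.0
    min_len_bp = params.min_length_kb * 1000.0
    max_density_bp = params.max_density_kb_per_snp * 1000.0

    segments: list[ROHSegment] = []
    cand_idx = np.flatnonzero(cand)
    if cand_idx.size == 0:
        return segments
    # maximal stretches of consecutively indexed candidate SNPs, additionally
    # split where the bp gap between consecutive candidates exceeds max_gap
    breaks = (np.diff(cand_idx) > 1) | (np.diff(pos[cand_idx]) > max_gap_bp)
    run_bounds = np.concatenate(([0], np.flatnonzero(breaks) + 1, [cand_idx.size]))
    good = (geno != HET) & (geno != MISSING)
    for k in range(run_bounds.size - 1):
        run = cand_idx[run_bounds[k]:run_bounds[k + 1]]
        # trim both ends to the outermost confidently homozygous SNP
        inner = np.flatnonzero(good[run])
        if inner.size == 0:
            continue
        i0, i1 = int(run[inner[0]]), int(run[inner[-1]])
        n_snps = i1 - i0 + 1
        length_bp = int(pos[i1]) - int(pos[i0]) + 1
        if n_snps < params.min_snps:
            continue
        if length_bp < min_len_bp:
            continue
        if length_bp / n_snps > max_density_bp:
            continue
        segments.append(ROHSegment(sample, chrom, int(pos[i0]), int(pos[i1]), n_snps))
    return segments


def call_roh(
    gm: GenotypeMatrix,
    params: ROHParams | None = None,
    samples: Sequence[str] | None = None,
) -> list[ROHSegment]:
    """Detect ROH for each sample; segments sorted by (sample, chrom, start).

    Chromosome order follows ``gm.chrom_order``; an empty matrix yields an
    empty list.
    """
    params = params or ROHParams()
    samples = list(samples) if samples is not None else list(gm.samples)
    segments: list[ROHSegment] = []
    chrom_slices = [(c, gm.chrom_slice(c)) for c in gm.chromosomes()]
    pos_all = gm.sites["pos"].to_numpy()
    for sample in samples:
        col = gm.calls[:, gm.sample_index(sample)]
        for chrom, sl in chrom_slices:
            geno = col[sl]
            if geno.size == 0:
                continue
            frac = _hit_fractions_chrom(geno, params)
            cand = frac >= params.hit_proportion
            segments.extend(
                _runs_from_candidates(cand, pos_all[sl], geno, params, sample, chrom)
            )
    return segments


# --------------------------------------------------------------------------
# brute-force oracle


def brute_force_roh(
    gm: GenotypeMatrix,
    sample: str,
    params: ROHParams | None = None,
    size_guard: int = 5000,
) -> list[ROHSegment]:
    """Reference ROH caller by direct enumeration (testing oracle).

    Evaluates every window afresh per SNP and builds runs with explicit
    loops; refuses matrices above ``size_guard`` sites.
    """
    params = params or ROHParams()
    if gm.n_sites > size_guard:
        raise ValueError(f"brute_force_roh refuses inputs above {size_guard} SNPs")
    col = gm.calls[:, gm.sample_index(sample)]
    pos_all = gm.sites["pos"].to_numpy()
    segments: list[ROHSegment] = []
    for chrom in gm.chromosomes():
        sl = gm.chrom_slice(chrom)
        geno = col[sl]
        pos = pos_all[sl]
        m = geno.size
        if m == 0:
            continue
        w = params.window_snps

        def window_ok(a: int, b: int) -> bool:
            chunk = geno[a:b]
            n_het = int(np.sum(chunk == HET))
            n_miss = int(np.sum(chunk == MISSING))
            return (n_het <= params.max_het_per_window
                    and n_miss <= params.max_missing_per_window)

        cand = []
        for i in range(m):
            if m < w:
                cand.append(window_ok(0, m))
                continue
            hits = total = 0
            for s in range(max(0, i - w + 1), min(i, m - w) + 1):
                total += 1
                if window_ok(s, s + w):
                    hits += 1
            cand.append(hits / total >= params.hit_proportion)

        # explicit run construction: consecutive candidates, gap split
        runs: list[list[int]] = []
        current: list[int] = []
        for i in range(m):
            if not cand[i]:
                if current:
                    runs.append(current)
                current = []
                continue
            if current and pos[i] - pos[current[-1]] > params.max_gap_kb * 1000.0:
                runs.append(current)
                current = []
            current.append(i)
        if current:
            runs.append(current)

        for run in runs:
            while run and geno[run[0]] in (HET, MISSING):
                run = run[1:]
            while run and geno[run[-1]] in (HET, MISSING):
                run = run[:-1]
            if not run:
                continue
            i0, i1 = run[0], run[-1]
            n_snps = i1 - i0 + 1
            length_bp = int(pos[i1]) - int(pos[i0]) + 1
            if n_snps < params.min_snps:
                continue
            if length_bp < params.min_length_kb * 1000.0:
                continue
            if length_bp / n_snps > params.max_density_kb_per_snp * 1000.0:
                continue
            segments.append(ROHSegment(sample, chrom, int(pos[i0]), int(pos[i1]), n_snps))
    return segments


def segments_to_frame(segments: Sequence[ROHSegment]):
    """Tabulate segments as a DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start_pos,
                "end": s.end_pos,
                "n_snps": s.n_snps,
                "length_bp": s.length_bp,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start", "end", "n_snps", "length_bp"],
    )


def segments_from_frame(df) -> list[ROHSegment]:
    """Inverse of :func:`segments_to_frame`."""
    return [
        ROHSegment(str(r.sample_id), str(r.chrom), int(r.start), int(r.end), int(r.n_snps))
        for r in df.itertuples(index=False)
    ]
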