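"""Pairwise linkage disequilibrium, LD decay, and LD-based Ne estimation.

LD is summarised as the squared Pearson correlation (r^2) of genotype
dosages (0/1/2 alternate-allele counts), the composite measure appropriate
for unphased data. Binned mean r^2 against distance gives the decay curve.

Effective population size follows the Sved relation
``E[r^2] = 1 / (alpha + 4 N_e c)`` with the sampling-noise adjustment
``r^2_adj = mean r^2 - 1/(2 n)``; inverting gives
``N_e = (1/(4c)) (1/r^2_adj - alpha)`` referred to ``t = 1/(2c)``
generations ago. Physical distance maps to recombination fraction c through
a uniform genetic map (default 1 cM/Mb).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from rohkit.genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: floor for the adjusted r^2 so the Sved inversion stays finite
R2_ADJ_EPS = 1e-12


@dataclass(frozen=True)
class LDBin:
    """Half-open distance bin [start_bp, end_bp) with its mean r^2."""

    start_bp: int
    end_bp: int
    mean_r2: float
    n_pairs: int
    c_morgans: float  # recombination fraction at the bin midpoint

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


@dataclass(frozen=True)
class NeEstimate:
    t_generations: float
    ne: float
    bin: LDBin


def _dosages(gm: GenotypeMatrix, sample_idx: Sequence[int]) -> np.ndarray:
    """Float dosage matrix (sites x selected samples) with NaN for missing."""
    d = gm.calls[:, list(sample_idx)].astype(float)
    d[d == MISSING] = np.nan
    return d


def pairwise_r2(
    gm: GenotypeMatrix,
    group_samples: Sequence[str] | None = None,
    max_dist_bp: int = 1_000_000,
) -> pd.DataFrame:
    """r^2 for all same-chromosome SNP pairs within ``max_dist_bp``.

    r^2 is the squared Pearson correlation of dosages over individuals
    non-missing at both sites. Pairs with fewer than two complete
    observations, and sites monomorphic within the group, are skipped.
    Returns a DataFrame with columns ``chrom, dist_bp, r2``.
    """
    samples = list(group_samples) if group_samples is not None else list(gm.samples)
    if len(samples) < 2:
        raise ValueError("need at least two individuals for LD")
    idx = [gm.sample_index(s) for s in samples]
    dos = _dosages(gm, idx)
    pos_all = gm.sites["pos"].to_numpy()

    out_chrom: list[str] = []
    out_dist: list[int] = []
    out_r2: list[float] = []
    for chrom in gm.chromosomes():
        sl = gm.chrom_slice(chrom)
        pos = pos_all[sl]
        d = dos[sl]
        m = pos.size
        for i in range(m):
            j_hi = int(np.searchsorted(pos, pos[i] + max_dist_bp, side="right"))
            for j in range(i + 1, j_hi):
                both = ~(np.isnan(d[i]) | np.isnan(d[j]))
                if both.sum() < 2:
                    continue
                x, y = d[i, both], d[j, both]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    continue  # monomorphic within the compared individuals
                r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
                out_chrom.append(chrom)
                out_dist.append(int(pos[j] - pos[i]))
                out_r2.append(float(r * r))
    return pd.DataFrame({"chrom": out_chrom, "dist_bp": out_dist, "r2": out_r2})


def ld_decay(
    pairs: pd.DataFrame,
    bin_width_bp: int = 50_000,
    cm_per_mb: float = 1.0,
) -> list[LDBin]:
    """Group (distance, r^2) pairs into half-open distance bins.

    Empty bins are omitted. Bin midpoints are converted to recombination
    fractions c (Morgans) through the uniform map.
    """
    if pairs.empty:
        raise ValueError("no LD pairs supplied")
    dist = pairs["dist_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    bin_idx = dist // bin_width_bp
    bins: list[LDBin] = []
    for b in np.unique(bin_idx):
        sel = bin_idx == b
        start = int(b) * bin_width_bp
        end = start + bin_width_bp
        mid_mb = (start + end) / 2.0 / 1e6
        bins.append(
            LDBin(
                start_bp=start,
                end_bp=end,
                mean_r2=float(r2[sel].mean()),
                n_pairs=int(sel.sum()),
                c_morgans=mid_mb * cm_per_mb / 100.0,
            )
        )
    return bins


def ne_from_ld(
    bins: Sequence[LDBin],
    sample_n: int,
    alpha: float = 1.0,
) -> list[NeEstimate]:
    """Invert the Sved relation per bin.

    ``r2_adj = mean_r2 - 1/(2 sample_n)`` floored at a small positive
    epsilon; ``Ne = (1/(4c)) (1/r2_adj - alpha)`` at ``t = 1/(2c)``
    generations. Negative Ne (r2_adj above the alpha asymptote) is floored
    at 0 with a warning. Bins with c <= 0 are skipped.
    """
    if sample_n < 2:
        raise ValueError("sample_n must be >= 2")
    estimates: list[NeEstimate] = []
    for b in bins:
        c = b.c_morgans
        if c <= 0:
            continue
        r2_adj = max(b.mean_r2 - 1.0 / (2.0 * sample_n), R2_ADJ_EPS)
        ne = (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha)
        if ne < 0:
            warnings.warn(
                f"bin [{b.start_bp}, {b.end_bp}): adjusted r^2 {r2_adj:.4f} exceeds "
                f"the 1/alpha asymptote; Ne floored at 0",
                stacklevel=2,
            )
            ne = 0.0
        estimates.append(NeEstimate(t_generations=1.0 / (2.0 * c), ne=ne, bin=b))
    return estimates


def sved_r2(ne: float, c: float, alpha: float = 1.0) -> float:
    """Forward Sved map: expected r^2 (without sampling noise)."""
    return 1.0 / (alpha + 4.0 * ne * c)


def ld_bins_to_frame(bins: Sequence[LDBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_bp": b.start_bp,
                "end_bp": b.end_bp,
                "mean_r2": b.mean_r2,
                "n_pairs": b.n_pairs,
                "c_morgans": b.c_morgans,
            }
            for b in bins
        ]
    )


def ne_to_frame(estimates: Sequence[NeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"t_generations": e.t_generations, "Ne": e.ne} for e in estimates]
    )
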