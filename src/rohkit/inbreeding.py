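"""Genomic inbreeding coefficients.

F_ROH = L_ROH / L_au: total ROH length over the autosomal length covered by
SNPs. L_au defaults to the summed first-to-last-SNP span per autosome in the
input matrix, overridable by a user constant.

F_HOM is the excess-homozygosity (method-of-moments) coefficient:
F_HOM = (O_hom - E_hom) / (N_sites - E_hom), where for each site used the
expected homozygosity is 1 - 2pq * n/(n-1), with p, q cohort allele
frequencies and n the number of non-missing alleles at the site (the
small-sample correction matches the conventional --het-style estimator).
Missing calls in a sample are excluded from both O_hom and N_sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rohkit.genotype_io import HET, MISSING, GenotypeMatrix
from rohkit.roh_detect import ROHSegment


@dataclass
class InbreedingRecord:
    sample_id: str
    L_ROH_mb: float
    L_au_mb: float
    F_ROH: float
    O_hom: int
    E_hom: float
    N_sites: int
    F_HOM: float  # NaN when the denominator degenerates


def f_roh(segments: Sequence[ROHSegment], sample: str, L_au_mb: float) -> float:
    """F_ROH = total ROH length / autosomal SNP-covered length (both Mb)."""
    if L_au_mb <= 0:
        raise ValueError("L_au must be positive")
    L_roh = sum(s.length_mb for s in segments if s.sample_id == sample)
    return L_roh / L_au_mb


def _site_expected_hom(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site expected homozygosity 1 - 2pq*n/(n-1) and usability mask.

    Sites with fewer than 2 non-missing genotypes (n < 4 alleles would still
    be fine; n < 2 alleles is degenerate) are unusable.
    """
    nonmiss = gm.calls != MISSING
    n_geno = nonmiss.sum(axis=1)
    alt = np.where(nonmiss, gm.calls, 0).sum(axis=1).astype(float)
    n_alleles = 2.0 * n_geno
    usable = n_geno >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(usable, alt / np.maximum(n_alleles, 1.0), np.nan)
        q = 1.0 - p
        corr = n_alleles / np.maximum(n_alleles - 1.0, 1.0)
        e_hom = 1.0 - 2.0 * p * q * corr
    return e_hom, usable


def f_hom(gm: GenotypeMatrix, sample: str) -> tuple[int, float, int, float]:
    """Observed/expected homozygosity for one sample.

    Returns ``(O_hom, E_hom, N_sites, F_HOM)`` over sites that are
    non-missing in the sample and have computable cohort frequencies.
    F_HOM is NaN when N_sites == E_hom.
    """
    e_hom_site, usable = _site_expected_hom(gm)
    col = gm.calls[:, gm.sample_index(sample)]
    used = usable & (col != MISSING)
    n_sites = int(used.sum())
    o_hom = int(np.sum(used & (col != HET)))
    e_hom = float(np.sum(e_hom_site[used]))
    denom = n_sites - e_hom
    fh = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else float("nan")
    return o_hom, e_hom, n_sites, fh


def inbreeding_table(
    gm: GenotypeMatrix,
    segments: Sequence[ROHSegment],
    L_au_mb: float | None = None,
    samples: Sequence[str] | None = None,
) -> list[InbreedingRecord]:
    """Per-individual F_ROH and F_HOM for all (or selected) samples."""
    if L_au_mb is None:
        L_au_mb = gm.autosomal_span_mb()
    records = []
    for sample in samples or gm.samples:
        fr = f_roh(segments, sample, L_au_mb)
        o_hom, e_hom, n_sites, fh = f_hom(gm, sample)
        records.append(
            InbreedingRecord(
                sample_id=sample,
                L_ROH_mb=fr * L_au_mb,
                L_au_mb=L_au_mb,
                F_ROH=fr,
                O_hom=o_hom,
                E_hom=e_hom,
                N_sites=n_sites,
                F_HOM=fh,
            )
        )
    return records


def correlate_f(
    records: Sequence[InbreedingRecord],
    metadata: pd.DataFrame | None = None,
    group: str | None = None,
) -> float:
    """Pearson correlation between F_ROH and F_HOM over a group's individuals.

    NaN when fewer than two individuals have both coefficients defined or
    either coefficient has zero variance.
    """
    if group is not None:
        if metadata is None:
            raise ValueError("metadata required when a group is requested")
        ids = set(metadata.loc[metadata["group"] == group, "sample_id"])
        if not ids:
            raise KeyError(f"unknown group: {group!r}")
        records = [r for r in records if r.sample_id in ids]
    x = np.array([r.F_ROH for r in records], dtype=float)
    y = np.array([r.F_HOM for r in records], dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def records_to_frame(records: Sequence[InbreedingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "L_ROH_mb": r.L_ROH_mb,
                "L_au_mb": r.L_au_mb,
                "F_ROH": r.F_ROH,
                "O_hom": r.O_hom,
                "E_hom": r.E_hom,
                "N_sites": r.N_sites,
                "F_HOM": r.F_HOM,
            }
            for r in records
        ]
    )
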