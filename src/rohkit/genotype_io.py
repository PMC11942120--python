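"""Genotype matrix container, VCF input/output, and site-level quality filters.

Genotypes are stored as an int8 matrix of codes (sites x samples):
``HOM_REF=0, HET=1, HOM_ALT=2, MISSING=-1``. Phase is ignored; half-calls
(e.g. ``./1``) are treated as missing. Only biallelic SNP records are kept.

Coordinates are 1-based inclusive (VCF convention) throughout the package;
BED exports are converted to 0-based half-open at write time.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP site (1-based position)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    site_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alleles must be single nucleotides "
                f"(got {self.ref_allele!r}/{self.alt_allele!r})"
            )


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for sites x samples.

    Attributes
    ----------
    sites : pd.DataFrame
        Columns ``chrom, pos, ref, alt, id``; sorted by (chrom, pos) with
        strictly increasing pos within each chromosome. Chromosome order
        follows ``chrom_order``.
    samples : list of str
        Sample identifiers, column order of ``calls``.
    calls : np.ndarray
        int8 array of shape (n_sites, n_samples) with genotype codes.
    chrom_order : list of str
        Chromosome ordering (from the VCF header contig lines, or order of
        first appearance).
    contig_lengths : dict
        Optional chromosome lengths in bp (from header contig lines).
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    chrom_order: list[str] = field(default_factory=list)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if not self.chrom_order:
            self.chrom_order = list(dict.fromkeys(self.sites["chrom"]))
        self._validate_sorted()

    def _validate_sorted(self) -> None:
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        for i in range(1, len(self.sites)):
            if chrom[i] == chrom[i - 1]:
                if pos[i] == pos[i - 1]:
                    raise ValueError(
                        f"duplicated site {chrom[i]}:{pos[i]} (records {i - 1} and {i})"
                    )
                if pos[i] < pos[i - 1]:
                    raise ValueError(
                        f"unsorted input at {chrom[i]}:{pos[i]} "
                        f"(follows {chrom[i - 1]}:{pos[i - 1]})"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def chromosomes(self) -> list[str]:
        """Chromosomes present in the site table, in chrom_order."""
        present = set(self.sites["chrom"])
        return [c for c in self.chrom_order if c in present]

    def chrom_slice(self, chrom: str) -> slice:
        """Row slice of ``sites``/``calls`` belonging to one chromosome."""
        idx = np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def missing_rate(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency over non-missing calls only.

        Sites with zero non-missing calls get MAF 0.
        """
        nonmiss = self.calls != MISSING
        alt_count = np.where(nonmiss, self.calls, 0).sum(axis=1).astype(float)
        total = 2.0 * nonmiss.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(total > 0, alt_count / np.maximum(total, 1), 0.0)
        return np.minimum(p_alt, 1.0 - p_alt)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping sites where ``mask`` is True (order preserved)."""
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            calls=self.calls[mask],
            chrom_order=list(self.chrom_order),
            contig_lengths=dict(self.contig_lengths),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            sites=self.sites.copy(),
            samples=list(sample_ids),
            calls=self.calls[:, cols],
            chrom_order=list(self.chrom_order),
            contig_lengths=dict(self.contig_lengths),
        )

    def autosomal_span_mb(self) -> float:
        """Summed first-to-last SNP span per chromosome, in Mb.

        Default estimate of the autosomal length covered by SNPs (L_au)
        when the user supplies no constant.
        """
        total_bp = 0
        for chrom in self.chromosomes():
            sl = self.chrom_slice(chrom)
            pos = self.sites["pos"].to_numpy()[sl]
            total_bp += int(pos[-1]) - int(pos[0]) + 1
        return total_bp / 1e6

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and self.sites[["chrom", "pos", "ref", "alt"]].equals(
                other.sites[["chrom", "pos", "ref", "alt"]]
            )
        )


def _gt_code(allele_indices: list[int]) -> int:
    """Map a pair of allele indices (−1 = missing) to a genotype code."""
    if len(allele_indices) != 2 or -1 in allele_indices:
        return MISSING  # haploid or half-call: conservative
    a, b = allele_indices
    if a == 0 and b == 0:
        return HOM_REF
    if a == 1 and b == 1:
        return HOM_ALT
    return HET


def read_vcf(
    path: str | Path,
    samples: Sequence[str] | None = None,
    autosomes: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read a (possibly gzipped) VCF into a GenotypeMatrix.

    Only biallelic SNP records are retained. Phase is ignored; half-calls
    become MISSING. Raises on unsorted positions or duplicated (chrom, pos).

    Parameters
    ----------
    path : str or Path
    samples : optional subset of sample ids to load (order respected)
    autosomes : optional allow-list of contigs to keep (e.g. exclude X/MT);
        default keeps every contig in the file.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=False)
    if samples is not None:
        vcf.set_samples(list(samples))
    sample_ids = list(vcf.samples)

    chrom_order: list[str] = list(vcf.seqnames)
    contig_lengths: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        if length:
            contig_lengths[name] = int(length)

    allowed = set(autosomes) if autosomes is not None else None
    rows: list[tuple[str, int, str, str, str | None]] = []
    codes: list[np.ndarray] = []
    for var in vcf:
        if allowed is not None and var.CHROM not in allowed:
            continue
        if len(var.ALT) != 1:
            continue  # biallelic only
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            continue  # SNPs only
        rows.append((var.CHROM, var.POS, ref, alt, var.ID))
        row = np.fromiter(
            (_gt_code(list(g[:-1])) for g in var.genotypes),
            dtype=np.int8,
            count=len(sample_ids),
        )
        codes.append(row)
    vcf.close()

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "id"])
    calls = (
        np.vstack(codes) if codes else np.empty((0, len(sample_ids)), dtype=np.int8)
    )
    if autosomes is not None:
        chrom_order = [c for c in chrom_order if c in allowed]
    gm = GenotypeMatrix(
        sites=sites,
        samples=sample_ids,
        calls=calls,
        chrom_order=chrom_order or list(dict.fromkeys(sites["chrom"])),
        contig_lengths=contig_lengths,
    )
    logger.info("read %d biallelic SNPs x %d samples from %s", gm.n_sites, gm.n_samples, path)
    return gm


_CODE_TO_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path, extra_header: Iterable[str] = ()) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT-only FORMAT).

    Gzip-compresses when the path ends in ``.gz``.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohkit\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        for chrom in gm.chrom_order:
            length = gm.contig_lengths.get(chrom)
            if length:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        chroms = gm.sites["chrom"].to_numpy()
        poss = gm.sites["pos"].to_numpy()
        refs = gm.sites["ref"].to_numpy()
        alts = gm.sites["alt"].to_numpy()
        ids = gm.sites["id"].to_numpy() if "id" in gm.sites else [None] * gm.n_sites
        for i in range(gm.n_sites):
            sid = ids[i] if ids[i] not in (None, "", np.nan) else "."
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in gm.calls[i])
            fh.write(
                f"{chroms[i]}\t{poss[i]}\t{sid}\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    logger.info("wrote %d sites x %d samples to %s", gm.n_sites, gm.n_samples, path)


def filter_sites(
    gm: GenotypeMatrix,
    max_missing: float = 0.1,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Apply site-level quality filters.

    A site is retained iff its missing rate is strictly below ``max_missing``
    AND its minor allele frequency is at least ``min_maf`` (sites with
    missing rate >= 0.1 or MAF < 0.05 are removed under the defaults).
    MAF is computed from non-missing calls only. Order is preserved and the
    operation is idempotent.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    miss = gm.missing_rate()
    maf = gm.maf()
    keep_miss = miss < max_missing
    keep_maf = maf >= min_maf
    keep = keep_miss & keep_maf
    logger.info(
        "filter_sites: %d/%d retained (%d removed for missing rate >= %g, "
        "%d removed for MAF < %g)",
        int(keep.sum()), gm.n_sites,
        int((~keep_miss).sum()), max_missing,
        int(keep_miss.sum() - keep.sum()), min_maf,
    )
    return gm.subset_sites(keep)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a 2–3 column TSV: sample_id, group [, origin].

    Header optional (detected by a 'sample' prefix on the first field).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if str(df.iloc[0, 0]).lower().startswith("sample"):
        df = df.iloc[1:].reset_index(drop=True)
    cols = ["sample_id", "group", "origin"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample id in metadata: {dup}")
    return df[cols]


def group_samples(metadata: pd.DataFrame, group: str) -> list[str]:
    """Sample ids belonging to one group label."""
    sel = metadata.loc[metadata["group"] == group, "sample_id"].tolist()
    if not sel:
        raise KeyError(f"unknown group: {group!r}")
    return sel
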