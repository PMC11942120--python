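"""ROH islands: group-level homozygosity hotspots.

For a group of individuals, each SNP's *occurrence* is the fraction of the
group whose ROH cover its position. SNPs in the top 0.5% of occurrence
(empirical quantile, ties included) are retained, maximal runs of adjacent
retained SNPs become islands, and islands are annotated with the genes they
overlap in a GTF/GFF annotation.

Degenerate tracks (all zero, or constant so that "top" is meaningless)
yield no islands: :func:`island_threshold` returns ``None`` as a sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from rohkit.genotype_io import GenotypeMatrix
from rohkit.roh_detect import ROHSegment

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceTrack:
    """Per-SNP in-ROH occurrence within one group (values are multiples of 1/n)."""

    group: str
    n: int
    chrom: np.ndarray  # per-SNP chromosome labels, aligned with occurrence
    pos: np.ndarray  # per-SNP 1-based positions
    occurrence: np.ndarray  # fractions in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "occurrence": self.occurrence}
        )


@dataclass
class IslandRegion:
    chrom: str
    start_pos: int
    end_pos: int
    n_snps: int
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start_pos <= end and start <= self.end_pos


def snp_occurrence(
    segments: Sequence[ROHSegment],
    gm: GenotypeMatrix,
    metadata: pd.DataFrame,
    group: str,
) -> OccurrenceTrack:
    """Fraction of group individuals whose ROH cover each SNP position.

    An individual contributes at most 1 to a SNP's count regardless of how
    many of its segments cover it, so the track is invariant to duplicating
    every individual.
    """
    ids = metadata.loc[metadata["group"] == group, "sample_id"].tolist()
    if not ids:
        raise KeyError(f"unknown group: {group!r}")
    pos_all = gm.sites["pos"].to_numpy()
    counts = np.zeros(gm.n_sites, dtype=np.int64)
    for sample in ids:
        covered = np.zeros(gm.n_sites, dtype=bool)
        for seg in segments:
            if seg.sample_id != sample:
                continue
            sl = gm.chrom_slice(seg.chrom)
            pos = pos_all[sl]
            lo = sl.start + int(np.searchsorted(pos, seg.start_pos, side="left"))
            hi = sl.start + int(np.searchsorted(pos, seg.end_pos, side="right"))
            covered[lo:hi] = True
        counts += covered
    # segments of non-member samples are simply ignored
    return OccurrenceTrack(
        group=group,
        n=len(ids),
        chrom=gm.sites["chrom"].to_numpy(),
        pos=pos_all.copy(),
        occurrence=counts / len(ids),
    )


def island_threshold(
    track: OccurrenceTrack, top_fraction: float = 0.005
) -> float | None:
    """Occurrence threshold at the (1 - top_fraction) empirical quantile.

    SNPs with occurrence >= threshold are retained (ties included; occurrence
    values are discrete multiples of 1/n, so a strict cut could retain
    nothing). A SNP covered by no ROH at all can never be an island member,
    so the threshold is floored at the smallest positive occurrence when the
    quantile lands on zero (sparse tracks). Returns ``None`` for degenerate
    constant tracks, including the all-zero track, where "top" carries no
    information.
    """
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    occ = track.occurrence
    if occ.size == 0 or occ.max() == occ.min():
        return None
    thr = float(np.quantile(occ, 1.0 - top_fraction, method="higher"))
    if thr <= 0:
        thr = float(occ[occ > 0].min())
    return thr


def merge_islands(
    track: OccurrenceTrack,
    threshold: float | None,
    min_island_snps: int = 2,
    bridge_bp: int | None = None,
) -> list[IslandRegion]:
    """Merge adjacent above-threshold SNPs into islands.

    A run is a maximal stretch of consecutively indexed retained SNPs on one
    chromosome (no intervening non-retained SNP); runs with fewer than
    ``min_island_snps`` SNPs are dropped. When ``bridge_bp`` is set, two runs
    on the same chromosome separated by at most that many bp are merged
    despite intervening non-retained SNPs (off by default).
    """
    if threshold is None:
        return []
    retained = np.flatnonzero(track.occurrence >= threshold)
    if retained.size == 0:
        return []
    runs: list[list[int]] = [[int(retained[0])]]
    for i in retained[1:]:
        i = int(i)
        prev = runs[-1][-1]
        same_chrom = track.chrom[i] == track.chrom[prev]
        adjacent = i == prev + 1
        bridged = (
            bridge_bp is not None
            and same_chrom
            and track.pos[i] - track.pos[prev] <= bridge_bp
        )
        if same_chrom and (adjacent or bridged):
            runs[-1].append(i)
        else:
            runs.append([i])
    islands = [
        IslandRegion(
            chrom=str(track.chrom[run[0]]),
            start_pos=int(track.pos[run[0]]),
            end_pos=int(track.pos[run[-1]]),
            n_snps=len(run),
        )
        for run in runs
        if len(run) >= min_island_snps
    ]
    logger.info(
        "group %s: threshold %.4f, %d retained SNPs, %d islands",
        track.group, threshold, retained.size, len(islands),
    )
    return islands


def find_islands(
    segments: Sequence[ROHSegment],
    gm: GenotypeMatrix,
    metadata: pd.DataFrame,
    group: str,
    top_fraction: float = 0.005,
    min_island_snps: int = 2,
    bridge_bp: int | None = None,
) -> tuple[OccurrenceTrack, float | None, list[IslandRegion]]:
    """Occurrence track, threshold, and merged islands for one group."""
    track = snp_occurrence(segments, gm, metadata, group)
    thr = island_threshold(track, top_fraction)
    return track, thr, merge_islands(track, thr, min_island_snps, bridge_bp)


def annotate_genes(
    islands: Sequence[IslandRegion], gtf_path: str | Path
) -> list[IslandRegion]:
    """Attach overlapping gene ids to each island (>= 1 bp overlap, strand
    ignored). Accepts GTF or GFF3; explicit ``gene`` features are read with
    gffutils (annotations that only list exons/transcripts are not inferred).

    Returns the same island objects with ``gene_ids`` filled in, sorted by
    genomic position of the gene.
    """
    import gffutils
    from intervaltree import IntervalTree

    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise FileNotFoundError(f"annotation file not found: {gtf_path}")
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    trees: dict[str, IntervalTree] = {}
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("gene_id", [gene.id])[0]
        # IntervalTree is half-open; gene coords are 1-based inclusive
        trees.setdefault(gene.seqid, IntervalTree()).addi(
            gene.start, gene.end + 1, name
        )
    for isl in islands:
        tree = trees.get(isl.chrom)
        if tree is None:
            isl.gene_ids = []
            continue
        hits = tree.overlap(isl.start_pos, isl.end_pos + 1)
        isl.gene_ids = sorted({h.data for h in hits}, key=lambda g: str(g))
    return list(islands)


def islands_to_frame(islands: Sequence[IslandRegion]) -> pd.DataFrame:
    """Tabulate islands (chrom, n_snps, start, end, n_genes, gene_ids)."""
    return pd.DataFrame(
        [
            {
                "chrom": i.chrom,
                "n_snps": i.n_snps,
                "start_bp": i.start_pos,
                "end_bp": i.end_pos,
                "n_genes": len(i.gene_ids),
                "gene_ids": ",".join(i.gene_ids),
            }
            for i in islands
        ],
        columns=["chrom", "n_snps", "start_bp", "end_bp", "n_genes", "gene_ids"],
    )
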