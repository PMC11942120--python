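"""Per-individual, per-breed, per-chromosome ROH summaries and the
ROH-length <-> generations-since-common-ancestor mapping.

ROH are binned into four length classes — 0.5–1.0, 1.0–1.5, 1.5–2.0 and
>2.0 Mb — with half-open boundaries [a, b), so a segment of exactly 1.0 Mb
falls in the 1.0–1.5 Mb class. Under a uniform 1 cM/Mb map the expected
length of an autozygous segment that coalesces g generations ago is
1/(2g) Morgans, so longer classes correspond to more recent inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rohkit.roh_detect import ROHSegment

#: class lower edges in Mb; the last class is unbounded above
LENGTH_CLASS_EDGES_MB: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
LENGTH_CLASS_LABELS: tuple[str, ...] = (
    "0.5-1.0Mb", "1.0-1.5Mb", "1.5-2.0Mb", ">2.0Mb",
)


def length_class(length_mb: float) -> str:
    """Length class label for one segment ([a, b) boundaries)."""
    edges = LENGTH_CLASS_EDGES_MB
    if length_mb < edges[0]:
        raise ValueError(f"segment of {length_mb} Mb is below the minimum class edge")
    for lo, hi, label in zip(edges[:-1], edges[1:], LENGTH_CLASS_LABELS[:-1]):
        if lo <= length_mb < hi:
            return label
    return LENGTH_CLASS_LABELS[-1]


@dataclass
class IndividualROHSummary:
    sample_id: str
    total_n_roh: int
    total_length_mb: float
    class_counts: dict[str, int] = field(default_factory=dict)
    class_length_mb: dict[str, float] = field(default_factory=dict)
    chrom_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class BreedSummary:
    group: str
    n_individuals: int
    mn_roh: float  # mean ROH count per individual
    al_roh: float  # mean length per ROH segment (Mb)
    mean_total_length_mb: float
    mean_class_sum_mb: dict[str, float] = field(default_factory=dict)
    chrom_counts: dict[str, int] = field(default_factory=dict)


def summarize_individual(
    segments: Sequence[ROHSegment], sample: str
) -> IndividualROHSummary:
    """Totals and per-length-class decomposition of one individual's ROH.

    Class sums add exactly to the total length and class counts to the
    total count (conservation).
    """
    own = [s for s in segments if s.sample_id == sample]
    class_counts = {lab: 0 for lab in LENGTH_CLASS_LABELS}
    class_len = {lab: 0.0 for lab in LENGTH_CLASS_LABELS}
    chrom_counts: dict[str, int] = {}
    total = 0.0
    for s in own:
        lab = length_class(s.length_mb)
        class_counts[lab] += 1
        class_len[lab] += s.length_mb
        chrom_counts[s.chrom] = chrom_counts.get(s.chrom, 0) + 1
        total += s.length_mb
    return IndividualROHSummary(
        sample_id=sample,
        total_n_roh=len(own),
        total_length_mb=total,
        class_counts=class_counts,
        class_length_mb=class_len,
        chrom_counts=chrom_counts,
    )


def summarize_breed(
    summaries: Sequence[IndividualROHSummary],
    metadata: pd.DataFrame,
    group: str,
) -> BreedSummary:
    """Breed-level means: MN_ROH (mean segment count per individual),
    AL_ROH (mean length per segment, Mb), and per-class mean sums computed
    by summing all segments in a class over the group and dividing by the
    group sample size."""
    ids = set(metadata.loc[metadata["group"] == group, "sample_id"])
    if not ids:
        raise KeyError(f"unknown group: {group!r}")
    members = [s for s in summaries if s.sample_id in ids]
    if not members:
        raise ValueError(f"no summaries supplied for group {group!r}")
    n = len(members)
    total_count = sum(s.total_n_roh for s in members)
    total_len = sum(s.total_length_mb for s in members)
    chrom_counts: dict[str, int] = {}
    for s in members:
        for chrom, c in s.chrom_counts.items():
            chrom_counts[chrom] = chrom_counts.get(chrom, 0) + c
    return BreedSummary(
        group=group,
        n_individuals=n,
        mn_roh=total_count / n,
        al_roh=(total_len / total_count) if total_count else 0.0,
        mean_total_length_mb=total_len / n,
        mean_class_sum_mb={
            lab: sum(s.class_length_mb[lab] for s in members) / n
            for lab in LENGTH_CLASS_LABELS
        },
        chrom_counts=chrom_counts,
    )


def generations_from_length(length_mb: float, cm_per_mb: float = 1.0) -> float:
    """Generations since the common ancestor for an expected ROH length.

    With segment lengths exponential of mean 1/(2g) Morgans, a length of
    L Morgans corresponds to g = 1/(2L); at 1 cM/Mb, 0.5 Mb -> 100
    generations, 1.0 Mb -> 50, 2.0 Mb -> 25.
    """
    if length_mb <= 0:
        raise ValueError("length must be positive")
    morgans = length_mb * cm_per_mb / 100.0
    return 1.0 / (2.0 * morgans)


def length_from_generations(g: float, cm_per_mb: float = 1.0) -> float:
    """Inverse of :func:`generations_from_length` (expected length, Mb)."""
    if g <= 0:
        raise ValueError("generations must be positive")
    morgans = 1.0 / (2.0 * g)
    return morgans * 100.0 / cm_per_mb


def chromosome_roh_fraction(
    segments: Sequence[ROHSegment], contig_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-chromosome ROH count, summed length and percent of chromosome size."""
    rows = []
    for chrom, length in contig_lengths.items():
        segs = [s for s in segments if s.chrom == chrom]
        total_bp = sum(s.length_bp for s in segs)
        rows.append(
            {
                "chrom": chrom,
                "n_roh": len(segs),
                "roh_length_bp": total_bp,
                "pct_of_chrom": 100.0 * total_bp / length if length else np.nan,
            }
        )
    return pd.DataFrame(rows)


def individual_summary_frame(summaries: Sequence[IndividualROHSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "sample_id": s.sample_id,
            "total_n_roh": s.total_n_roh,
            "total_length_mb": s.total_length_mb,
        }
        for lab in LENGTH_CLASS_LABELS:
            row[f"n_{lab}"] = s.class_counts.get(lab, 0)
            row[f"mb_{lab}"] = s.class_length_mb.get(lab, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
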