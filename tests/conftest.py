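"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohkit.genotype_io import GenotypeMatrix


def make_gm(
    chrom_data: dict[str, tuple[np.ndarray, np.ndarray]],
    samples: list[str] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {chrom: (positions, calls sites x samples)}."""
    frames, blocks = [], []
    n_samples = None
    for chrom, (pos, calls) in chrom_data.items():
        pos = np.asarray(pos)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim == 1:
            calls = calls[:, None]
        n_samples = calls.shape[1]
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G", "id": None}
            )
        )
        blocks.append(calls)
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(
        sites=pd.concat(frames, ignore_index=True),
        samples=samples,
        calls=np.vstack(blocks),
        chrom_order=list(chrom_data),
        contig_lengths=contig_lengths or {},
    )


def make_single_sample_gm(pos, calls, chrom: str = "chr1") -> GenotypeMatrix:
    return make_gm({chrom: (np.asarray(pos), np.asarray(calls, dtype=np.int8))})


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
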