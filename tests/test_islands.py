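"""ROH island discovery: occurrence track, threshold, merging, annotation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohkit.islands import (
    OccurrenceTrack,
    island_threshold,
    merge_islands,
    snp_occurrence,
)
from rohkit.roh_detect import ROHSegment

from conftest import make_gm


def _gm(n_snps=100, n_samples=20, spacing=10_000):
    pos = (np.arange(n_snps) + 1) * spacing
    calls = np.zeros((n_snps, n_samples), dtype=np.int8)
    return make_gm({"chr1": (pos, calls)},
                   samples=[f"i{k}" for k in range(n_samples)])


def _meta(gm, group="g"):
    return pd.DataFrame({"sample_id": gm.samples, "group": group})


def _track(occ, chrom=None, pos=None, n=20):
    occ = np.asarray(occ, dtype=float)
    return OccurrenceTrack(
        group="g",
        n=n,
        chrom=np.asarray(chrom if chrom is not None else ["chr1"] * occ.size),
        pos=np.asarray(pos if pos is not None else (np.arange(occ.size) + 1) * 1000),
        occurrence=occ,
    )


class TestOccurrence:
    def test_counts_covering_individuals(self):
        gm = _gm()
        # SNP at 500_000 covered by ROH in 13 of 20 individuals
        segs = [ROHSegment(f"i{k}", "chr1", 400_000, 600_000, 100) for k in range(13)]
        track = snp_occurrence(segs, gm, _meta(gm), "g")
        i = np.flatnonzero(track.pos == 500_000)[0]
        assert track.occurrence[i] == pytest.approx(0.65)
        assert track.occurrence[0] == 0.0

    def test_full_coverage_and_empty(self):
        gm = _gm()
        segs = [ROHSegment(f"i{k}", "chr1", 1, 10**7, 100) for k in range(20)]
        track = snp_occurrence(segs, gm, _meta(gm), "g")
        assert np.all(track.occurrence == 1.0)
        assert np.all(snp_occurrence([], gm, _meta(gm), "g").occurrence == 0.0)

    def test_multiple_segments_per_individual_count_once(self):
        gm = _gm()
        segs = [
            ROHSegment("i0", "chr1", 400_000, 600_000, 50),
            ROHSegment("i0", "chr1", 450_000, 550_000, 30),  # nested
        ]
        track = snp_occurrence(segs, gm, _meta(gm), "g")
        assert track.occurrence.max() == pytest.approx(1 / 20)

    def test_duplicating_every_individual_leaves_track_unchanged(self):
        gm = _gm(n_samples=5)
        segs = [ROHSegment("i0", "chr1", 100_000, 300_000, 50),
                ROHSegment("i3", "chr1", 200_000, 400_000, 50)]
        t1 = snp_occurrence(segs, gm, _meta(gm), "g")
        dup = make_gm(
            {"chr1": ((np.arange(100) + 1) * 10_000,
                      np.zeros((100, 10), dtype=np.int8))},
            samples=[f"i{k}" for k in range(5)] + [f"j{k}" for k in range(5)],
        )
        dup_segs = segs + [
            ROHSegment(s.sample_id.replace("i", "j"), s.chrom, s.start_pos,
                       s.end_pos, s.n_snps)
            for s in segs
        ]
        t2 = snp_occurrence(dup_segs, dup, _meta(dup), "g")
        assert np.allclose(t1.occurrence, t2.occurrence)

    def test_unknown_group(self):
        gm = _gm()
        with pytest.raises(KeyError):
            snp_occurrence([], gm, _meta(gm), "nope")


class TestThreshold:
    def test_distinct_values_top_half_percent(self, rng):
        occ = rng.permutation(np.arange(1000)) / 1000.0  # all distinct
        track = _track(occ, n=1000)
        thr = island_threshold(track, 0.005)
        retained = occ[occ >= thr]
        assert sorted(retained) == sorted(np.sort(occ)[-5:])  # the 5 largest

    def test_retained_count_lower_bound(self, rng):
        for _ in range(10):
            occ = rng.integers(0, 21, size=int(rng.integers(300, 2000))) / 20.0
            if occ.max() == occ.min():
                continue
            thr = island_threshold(_track(occ), 0.005)
            assert np.sum(occ >= thr) >= int(np.ceil(0.005 * occ.size))

    def test_constant_track_sentinel(self):
        assert island_threshold(_track(np.zeros(100))) is None
        assert island_threshold(_track(np.full(100, 0.4))) is None

    def test_single_hot_snp(self):
        occ = np.zeros(1000)
        occ[137] = 1.0
        thr = island_threshold(_track(occ))
        assert np.flatnonzero(occ >= thr).tolist() == [137]


class TestMerge:
    def test_enumeration_example(self):
        occ = np.zeros(50)
        occ[[10, 11, 12, 40]] = 0.9
        islands = merge_islands(_track(occ), threshold=0.9, min_island_snps=2)
        assert len(islands) == 1  # singleton at 40 dropped
        (isl,) = islands
        assert isl.n_snps == 3
        assert (isl.start_pos, isl.end_pos) == (11 * 1000, 13 * 1000)

    def test_sentinel_and_empty(self):
        assert merge_islands(_track(np.zeros(10)), None) == []
        assert merge_islands(_track(np.zeros(10)), threshold=0.5) == []

    def test_all_retained_single_island_per_chrom(self):
        chrom = ["chr1"] * 30 + ["chr2"] * 20
        occ = np.full(50, 0.8)
        occ[0] = 0.81  # avoid the constant-track degenerate case upstream
        islands = merge_islands(_track(occ, chrom=chrom), threshold=0.5)
        assert [(i.chrom, i.n_snps) for i in islands] == [("chr1", 30), ("chr2", 20)]

    def test_conservation_of_retained_snps(self, rng):
        occ = rng.choice([0.0, 0.2, 0.9], size=300, p=[0.7, 0.2, 0.1])
        track = _track(occ)
        thr = 0.9
        islands = merge_islands(track, thr, min_island_snps=2)
        retained = np.flatnonzero(occ >= thr)
        in_islands = sum(i.n_snps for i in islands)
        # dropped SNPs are exactly those in runs shorter than min_island_snps
        runs = np.split(retained, np.flatnonzero(np.diff(retained) > 1) + 1)
        dropped = sum(len(r) for r in runs if len(r) < 2)
        assert in_islands + dropped == retained.size

    def test_bridge_option_merges_across_gap(self):
        occ = np.zeros(30)
        occ[[5, 6, 10, 11]] = 0.9
        strict = merge_islands(_track(occ), 0.9)
        bridged = merge_islands(_track(occ), 0.9, bridge_bp=10_000)
        assert len(strict) == 2 and len(bridged) == 1


TOY_GTF = """\
chr1\ttest\tgene\t1000\t5000\t.\t+\t.\tgene_id "GENE_A";
chr1\ttest\tgene\t8000\t12000\t.\t-\t.\tgene_id "GENE_B";
chr1\ttest\tgene\t50000\t60000\t.\t+\t.\tgene_id "GENE_C";
chr2\ttest\tgene\t100\t200\t.\t+\t.\tgene_id "GENE_D";
"""


class TestAnnotate:
    @pytest.fixture
    def gtf(self, tmp_path):
        p = tmp_path / "toy.gtf"
        p.write_text(TOY_GTF)
        return p

    def test_overlap_assignment(self, gtf):
        from rohkit.islands import IslandRegion, annotate_genes

        islands = [
            IslandRegion("chr1", 4000, 9000, 10),  # spans GENE_A and GENE_B
            IslandRegion("chr1", 20000, 30000, 5),  # no genes
            IslandRegion("chr3", 1, 100, 2),  # chromosome absent from GTF
        ]
        out = annotate_genes(islands, gtf)
        assert out[0].gene_ids == ["GENE_A", "GENE_B"]
        assert out[1].gene_ids == []
        assert out[2].gene_ids == []

    def test_boundary_conventions(self, gtf):
        from rohkit.islands import IslandRegion, annotate_genes

        touching = annotate_genes([IslandRegion("chr1", 5000, 6000, 3)], gtf)
        assert touching[0].gene_ids == ["GENE_A"]  # 1-bp overlap counts
        apart = annotate_genes([IslandRegion("chr1", 5001, 6000, 3)], gtf)
        assert apart[0].gene_ids == []  # gene ends at island start - 1

    def test_missing_file(self):
        from rohkit.islands import IslandRegion, annotate_genes

        with pytest.raises(FileNotFoundError):
            annotate_genes([IslandRegion("chr1", 1, 2, 2)], "/nonexistent.gtf")
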