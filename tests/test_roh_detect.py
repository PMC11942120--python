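"""Sliding-window ROH detection against its brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

from rohkit.genotype_io import HET, HOM_ALT, HOM_REF, MISSING
from rohkit.roh_detect import ROHParams, brute_force_roh, call_roh, window_scan

from conftest import make_gm, make_single_sample_gm


def even_positions(n: int, span_bp: int, start: int = 1) -> np.ndarray:
    return np.linspace(start, start + span_bp - 1, n).round().astype(int)


def test_window_scan_all_homozygous_is_one():
    gm = make_single_sample_gm(even_positions(200, 1_000_000), np.zeros(200))
    frac = window_scan(gm, "s1")
    assert np.all(frac == 1.0)


def test_window_scan_zero_inside_het_block():
    calls = np.zeros(200, dtype=np.int8)
    calls[70:130] = HET  # 60 consecutive heterozygotes
    gm = make_single_sample_gm(even_positions(200, 1_000_000), calls)
    frac = window_scan(gm, "s1")
    # central het SNPs: every covering 50-SNP window holds > 2 hets
    assert np.all(frac[95:105] == 0.0)
    assert frac[0] == 1.0 and frac[-1] == 1.0


def test_window_scan_matches_direct_enumeration(rng):
    params = ROHParams(window_snps=20, max_het_per_window=2, max_missing_per_window=3)
    calls = rng.choice(
        np.array([HOM_REF, HET, HOM_ALT, MISSING], dtype=np.int8),
        p=[0.5, 0.3, 0.15, 0.05], size=500,
    )
    pos = np.sort(rng.choice(np.arange(1, 3_000_000), 500, replace=False))
    gm = make_single_sample_gm(pos, calls)
    frac = window_scan(gm, "s1", params)

    w = params.window_snps
    for i in range(500):  # direct O(n*w) enumeration
        hits, total = 0, 0
        for s in range(max(0, i - w + 1), min(i, 500 - w) + 1):
            chunk = calls[s:s + w]
            total += 1
            if (np.sum(chunk == HET) <= 2) and (np.sum(chunk == MISSING) <= 3):
                hits += 1
        assert frac[i] == pytest.approx(hits / total)


def test_window_scan_unknown_sample():
    gm = make_single_sample_gm([100, 200], [0, 0])
    with pytest.raises(KeyError):
        window_scan(gm, "nobody")


def test_truncated_window_on_short_chromosome():
    # fewer SNPs than the window: one truncated window scores the chromosome
    gm = make_single_sample_gm(even_positions(30, 100_000), np.zeros(30))
    assert np.all(window_scan(gm, "s1") == 1.0)
    calls = np.zeros(30, dtype=np.int8)
    calls[10:13] = HET  # 3 hets > allowance of 2
    gm = make_single_sample_gm(even_positions(30, 100_000), calls)
    assert np.all(window_scan(gm, "s1") == 0.0)


class TestCallROHRules:
    def test_single_clean_run(self):
        gm = make_single_sample_gm(even_positions(200, 1_000_000), np.zeros(200))
        segs = call_roh(gm)
        assert len(segs) == 1
        (s,) = segs
        assert s.n_snps == 200
        assert s.length_bp == pytest.approx(1_000_000, rel=0.01)

    def test_min_snp_count_rule(self):
        gm = make_single_sample_gm(even_positions(99, 600_000), np.zeros(99))
        assert call_roh(gm) == []

    def test_min_length_rule(self):
        gm = make_single_sample_gm(even_positions(150, 400_000), np.zeros(150))
        assert call_roh(gm) == []

    def test_gap_splits_run(self):
        # 300 hom SNPs over 1.5 Mb of SNP span with a 1.2-Mb internal gap
        left = even_positions(150, 750_000)
        right = even_positions(150, 750_000, start=750_000 + 1_200_000)
        gm = make_single_sample_gm(np.concatenate([left, right]), np.zeros(300))
        segs = call_roh(gm)
        assert len(segs) == 2
        assert segs[0].n_snps == segs[1].n_snps == 150

    def test_gap_exactly_at_limit_not_split(self):
        left = even_positions(150, 750_000)
        right = even_positions(150, 750_000, start=750_000 + 1_000_000)
        gm = make_single_sample_gm(np.concatenate([left, right]), np.zeros(300))
        assert len(call_roh(gm)) == 1  # inclusive allowance: split only on ">"

    def test_density_rule(self):
        # 100 SNPs over 6 Mb: 60 kb/SNP exceeds the 50 kb/SNP cap
        gm = make_single_sample_gm(even_positions(100, 6_000_000), np.zeros(100))
        assert call_roh(gm) == []

    def test_empty_matrix(self):
        gm = make_single_sample_gm(even_positions(10, 10_000), np.zeros(10))
        empty = gm.subset_sites(np.zeros(10, dtype=bool))
        assert call_roh(empty) == []


def random_instance(rng, max_snps=1000):
    """Random genotypes with planted homozygous runs and het/missing noise."""
    n = int(rng.integers(50, max_snps + 1))
    n_chrom = int(rng.integers(1, 3))
    sizes = np.diff(np.sort(np.r_[0, rng.choice(np.arange(1, n), n_chrom - 1, replace=False), n]))
    data = {}
    for ci, m in enumerate(sizes):
        m = int(m)
        if m == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, 5_000_000), m, replace=False))
        calls = rng.choice(
            np.array([HOM_REF, HET, HOM_ALT], dtype=np.int8), p=[0.4, 0.4, 0.2], size=m
        )
        for _ in range(int(rng.integers(0, 4))):  # planted runs
            a = int(rng.integers(0, m))
            b = min(m, a + int(rng.integers(20, 400)))
            calls[a:b] = rng.choice(np.array([HOM_REF, HOM_ALT], dtype=np.int8), size=b - a)
        noise = rng.random(m)
        calls[noise < 0.02] = HET
        calls[(noise >= 0.02) & (noise < 0.04)] = MISSING
        data[f"chr{ci + 1}"] = (pos, calls)
    params = ROHParams(
        window_snps=int(rng.integers(5, 51)),
        max_het_per_window=int(rng.integers(0, 3)),
        max_missing_per_window=int(rng.integers(0, 6)),
        min_snps=int(rng.integers(10, 80)),
        min_length_kb=float(rng.integers(50, 500)),
        max_density_kb_per_snp=float(rng.integers(10, 100)),
        max_gap_kb=float(rng.integers(100, 1000)),
        hit_proportion=0.05,
    )
    return make_gm(data), params


@pytest.mark.parametrize("seed", range(25))
def test_oracle_equivalence_random_instances(seed):
    """call_roh must equal the brute-force enumeration segment-for-segment."""
    rng = np.random.default_rng(1_000 + seed)
    gm, params = random_instance(rng)
    assert call_roh(gm, params) == brute_force_roh(gm, "s1", params)


def test_brute_force_refuses_large_input(rng):
    gm = make_single_sample_gm(np.arange(1, 6002) * 100, np.zeros(6001))
    with pytest.raises(ValueError, match="refuses"):
        brute_force_roh(gm, "s1")


def test_segments_never_border_het_or_missing(rng):
    for seed in range(10):
        r = np.random.default_rng(seed)
        gm, params = random_instance(r, max_snps=600)
        col = gm.calls[:, 0]
        pos = gm.sites["pos"].to_numpy()
        chrom = gm.sites["chrom"].to_numpy()
        for s in call_roh(gm, params):
            i0 = np.flatnonzero((chrom == s.chrom) & (pos == s.start_pos))[0]
            i1 = np.flatnonzero((chrom == s.chrom) & (pos == s.end_pos))[0]
            assert col[i0] in (HOM_REF, HOM_ALT)
            assert col[i1] in (HOM_REF, HOM_ALT)


def test_monotonicity_in_thresholds(rng):
    gm, _ = random_instance(rng, max_snps=800)
    base = ROHParams(window_snps=20, min_snps=40, min_length_kb=200)
    loose_snps = ROHParams(window_snps=20, min_snps=20, min_length_kb=200)
    loose_len = ROHParams(window_snps=20, min_snps=40, min_length_kb=100)
    n_base = len(call_roh(gm, base))
    assert len(call_roh(gm, loose_snps)) >= n_base
    assert len(call_roh(gm, loose_len)) >= n_base
    more_het = ROHParams(window_snps=20, min_snps=40, min_length_kb=200,
                         max_het_per_window=4)
    total = lambda segs: sum(s.length_bp for s in segs)  # noqa: E731
    assert total(call_roh(gm, more_het)) >= total(call_roh(gm, base))


def test_determinism(rng):
    gm, params = random_instance(rng)
    assert call_roh(gm, params) == call_roh(gm, params)
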