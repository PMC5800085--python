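"""Verdict logic and the weighted Welch expansion scan."""
import numpy as np
import pandas as pd
import pytest

from dmrwwe import (DMRCriteria, GroupedCounts, call_dmrs, parameter_sweep,
                    region_test, site_p_value, site_verdict)
from dmrwwe.caller import EmptyRegionError

from conftest import make_grouped, random_grouped
from _oracles import site_qualifies_reference, wwe_scan_reference


def block_data(n=14, block=(3, 10), coverage=30, r=3, spacing=100):
    """Sites with a strongly differential block flanked by null sites."""
    pos = 100 + spacing * np.arange(n)
    cov = np.full((n, r), coverage)
    frac_a = np.full(n, 0.5)
    frac_b = np.full(n, 0.5)
    s, e = block
    frac_a[s:e + 1] = 0.1
    frac_b[s:e + 1] = 0.9
    meth_a = np.round(cov * frac_a[:, None]).astype(int)
    meth_b = np.round(cov * frac_b[:, None]).astype(int)
    return make_grouped(pos, meth_a, cov, meth_b, cov)


class TestSiteVerdict:
    def test_low_coverage_fails_regardless(self):
        v = site_verdict([1, 1, 1], [9, 30, 30], [25, 25, 25], [30, 30, 30],
                         DMRCriteria(min_coverage=10))
        assert not v.qualifies and "coverage" in v.failed_criteria

    def test_equal_means_fail_diff(self):
        v = site_verdict([15, 15], [30, 30], [15, 15], [30, 30],
                         DMRCriteria(min_coverage=10, min_diff=1))
        assert "diff" in v.failed_criteria

    def test_strong_separation_qualifies(self):
        v = site_verdict([3, 3, 3], [30, 30, 30], [27, 27, 27], [30, 30, 30],
                         DMRCriteria())
        assert v.qualifies and v.failed_criteria == frozenset()
        assert v.diff == pytest.approx(0.8)


class TestCallDmrs:
    def test_no_coverage_no_dmrs(self):
        data = block_data(coverage=5)
        assert call_dmrs(data, DMRCriteria(min_coverage=10)) == []

    def test_single_block_recovered(self):
        data = block_data(n=14, block=(3, 10))
        dmrs = call_dmrs(data, DMRCriteria(min_cpn=5))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end) == (int(data.pos[3]), int(data.pos[10]))
        assert d.n_cpn == 8
        assert d.direction == "hyper"

    def test_interior_similar_sites_tolerated(self):
        data = block_data(n=14, block=(3, 10))
        # null out two interior sites of the block
        data.meth_a[6:8] = (data.cov_a[6:8] * 0.5).astype(int)
        data.meth_b[6:8] = (data.cov_b[6:8] * 0.5).astype(int)
        dmrs = call_dmrs(data, DMRCriteria(min_cpn=5, max_similar=5))
        assert len(dmrs) == 1
        assert (dmrs[0].start, dmrs[0].end) == (int(data.pos[3]), int(data.pos[10]))
        assert dmrs[0].n_cpn == 6

    def test_zero_similar_splits_block(self):
        data = block_data(n=14, block=(3, 10))
        data.meth_a[6] = int(data.cov_a[6, 0] * 0.5)
        data.meth_b[6] = int(data.cov_b[6, 0] * 0.5)
        strict = call_dmrs(data, DMRCriteria(min_cpn=3, max_similar=0))
        assert [(d.start, d.end) for d in strict] == \
            [(int(data.pos[3]), int(data.pos[5])),
             (int(data.pos[7]), int(data.pos[10]))]
        # with min_cpn 5 both halves are too short
        assert call_dmrs(data, DMRCriteria(min_cpn=5, max_similar=0)) == []

    def test_gap_terminates_region(self):
        data = block_data(n=14, block=(3, 10))
        data.pos[7:] += 30_000
        dmrs = call_dmrs(data, DMRCriteria(min_cpn=4, max_gap=20_000))
        assert [(d.start, d.end) for d in dmrs] == \
            [(int(data.pos[3]), int(data.pos[6])),
             (int(data.pos[7]), int(data.pos[10]))]

    def test_opposite_direction_seeds_new_region(self):
        n, r = 12, 3
        pos = 100 + 50 * np.arange(n)
        cov = np.full((n, r), 30)
        fa = np.concatenate([np.full(6, 0.1), np.full(6, 0.9)])
        fb = 1.0 - fa
        data = make_grouped(pos, np.round(cov * fa[:, None]).astype(int), cov,
                            np.round(cov * fb[:, None]).astype(int), cov)
        dmrs = call_dmrs(data, DMRCriteria(min_cpn=5))
        assert [d.direction for d in dmrs] == ["hyper", "hypo"]
        assert [(d.start, d.end) for d in dmrs] == \
            [(int(pos[0]), int(pos[5])), (int(pos[6]), int(pos[11]))]

    def test_shrink_back_makes_boundaries_qualify(self):
        data = block_data(n=16, block=(3, 8))
        dmrs = call_dmrs(data, DMRCriteria(min_cpn=4))
        assert len(dmrs) == 1
        # trailing similar sites (9..15) are shrunk away
        assert dmrs[0].end == int(data.pos[8])

    def test_min_span_filters_short_regions(self):
        data = block_data(n=14, block=(3, 10), spacing=10)
        assert call_dmrs(data, DMRCriteria(min_cpn=5, min_span=500)) == []
        assert len(call_dmrs(data, DMRCriteria(min_cpn=5, min_span=50))) == 1

    def test_determinism(self):
        rng = np.random.default_rng(0)
        data = random_grouped(rng, n_sites=120, block=(40, 60))
        a = call_dmrs(data, DMRCriteria(min_cpn=3))
        b = call_dmrs(data, DMRCriteria(min_cpn=3))
        assert a == b

    def test_emitted_regions_sorted_nonoverlapping_valid(self):
        rng = np.random.default_rng(14)
        crit = DMRCriteria(min_cpn=2, min_diff=5, max_p=0.3)
        for _ in range(20):
            data = random_grouped(rng, n_sites=150,
                                  block=(30, 45), cov_low=5)
            dmrs = call_dmrs(data, crit)
            for d1, d2 in zip(dmrs, dmrs[1:]):
                if d1.chrom == d2.chrom:
                    assert d1.end < d2.start
            for d in dmrs:
                assert d.n_cpn >= crit.min_cpn
                assert d.span >= crit.min_span
                assert 0.0 <= d.p <= 1.0 and d.p <= d.q <= 1.0

    def test_monotone_in_criteria(self):
        rng = np.random.default_rng(23)
        data = random_grouped(rng, n_sites=200, block=(50, 80), cov_low=5)
        base = DMRCriteria(min_cpn=2, min_diff=5, max_p=0.2)
        n0 = len(call_dmrs(data, base))
        assert len(call_dmrs(data, base.replace(min_cpn=4))) <= n0
        assert len(call_dmrs(data, base.replace(min_diff=15))) <= n0
        assert len(call_dmrs(data, base.replace(max_p=0.01))) <= n0
        assert len(call_dmrs(data, base.replace(min_coverage=20))) <= n0


def random_criteria(rng):
    return DMRCriteria(
        min_coverage=int(rng.choice([0, 5, 10, 20])),
        min_diff=float(rng.choice([0.0, 5.0, 10.0, 25.0])),
        max_p=float(rng.choice([0.01, 0.05, 0.2, 1.0])),
        min_cpn=int(rng.choice([1, 2, 3, 5])),
        min_span=int(rng.choice([0, 0, 100])),
        max_gap=int(rng.choice([100, 500, 20_000])),
        max_similar=int(rng.choice([0, 1, 2, 5])),
    )


def oracle_call(data, crit):
    """Fully independent re-derivation: scalar verdicts + naive scan."""
    out = []
    for chrom in pd.unique(data.chrom):
        idx = np.flatnonzero(data.chrom == chrom)
        qual = np.zeros(len(idx), dtype=bool)
        sign = np.zeros(len(idx), dtype=int)
        for k, i in enumerate(idx):
            qual[k], sign[k] = site_qualifies_reference(
                data.meth_a[i], data.cov_a[i],
                data.meth_b[i], data.cov_b[i], crit)
        for f, l, n_cpn in wwe_scan_reference(data.pos[idx], qual, sign, crit):
            out.append((chrom, int(data.pos[idx[f]]),
                        int(data.pos[idx[l]]), n_cpn))
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_bruteforce_scanner(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            r_a = int(rng.choice([1, 2, 3], p=[0.15, 0.35, 0.5]))
            r_b = int(rng.choice([1, 2, 3], p=[0.15, 0.35, 0.5]))
            data = random_grouped(rng, n_sites=int(rng.integers(5, 80)),
                                  r_a=r_a, r_b=r_b,
                                  block=(2, int(rng.integers(3, 20))),
                                  cov_low=3)
            crit = random_criteria(rng)
            got = [(d.chrom, d.start, d.end, d.n_cpn)
                   for d in call_dmrs(data, crit)]
            assert got == oracle_call(data, crit)


class TestRegionTest:
    def test_single_site_equals_site_test(self):
        data = block_data(n=5, block=(2, 2))
        i = 2
        _, _, _, p = region_test(data, "chr1", int(data.pos[i]), int(data.pos[i]))
        direct = site_p_value(data.meth_a[i], data.cov_a[i],
                              data.meth_b[i], data.cov_b[i])
        assert p == pytest.approx(direct.p, abs=1e-14)

    def test_identical_groups_p_one(self):
        pos = [100, 200, 300]
        m = [[5, 5], [6, 6], [7, 7]]
        c = [[10, 10], [12, 12], [14, 14]]
        data = make_grouped(pos, m, c, m, c)
        with pytest.warns(RuntimeWarning):
            _, _, diff, p = region_test(data, "chr1", 100, 300)
        assert p == 1.0 and diff == pytest.approx(0.0)

    def test_aggregation_matches_manual_sums(self):
        rng = np.random.default_rng(4)
        data = random_grouped(rng, n_sites=6, cov_low=3)
        mean_a, mean_b, diff, p = region_test(
            data, "chr1", int(data.pos[1]), int(data.pos[3]))
        ma = data.meth_a[1:4].sum(axis=0)
        ca = data.cov_a[1:4].sum(axis=0)
        mb = data.meth_b[1:4].sum(axis=0)
        cb = data.cov_b[1:4].sum(axis=0)
        assert mean_a == pytest.approx(ma.sum() / ca.sum())
        assert mean_b == pytest.approx(mb.sum() / cb.sum())
        assert p == pytest.approx(site_p_value(ma, ca, mb, cb).p, abs=1e-14)

    def test_empty_region_raises(self):
        data = block_data(n=5, block=(1, 3))
        with pytest.raises(EmptyRegionError):
            region_test(data, "chr9", 1, 10)


class TestParameterSweep:
    def test_single_combination_reduces_to_call(self):
        data = block_data()
        table = parameter_sweep(data, {"min_cpn": [5]})
        assert len(table) == 1
        assert table["n_dmrs"].iloc[0] == len(call_dmrs(data, DMRCriteria()))

    def test_empty_grid_defaults_row(self):
        data = block_data()
        table = parameter_sweep(data, {})
        assert len(table) == 1

    def test_min_cpn_monotone(self):
        rng = np.random.default_rng(77)
        data = random_grouped(rng, n_sites=150, block=(30, 60), cov_low=5)
        table = parameter_sweep(
            data, {"min_cpn": [1, 2, 4, 8]},
            criteria=DMRCriteria(min_diff=5, max_p=0.2))
        counts = table.sort_values("min_cpn")["n_dmrs"].to_numpy()
        assert (np.diff(counts) <= 0).all()

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            parameter_sweep(block_data(), {"window": [100]})
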