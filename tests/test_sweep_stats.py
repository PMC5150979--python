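"""Window statistics: Hp, ZHp, FST, di — hand values, identities, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan import (
    assign_snps,
    di_statistic,
    make_windows,
    pooled_heterozygosity,
    score_windows,
    snp_fst,
    window_allele_sums,
    window_fst,
    z_transform,
)

from conftest import make_table, random_table


class TestPooledHeterozygosity:
    @pytest.mark.parametrize(
        "nmaj,nmin,expected",
        [
            (10, 10, 0.5),  # symmetric maximum
            (40, 0, 0.0),  # no minor reads
            (30, 10, 0.375),  # 2*30*10/40^2 = 600/1600
        ],
    )
    def test_hand_values(self, nmaj, nmin, expected):
        assert pooled_heterozygosity(nmaj, nmin) == pytest.approx(expected, abs=1e-12)

    def test_undefined_when_empty(self):
        assert np.isnan(pooled_heterozygosity(0, 0))

    def test_negative_sums_rejected(self):
        with pytest.raises(ValueError):
            pooled_heterozygosity(-1, 5)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 10**6), st.integers(0, 10**6))
    def test_bounded_and_monotone_toward_balance(self, total, nmin):
        nmin = min(nmin, total // 2)
        nmaj = total - nmin
        hp = pooled_heterozygosity(nmaj, nmin)
        assert 0.0 <= hp <= 0.5
        if nmin + 1 <= nmaj - 1:  # push one read toward balance at fixed total
            assert pooled_heterozygosity(nmaj - 1, nmin + 1) > hp

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(1, 1000), st.integers(0, 1000), st.integers(2, 9))
    def test_scaling_read_counts_leaves_hp_unchanged(self, nmaj, nmin, k):
        assert pooled_heterozygosity(nmaj * k, nmin * k) == pytest.approx(
            pooled_heterozygosity(nmaj, nmin), abs=1e-12
        )


class TestZTransform:
    def test_three_point_example(self):
        # mu = 0.2, population sigma = sqrt(0.02/3) = 0.0816497
        z = z_transform([0.1, 0.2, 0.3])
        assert z == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_constant_vector_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            z_transform([0.3, 0.3, 0.3])

    def test_nan_entries_ignored_and_propagated(self):
        z = z_transform([0.1, np.nan, 0.2, 0.3])
        assert np.isnan(z[1])
        assert z[[0, 2, 3]] == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_output_standardized(self, rng):
        v = rng.uniform(0, 0.5, 200)
        z = z_transform(v)
        assert abs(z.mean()) < 1e-9 and abs(z.std(ddof=0) - 1) < 1e-9


class TestSnpFst:
    @pytest.mark.parametrize(
        "p1,p2,num,den",
        [
            (1.0, 0.0, 0.5, 0.5),  # fixed difference -> ratio 1
            (0.3, 0.3, 0.0, 0.42),  # identical pools -> 0
            (0.8, 0.2, 0.18, 0.5),  # HT=0.5, HS=0.32 -> ratio 0.36
        ],
    )
    def test_closed_forms(self, p1, p2, num, den):
        n, d = snp_fst(p1, p2)
        assert n == pytest.approx(num, abs=1e-12)
        assert d == pytest.approx(den, abs=1e-12)

    def test_frequency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            snp_fst(1.2, 0.5)

    def test_window_ratio_of_averages(self):
        # SNPs (0.8,0.2) and (0.6,0.4): (0.18+0.02)/(0.5+0.5) = 0.20
        n1, d1 = snp_fst(0.8, 0.2)
        n2, d2 = snp_fst(0.6, 0.4)
        assert window_fst([n1, n2], [d1, d2]) == pytest.approx(0.20, abs=1e-12)

    def test_single_snp_window_equals_snp_ratio(self):
        n, d = snp_fst(0.9, 0.1)
        assert window_fst([n], [d]) == pytest.approx(n / d, abs=1e-12)

    def test_uninformative_window_missing(self):
        n, d = snp_fst(0.0, 0.0)  # HT = 0
        assert np.isnan(window_fst([n], [d]))


class TestDiStatistic:
    def test_three_pool_hand_example(self):
        # focal A over 3 windows; pair sds are population sds
        fst = {
            ("A", "B"): np.array([0.1, 0.2, 0.3]),
            ("A", "C"): np.array([0.0, 0.1, 0.5]),
        }
        di, means, sds = di_statistic(fst, "A", np.ones(3, dtype=bool))
        assert di[2] == pytest.approx(2.613475, abs=1e-6)
        assert di[1] == pytest.approx((0.0 / 1) + (0.1 - 0.2) / sds[("A", "C")], abs=1e-9)

    def test_window_at_pair_means_has_zero_di(self):
        fst = {
            ("A", "B"): np.array([0.1, 0.2, 0.3]),
            ("A", "C"): np.array([0.0, 0.2, 0.4]),
        }
        di, _, _ = di_statistic(fst, "A", np.ones(3, dtype=bool))
        assert di[1] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_pair_named_in_error(self):
        fst = {
            ("A", "B"): np.array([0.1, 0.2, 0.3]),
            ("A", "C"): np.array([0.2, 0.2, 0.2]),
        }
        with pytest.raises(ValueError, match=r"\('A', 'C'\)"):
            di_statistic(fst, "A", np.ones(3, dtype=bool))


class TestWindowAlleleSums:
    def test_summation_and_per_pool_polarity(self, rng):
        t = make_table(
            [
                ("chr1", 10, "A", "C", [(8, 2)]),
                ("chr1", 20, "G", "T", [(5, 5)]),
                ("chr1", 900, "A", "G", [(3, 9)]),  # ref is minor here
            ],
            ["p0"],
        )
        frame = assign_snps(t, make_windows({"chr1": 1000}, ["chr1"], 500, 500))
        maj, mn = window_allele_sums(t, frame, "p0")
        assert (maj[0], mn[0]) == (13, 7)
        assert (maj[1], mn[1]) == (9, 3)

    def test_empty_window_zero(self, rng):
        t = random_table(rng, n_snps=5, n_pools=1)
        t.pos = np.arange(1, 6, dtype=np.int64)
        frame = assign_snps(t, make_windows({"chr1": 1000}, ["chr1"], 100, 100))
        maj, mn = window_allele_sums(t, frame, "p0")
        assert maj[5] == 0 and mn[5] == 0


class TestScoreWindows:
    def _scored(self, rng, n_pools=3):
        t = random_table(rng, n_snps=300, n_pools=n_pools)
        t.pos = np.sort(rng.choice(np.arange(1, 3001), 300, replace=False))
        frame = assign_snps(t, make_windows({"chr1": 3000}, ["chr1"], 500, 250))
        return t, frame, score_windows(t, frame, min_snps=5)

    def test_deterministic(self, rng):
        t, frame, s1 = self._scored(rng)
        s2 = score_windows(t, frame, min_snps=5)
        assert np.array_equal(s1.hp, s2.hp, equal_nan=True)
        assert np.array_equal(s1.zhp, s2.zhp, equal_nan=True)
        for k in s1.fst:
            assert np.array_equal(s1.fst[k], s2.fst[k], equal_nan=True)

    def test_zhp_standardization_identity(self, rng):
        _, _, s = self._scored(rng)
        for j in range(len(s.pool_names)):
            z = s.zhp[s.included, j]
            z = z[~np.isnan(z)]
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=0) - 1) < 1e-9

    def test_standardized_fst_series_identity(self, rng):
        _, _, s = self._scored(rng)
        for pair, series in s.fst.items():
            use = s.included & ~np.isnan(series)
            z = (series[use] - s.fst_mean[pair]) / s.fst_sd[pair]
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=0) - 1) < 1e-9

    def test_random_window_brute_force_recomputation(self, rng):
        t, frame, s = self._scored(rng)
        w = int(rng.integers(0, frame.n_windows))
        idx = frame.snp_indices[w]
        for j, pool in enumerate(s.pool_names):
            maj = int(t.maj_counts[idx, j].sum())
            mn = int(t.min_counts[idx, j].sum())
            assert s.sum_nmaj[w, j] == maj and s.sum_nmin[w, j] == mn
            if s.included[w] and maj + mn > 0:
                expect = 2 * maj * mn / (maj + mn) ** 2
                assert s.hp[w, j] == pytest.approx(expect, abs=1e-12)
        # brute-force one pair's window FST from raw counts
        a, b = sorted(s.pool_names)[:2]
        ia, ib = t.pool_index(a), t.pool_index(b)
        num = den = 0.0
        for i in idx:
            d1, d2 = t.depths[i, ia], t.depths[i, ib]
            if d1 == 0 or d2 == 0:
                continue
            p1 = t.alt_counts[i, ia] / d1
            p2 = t.alt_counts[i, ib] / d2
            pbar = (p1 + p2) / 2
            ht = 2 * pbar * (1 - pbar)
            if ht == 0:
                continue
            num += ht - (p1 * (1 - p1) + p2 * (1 - p2))
            den += ht
        if s.included[w] and den > 0:
            assert s.fst[(a, b)][w] == pytest.approx(num / den, abs=1e-12)

    def test_pool_order_permutation_consistency(self, rng):
        t = random_table(rng, n_snps=200, n_pools=3)
        t.pos = np.sort(rng.choice(np.arange(1, 2001), 200, replace=False))
        frame = assign_snps(t, make_windows({"chr1": 2000}, ["chr1"], 500, 250))
        s1 = score_windows(t, frame, pools=["p0", "p1", "p2"], min_snps=5)
        s2 = score_windows(t, frame, pools=["p2", "p0", "p1"], min_snps=5)
        for j, p in enumerate(s1.pool_names):
            k = s2.pool_names.index(p)
            assert np.array_equal(s1.hp[:, j], s2.hp[:, k], equal_nan=True)
            assert np.array_equal(s1.zhp[:, j], s2.zhp[:, k], equal_nan=True)
        for pair in s1.fst:
            assert np.array_equal(s1.fst[pair], s2.fst[pair], equal_nan=True)
        for p in s1.di:
            assert np.array_equal(s1.di[p], s2.di[p], equal_nan=True)

    def test_excluded_windows_carry_nan(self, rng):
        _, _, s = self._scored(rng)
        if (~s.included).any():
            assert np.isnan(s.hp[~s.included]).all()
            assert np.isnan(s.zhp[~s.included]).all()
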