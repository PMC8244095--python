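import numpy as np
import pandas as pd
import pytest
import scipy.stats

from pbapflow import stats as pst


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pst.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pst.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_textbook_five_point_example(self):
        # hand computation: x=[1,2,3,4,5], y=[2,1,4,3,7]
        # sum xy = 2+2+12+12+35 = 63; n*mean_x*mean_y = 5*3*3.4 = 51; Sxy = 12
        # Sxx = 10, Syy = 21.2 -> r = 12 / sqrt(212) = 0.824163...
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 7])
        expected = 12.0 / np.sqrt(10.0 * 21.2)
        assert pst.pearson_r(x, y) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        assert pst.pearson_r(x, y) == pytest.approx(scipy.stats.pearsonr(x, y)[0], rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 3"):
            pst.pearson_r([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero-variance"):
            pst.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairing:
    def test_sample_joined_to_containing_hour(self):
        hourly = pd.DataFrame(
            {"frac": [0.1, 0.2]},
            index=pd.to_datetime(["2017-01-06 10:00", "2017-01-06 11:00"]),
        )
        marine = pd.DataFrame(
            {"timestamp": pd.to_datetime(["2017-01-06 10:30"]), "value": [5.0]}
        )
        pairs, dropped = pst.pair_marine_to_aerosol(marine, hourly, "frac")
        assert dropped == 0 and pairs["aerosol"].iloc[0] == pytest.approx(0.1)

    def test_sample_in_masked_hour_dropped_and_counted(self):
        hourly = pd.DataFrame(
            {"frac": [0.1, np.nan]},
            index=pd.to_datetime(["2017-01-06 10:00", "2017-01-06 11:00"]),
        )
        marine = pd.DataFrame(
            {"timestamp": pd.to_datetime(["2017-01-06 11:30", "2017-01-06 10:05"]),
             "value": [5.0, 6.0]}
        )
        pairs, dropped = pst.pair_marine_to_aerosol(marine, hourly, "frac")
        assert dropped == 1 and len(pairs) == 1

    def test_pair_count_matches_brute_force_join(self, small_campaign):
        from pbapflow.fluorescence import classify_particles, compute_ft_stats
        from pbapflow.aggregation import time_binned_series

        th = compute_ft_stats(small_campaign.ft_records)
        lab3 = classify_particles(small_campaign.particles, th, 3)
        lab9 = classify_particles(small_campaign.particles, th, 9)
        hourly = time_binned_series(
            small_campaign.particles, lab3["in_tier"].to_numpy(), lab9["in_tier"].to_numpy()
        )
        grp = small_campaign.marine[small_campaign.marine["variable"] == "HDNA"]
        pairs, dropped = pst.pair_marine_to_aerosol(grp, hourly, "frac_fluor")
        brute = sum(
            1
            for t in pd.to_datetime(grp["timestamp"])
            if t.floor("1h") in hourly.index and np.isfinite(hourly.loc[t.floor("1h"), "frac_fluor"])
        )
        assert len(pairs) == brute
        assert len(pairs) + dropped == len(grp)


class TestBootstrap:
    def test_perfectly_correlated_pairs(self):
        x = np.arange(40.0)
        summ = pst.bootstrap_r(x, 3 * x, seed=1)
        assert summ.mean == pytest.approx(1.0) and summ.sd == pytest.approx(0.0)

    def test_null_interval_covers_zero(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=200), rng.normal(size=200)
        summ = pst.bootstrap_r(x, y, seed=3)
        lo, hi = summ.interval
        assert lo < 0.0 < hi
        assert abs(summ.mean) < 0.2

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=50), rng.normal(size=50)
        s1 = pst.bootstrap_r(x, y, seed=7)
        s2 = pst.bootstrap_r(x, y, seed=7)
        np.testing.assert_array_equal(s1.r_values, s2.r_values)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 25"):
            pst.bootstrap_r(np.arange(10.0), np.arange(10.0))

    def test_replicate_count_honoured(self):
        x = np.arange(30.0)
        summ = pst.bootstrap_r(x, x + np.sin(x), n_rep=37, seed=0)
        assert summ.r_values.size + summ.n_discarded == 37


class TestPermutation:
    def test_extreme_case_minimum_p(self):
        x = np.arange(30.0)
        p = pst.permutation_p(x, x, n_perm=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert pst.permutation_p(x, y, n_perm=500, seed=9) == pst.permutation_p(
            x, y, n_perm=500, seed=9
        )

    def test_null_p_is_large_on_independent_data(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert pst.permutation_p(x, y, n_perm=999, seed=1) > 0.05


class TestBinnedMedianIqr:
    def test_constant_y(self):
        x = np.logspace(0, 2, 200)
        out = pst.binned_median_iqr(x, np.full(200, 3.0))
        assert (out["median"].dropna() == 3.0).all()

    def test_monotone_medians_for_y_equals_x(self):
        x = np.logspace(0, 2, 500)
        out = pst.binned_median_iqr(x, x)
        med = out["median"].dropna().to_numpy()
        assert (np.diff(med) > 0).all()

    def test_matches_brute_force_percentiles(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(0, 1, 400)
        y = rng.normal(size=400)
        out = pst.binned_median_iqr(x, y, n_bins=10)
        lx = np.log10(x)
        edges = np.linspace(lx.min(), lx.max(), 11)
        idx = np.clip(np.digitize(lx, edges) - 1, 0, 9)
        for i in range(10):
            v = y[idx == i]
            if v.size:
                assert out["median"].iloc[i] == pytest.approx(np.median(v))
                assert out["q25"].iloc[i] == pytest.approx(np.percentile(v, 25))

    def test_nonpositive_x_is_an_error(self):
        with pytest.raises(ValueError, match="positive"):
            pst.binned_median_iqr(np.array([0.0, 1.0, 2.0]), np.zeros(3))

    def test_sparse_bins_flagged(self):
        x = np.array([1.0, 1.1, 1.2, 100.0])
        out = pst.binned_median_iqr(x, np.zeros(4), n_bins=5, min_count=5)
        assert not out["ok"].any()


class TestClassFractionBootstrap:
    def _table(self, n, probs=None, seed=0):
        rng = np.random.default_rng(seed)
        classes = ["A", "B", "AB", "ABC"]
        if probs is None:
            probs = [0.4, 0.3, 0.2, 0.1]
        idx = pd.date_range("2017-01-06", periods=n, freq="5min")
        rows = rng.multinomial(50, probs, size=n) / 50.0
        return pd.DataFrame(rows, columns=classes, index=idx)

    def test_single_class_stream_all_replicates_identical(self):
        idx = pd.date_range("2017-01-06", periods=400, freq="5min")
        tbl = pd.DataFrame({"B": np.ones(400)}, index=idx)
        out = pst.class_fraction_bootstrap(tbl, n_rep=20, sample_size=288, seed=1)
        assert (out["B"] == 1.0).all() and len(out) == 20

    def test_homogeneous_mixture_recovered(self):
        tbl = self._table(2000)
        out = pst.class_fraction_bootstrap(tbl, n_rep=50, sample_size=288, seed=2)
        glob = tbl.median(axis=0)
        # subsample medians cluster around the global medians
        for c in tbl.columns:
            assert out[c].median() == pytest.approx(glob[c], abs=0.03)

    def test_window_mode_requires_a_qualifying_window(self):
        tbl = self._table(10)  # 50 minutes of data: no 24 h window has 12 h
        with pytest.raises(ValueError, match="window"):
            pst.class_fraction_bootstrap(tbl, mode="window_24h", n_rep=5, seed=3)

    def test_window_mode_runs_on_sufficient_data(self):
        tbl = self._table(600)  # 50 h of contiguous 5-min data
        out = pst.class_fraction_bootstrap(tbl, mode="window_24h", n_rep=10, seed=4)
        assert len(out) == 10
        assert out.to_numpy().max() <= 1.0

    def test_fixed_count_needs_enough_points(self):
        with pytest.raises(ValueError, match="data points"):
            pst.class_fraction_bootstrap(self._table(100), n_rep=5, sample_size=288)

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            pst.class_fraction_bootstrap(self._table(300), mode="bogus")


class TestCorrelatePairs:
    def test_full_analysis_and_significance_flag(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        y = 0.8 * x + 0.4 * rng.normal(size=80)
        res = pst.correlate_pairs(x, y, labels=("x", "y"), n_perm=999, seed=1)
        assert res.n_pairs == 80 and res.r > 0.7
        assert res.p_perm < 0.1 and res.significant
        row = res.to_row()
        assert row["var_x"] == "x" and row["bootstrap_sd"] >= 0.0

    def test_min_pairs_rule(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="at least 25"):
            pst.correlate_pairs(x, x)
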