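"""Distribution fitting, Kuiper and Kolmogorov-Smirnov machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats

from clotkit import dist_stats as ds


class TestFitting:
    def test_lognormal_mle_consistency(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(4.5, 0.4, 10_000)
        fit = ds.fit_distribution(x, "lognormal")
        assert fit.params["mu"] == pytest.approx(4.5, rel=0.02)
        assert fit.params["sigma"] == pytest.approx(0.4, rel=0.02)
        assert np.isfinite(fit.loglik)

    def test_constant_sample_degenerate(self):
        with pytest.raises(ds.DegenerateDataError):
            ds.fit_distribution(np.full(20, 7.0), "normal")

    def test_nonpositive_data_rejected_for_positive_support(self):
        x = np.array([1.0, 2.0, -1.0, 3.0, 4.0])
        for family in ("lognormal", "gamma"):
            with pytest.raises(ValueError):
                ds.fit_distribution(x, family)

    def test_true_family_wins_model_selection(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(4.5, 0.6, 5000)
        best = ds.best_fit(x)
        assert best.family == "lognormal"
        fits = {f: ds.fit_distribution(x, f).loglik for f in ds.FAMILIES}
        assert fits["lognormal"] >= fits["normal"]

    def test_gamma_fit_recovers_shape(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(5.0, 2.0, 20_000)
        fit = ds.fit_distribution(x, "gamma")
        assert fit.params["shape"] == pytest.approx(5.0, rel=0.05)


class TestKuiperStatistic:
    def test_single_point_at_median(self):
        v = ds.kuiper_statistic([0.0], stats.norm.cdf)
        assert v == pytest.approx(1.0, abs=1e-12)

    def test_minimal_v_at_midprobability_quantiles(self):
        n = 20
        q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        assert ds.kuiper_statistic(q, stats.norm.cdf) == pytest.approx(1.0 / n, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        v1 = ds.kuiper_statistic(x, stats.norm.cdf)
        v2 = ds.kuiper_statistic(np.exp(x), stats.lognorm(s=1.0).cdf)
        assert v2 == pytest.approx(v1, abs=1e-12)


class TestKuiperMC:
    def test_self_comparison_never_rejects_and_skews_high(self):
        # comparing a sample against itself: the reference fit is maximally
        # adapted, so p is stochastically large and never significant
        ps = []
        for s in range(15):
            rng = np.random.default_rng(s)
            x = rng.lognormal(4.5, 0.4, 200)
            ps.append(ds.kuiper_mc_test(x, x, n_mc=500, seed=s).p_value)
        assert min(ps) > 0.05
        assert np.median(ps) >= 0.5

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        a, b = rng.lognormal(4.5, 0.4, 150), rng.lognormal(4.6, 0.4, 150)
        r1 = ds.kuiper_mc_test(a, b, n_mc=400, seed=11)
        r2 = ds.kuiper_mc_test(a, b, n_mc=400, seed=11)
        assert r1 == r2

    def test_seed_stability_of_p(self):
        rng = np.random.default_rng(7)
        a, b = rng.lognormal(4.50, 0.4, 300), rng.lognormal(4.56, 0.4, 300)
        ps = [ds.kuiper_mc_test(a, b, n_mc=10_000, seed=s).p_value for s in (1, 2)]
        assert abs(ps[0] - ps[1]) < 0.01

    def test_clear_shift_detected(self):
        rng = np.random.default_rng(8)
        a = rng.lognormal(np.log(95.1), 0.4, 300)
        b = rng.lognormal(np.log(72.1), 0.4, 300)
        res = ds.kuiper_mc_test(a, b, n_mc=1000, seed=0)
        assert res.p_value < 0.01

    def test_small_n_mc_warns(self):
        rng = np.random.default_rng(9)
        a = rng.lognormal(4.5, 0.4, 50)
        with pytest.warns(UserWarning, match="unstable"):
            ds.kuiper_mc_test(a, a, n_mc=50, seed=0)

    def test_pooled_fit_variant_also_calibrated_under_null(self):
        rng = np.random.default_rng(10)
        a, b = rng.lognormal(4.5, 0.4, 100), rng.lognormal(4.5, 0.4, 100)
        res = ds.kuiper_mc_test(a, b, n_mc=500, seed=0, fit_to="pooled")
        assert 0.0 < res.p_value <= 1.0


class TestKSTwoSample:
    def test_disjoint_samples_enumeration_oracle(self):
        res = ds.ks_two_sample([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 / 20)  # 2 / C(6,3)
        assert res.method == "ks_exact"

    def test_identical_samples(self):
        x = [1.0, 2.0, 5.0]
        res = ds.ks_two_sample(x, x)
        assert res.statistic == 0.0

    def test_matches_scipy_exact_on_random_tie_free_data(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.normal(size=4)
            b = rng.normal(0.5, 1.0, size=4)
            ours = ds.ks_two_sample(a, b)
            ref = stats.ks_2samp(a, b, method="exact")
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_all_rank_partitions_n3(self):
        # exhaustively place sample-a ranks among 6 pooled ranks
        vals = np.arange(6, dtype=float)
        for ranks in itertools.combinations(range(6), 3):
            a = vals[list(ranks)]
            b = np.delete(vals, list(ranks))
            ours = ds.ks_two_sample(a, b)
            ref = stats.ks_2samp(a, b, method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_sample_asymptotic_agreement(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=200), rng.normal(0.2, 1.0, size=200)
        ours = ds.ks_two_sample(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert ours.method == "ks_asymp"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=0.2, abs=0.02)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        a, b = rng.uniform(1, 2, 30), rng.uniform(1.2, 2.2, 30)
        d1 = ds.ks_two_sample(a, b).statistic
        d2 = ds.ks_two_sample(np.log(a), np.log(b)).statistic
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ds.ks_two_sample([], [1.0])
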