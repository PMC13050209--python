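import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lohkit.simulate import simulate_count_table
from lohkit.variance_model import (
    BernoulliStitchLink,
    CountTable,
    IdentityLogLink,
    fit_glmm,
    fixed_effect_se,
    gtest_long_arms,
    lrt,
    partition_variance,
)


class TestIdentityLogLink:
    link = IdentityLogLink(0.01)

    def test_stitch_point(self):
        assert self.link.g(np.array([0.01]))[0] == pytest.approx(0.01)
        assert self.link.f(np.array([0.01]))[0] == pytest.approx(0.01)

    def test_mutual_inverse(self):
        y = np.logspace(-6, 1, 200)
        np.testing.assert_allclose(self.link.f(self.link.g(y)), y, rtol=1e-12)

    def test_positive_below_threshold(self):
        x = np.array([-5.0])
        f = self.link.f(x)
        assert f[0] > 0
        assert f[0] == pytest.approx(0.01 * np.exp((-5 - 0.01) / 0.01))

    def test_c1_at_stitch(self):
        eps = 1e-9
        lo = self.link.fp(np.array([0.01 - eps]))[0]
        hi = self.link.fp(np.array([0.01 + eps]))[0]
        assert lo == pytest.approx(hi, abs=1e-6)

    def test_g_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            self.link.g(np.array([0.0]))

    def test_strictly_increasing(self):
        x = np.linspace(-3, 3, 500)
        assert np.all(np.diff(self.link.f(x)) > 0)
        assert np.all(self.link.fp(x) > 0)


class TestBernoulliStitchLink:
    link = BernoulliStitchLink(0.03)

    def test_stitch_point(self):
        eps = self.link.eps
        assert self.link.g(np.array([eps]))[0] == pytest.approx(0.03)

    def test_upper_branch_is_poisson_zero_class(self):
        p = self.link.f(np.array([0.5]))[0]
        assert p == pytest.approx(1 - np.exp(-0.5), rel=1e-12)

    def test_mutual_inverse(self):
        y = np.concatenate([np.logspace(-8, -2, 50), np.linspace(0.05, 0.99, 50)])
        np.testing.assert_allclose(self.link.f(self.link.g(y)), y, rtol=1e-10)

    def test_derivative_continuity_at_stitch(self):
        # verified numerically: one-sided slopes agree to first order (the
        # curvature differs, so the finite-difference error is O(h * f''))
        d = 0.03
        h = 1e-8
        num_lo = (self.link.f(np.array([d])) - self.link.f(np.array([d - h])))[0] / h
        num_hi = (self.link.f(np.array([d + h])) - self.link.f(np.array([d])))[0] / h
        assert num_lo == pytest.approx(np.exp(-d), abs=1e-6)
        assert num_hi == pytest.approx(np.exp(-d), abs=1e-6)
        # analytic one-sided derivatives are exactly equal at the stitch
        fp_lo = self.link.fp(np.array([d - 1e-15]))[0]
        fp_hi = self.link.fp(np.array([d + 1e-15]))[0]
        assert fp_lo == pytest.approx(fp_hi, rel=1e-8)

    def test_positive_probability_everywhere(self):
        x = np.linspace(-10, 10, 200)
        p = self.link.f(x)
        assert np.all(p > 0) and np.all(p < 1)

    def test_g_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            self.link.g(np.array([1.0]))


class TestCountTable:
    def test_round_trip(self):
        tab, _ = simulate_count_table(
            2, 4, 3, 800.0, 1e-5, 1e-4, 0, 0, "poisson_iloh", seed=0
        )
        df = tab.to_frame()
        back = CountTable.from_frame(df)
        np.testing.assert_array_equal(back.count, tab.count)
        np.testing.assert_array_equal(back.arm, tab.arm)

    def test_cells_sufficient_stats(self):
        tab, _ = simulate_count_table(
            2, 3, 5, 800.0, 1e-5, 1e-4, 0, 0, "poisson_iloh", seed=1
        )
        h, a, S, n = tab.cells()
        assert len(S) == 6
        assert np.all(n == 5)
        assert S.sum() == tab.count.sum()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountTable(
                hybrid=[0], clone=[0], arm=[0], count=[-1],
                arm_bp=[1e6], generations=[800.0],
            )


class TestFitGlmm:
    def test_one_slope_recovery_within_2se(self):
        mu, alpha = 2e-5, 3e-4
        tab, _ = simulate_count_table(
            12, 32, 20, 800.0, mu, alpha, 0, 0, "poisson_iloh", seed=42
        )
        fit = fit_glmm(tab, "poisson_iloh", "one_slope")
        se = fixed_effect_se(fit)
        assert abs(fit.mu - mu) <= 2 * se["mu"] + 1e-12
        assert abs(fit.alpha[0] - alpha) <= 2 * se["alpha"][0] + 1e-12

    def test_zero_variance_truth_gives_zero_sigmas(self):
        tab, _ = simulate_count_table(
            8, 16, 15, 800.0, 2e-5, 3e-4, 0, 0, "poisson_iloh", seed=5
        )
        full = fit_glmm(tab, "poisson_iloh", "full")
        hs = fit_glmm(tab, "poisson_iloh", "hybrid_slopes")
        assert full.sigma_fc < 2e-6 and full.sigma_sc < 2e-6
        assert full.loglik == pytest.approx(hs.loglik, abs=1.0)

    def test_sigma_sc_detected(self):
        tab, _ = simulate_count_table(
            12, 32, 20, 800.0, 2e-5, 3e-4, 0.0, 1.2e-4, "poisson_iloh", seed=9
        )
        full = fit_glmm(tab, "poisson_iloh", "full")
        arm = fit_glmm(tab, "poisson_iloh", "arm")
        assert full.sigma_sc > 0
        assert lrt(arm, full, df=1) < 0.05

    def test_bernoulli_family(self):
        tab, truth = simulate_count_table(
            8, 16, 40, 800.0, 5e-6, 2e-4, 0, 0, "bernoulli_tloh", seed=11
        )
        fit = fit_glmm(tab, "bernoulli_tloh", "hybrid_slopes")
        se = fixed_effect_se(fit)
        assert abs(fit.mu - 5e-6) <= 3 * se["mu"] + 1e-9
        one = fit_glmm(tab, "bernoulli_tloh", "one_slope")
        p = lrt(one, fit, df=7)
        assert 0 <= p <= 1

    def test_bernoulli_rejects_counts_above_one(self):
        tab, _ = simulate_count_table(
            2, 4, 5, 800.0, 5e-4, 1e-3, 0, 0, "poisson_iloh", seed=2
        )
        tab.count[0] = 3
        with pytest.raises(ValueError):
            fit_glmm(tab, "bernoulli_tloh", "one_slope")

    def test_seed_reproducible(self):
        tab, _ = simulate_count_table(
            4, 8, 10, 800.0, 2e-5, 3e-4, 0, 0, "poisson_iloh", seed=3
        )
        f1 = fit_glmm(tab, "poisson_iloh", "hybrid_slopes", seed=7)
        f2 = fit_glmm(tab, "poisson_iloh", "hybrid_slopes", seed=7)
        assert f1.loglik == f2.loglik
        assert f1.mu == f2.mu


class TestLrt:
    def test_identical_models_p_one(self):
        tab, _ = simulate_count_table(
            4, 8, 10, 800.0, 2e-5, 3e-4, 0, 0, "poisson_iloh", seed=3
        )
        fit = fit_glmm(tab, "poisson_iloh", "hybrid_slopes")
        assert lrt(fit, fit, df=1) == pytest.approx(1.0)

    def test_null_pvalues_not_anticonservative(self):
        # one_slope truth with equal alphas: hybrid_slopes vs one_slope LRT
        pvals = []
        for rep in range(40):
            tab, _ = simulate_count_table(
                6, 12, 10, 800.0, 2e-5, 3e-4, 0, 0, "poisson_iloh", seed=100 + rep
            )
            small = fit_glmm(tab, "poisson_iloh", "one_slope")
            big = fit_glmm(tab, "poisson_iloh", "hybrid_slopes")
            pvals.append(lrt(small, big, df=5))
        # under the null, the p-value distribution should not pile up near 0
        assert np.mean(np.array(pvals) < 0.05) <= 0.2

    def test_fit_failure_raises(self):
        tab, _ = simulate_count_table(
            4, 8, 10, 800.0, 2e-5, 3e-4, 0, 0, "poisson_iloh", seed=3
        )
        small = fit_glmm(tab, "poisson_iloh", "one_slope")
        big = fit_glmm(tab, "poisson_iloh", "hybrid_slopes")
        with pytest.raises(ValueError):
            lrt(big, small, df=1)  # reversed nesting

    def test_boundary_mixture_halves_pvalue(self):
        tab, _ = simulate_count_table(
            6, 12, 10, 800.0, 2e-5, 3e-4, 0, 8e-5, "poisson_iloh", seed=21
        )
        arm = fit_glmm(tab, "poisson_iloh", "arm")
        full = fit_glmm(tab, "poisson_iloh", "full")
        p_plain = lrt(arm, full, df=1)
        p_mix = lrt(arm, full, df=1, boundary=True)
        assert p_mix <= p_plain


class TestPartitionVariance:
    def test_fractions_sum_to_one(self):
        tab, _ = simulate_count_table(
            6, 12, 10, 800.0, 2e-5, 3e-4, 5e-5, 5e-5, "poisson_iloh", seed=4
        )
        fit = fit_glmm(tab, "poisson_iloh", "full")
        vp = partition_variance(tab, fit)
        assert sum(vp.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_trans_only_truth(self):
        # strong hybrid-slope spread, no cis effects: trans dominates
        rng = np.random.default_rng(0)
        alpha = rng.uniform(5e-5, 6e-4, 12)
        tab, _ = simulate_count_table(
            12, 32, 25, 800.0, 2e-5, alpha, 0, 0, "poisson_iloh", seed=17
        )
        fit = fit_glmm(tab, "poisson_iloh", "full")
        vp = partition_variance(tab, fit)
        fr = vp.fractions
        assert fr["fixed_cis"] < 0.05
        assert fr["segregating_cis"] < 0.05
        assert fr["segregating_trans"] > fr["fixed_cis"] + fr["segregating_cis"]

    def test_tloh_two_way_partition(self):
        tab, _ = simulate_count_table(
            8, 16, 30, 800.0, 5e-6, 2e-4, 0, 0, "bernoulli_tloh", seed=6
        )
        fit = fit_glmm(tab, "bernoulli_tloh", "hybrid_slopes")
        vp = partition_variance(tab, fit)
        assert vp.v_fc == pytest.approx(0.0, abs=1e-12)
        assert vp.v_sc == pytest.approx(0.0, abs=1e-12)
        assert sum(vp.fractions.values()) == pytest.approx(1.0)


class TestGtest:
    def test_identical_proportions_g_zero(self):
        tab = gtest_long_arms({"armX": [10, 20, 30]}, [100, 200, 300])
        assert tab.iloc[0]["G"] == pytest.approx(0.0, abs=1e-9)
        assert tab.iloc[0]["p"] == pytest.approx(1.0)

    def test_hand_built_table_matches_formula(self):
        on = np.array([5.0, 15.0, 10.0])
        tot = np.array([50.0, 50.0, 50.0])
        tab = gtest_long_arms({"a": on}, tot, n_arms_tested=1)
        # oracle: G = 2 sum O ln(O/E) on the 2x3 table
        t = np.vstack([on, tot - on])
        E = np.outer(t.sum(1), t.sum(0)) / t.sum()
        g_oracle = 2 * np.sum(t * np.log(t / E))
        assert tab.iloc[0]["G"] == pytest.approx(g_oracle, rel=1e-10)
        assert tab.iloc[0]["df"] == 2

    def test_bonferroni(self):
        on = np.array([5.0, 15.0, 10.0])
        tot = np.array([50.0, 50.0, 50.0])
        tab = gtest_long_arms({"a": on}, tot, n_arms_tested=8)
        p = tab.iloc[0]["p"]
        assert tab.iloc[0]["p_bonferroni"] == pytest.approx(min(1.0, 8 * p))

    def test_zero_total_hybrid_excluded(self):
        tab = gtest_long_arms({"a": [5, 0, 10]}, [50, 0, 50])
        assert tab.iloc[0]["df"] == 1

    def test_chi2_reference_distribution(self):
        on = np.array([8.0, 12.0])
        tot = np.array([40.0, 40.0])
        tab = gtest_long_arms({"a": on}, tot, n_arms_tested=1)
        assert tab.iloc[0]["p"] == pytest.approx(
            stats.chi2.sf(tab.iloc[0]["G"], 1), rel=1e-12
        )
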