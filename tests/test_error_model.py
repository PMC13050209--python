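import itertools
import math

import numpy as np
import pytest

from lohkit.calls_io import Genotype
from lohkit.error_model import (
    DescendantConfig,
    ErrorModelParams,
    estimate_fdrs,
    f_from_observed,
    lambda_from_rate,
    odds_false_het,
    odds_false_hom,
    transition_probs,
)

from conftest import make_family

HOM_P1, HET, HOM_P2, MISS = (
    Genotype.HOM_P1,
    Genotype.HET,
    Genotype.HOM_P2,
    Genotype.MISSING,
)


def params(mu=4.45e-8, lam=0.128, f=0.1, eps_hom=0.01, eps_het=0.001):
    return ErrorModelParams(mu=mu, lam=lam, f=f, eps_hom=eps_hom, eps_het=eps_het)


def brute_force_transition_probs(p: ErrorModelParams) -> np.ndarray:
    """Independent two-stage enumeration over {true state} x {observed call}.

    True-state kernel and observation kernel enumerated explicitly; the
    product is marginalized over the hidden true state.
    """
    stage1 = {
        0: {0: 1 - p.mu, 1: p.mu, 2: 0.0},
        1: {0: (p.lam + p.mu) / 2, 1: 1 - p.lam - p.mu, 2: (p.lam + p.mu) / 2},
    }
    obs = {
        0: {0: 1 - p.eps_het, 1: p.eps_het, 2: 0.0},
        1: {0: p.eps_hom, 1: 1 - 2 * p.eps_hom, 2: p.eps_hom},
        2: {0: 0.0, 1: p.eps_het, 2: 1 - p.eps_het},
    }
    out = np.zeros((2, 3))
    for i in (0, 1):
        for j in (0, 1, 2):
            out[i, j] = sum(stage1[i][t] * obs[t][j] for t in (0, 1, 2))
    return out


class TestTransitionProbs:
    def test_no_events_no_errors_identity(self):
        p = transition_probs(params(mu=0, lam=0, eps_hom=0, eps_het=0))
        assert p[0, 0] == 1.0 and p[1, 1] == 1.0
        assert p[0, 1] == p[0, 2] == p[1, 0] == p[1, 2] == 0.0

    def test_rows_sum_to_one(self, rng):
        for _ in range(50):
            p = params(
                mu=float(rng.uniform(0, 1e-4)),
                lam=float(rng.uniform(0, 0.5)),
                eps_hom=float(rng.uniform(0, 0.2)),
                eps_het=float(rng.uniform(0, 0.2)),
            )
            probs = transition_probs(p)
            np.testing.assert_allclose(probs.sum(axis=1), [1.0, 1.0], atol=1e-12)

    def test_matches_bruteforce_enumeration(self):
        p = params(mu=4.45e-8, lam=0.128, eps_hom=0.01, eps_het=0.01)
        np.testing.assert_allclose(
            transition_probs(p), brute_force_transition_probs(p), rtol=1e-12
        )

    def test_het_row_symmetric(self):
        probs = transition_probs(params())
        assert probs[1, 0] == pytest.approx(probs[1, 2])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ErrorModelParams(mu=0.6, lam=0.6, f=0.1, eps_hom=0.01, eps_het=0.01)
        with pytest.raises(ValueError):
            ErrorModelParams(mu=0, lam=0, f=1.2, eps_hom=0.01, eps_het=0.01)


class TestOddsRatios:
    def test_prior_odds_no_data_false_hom(self):
        p = params()
        r = odds_false_hom(p, DescendantConfig(0, 0, 0))
        expect = p.eps_hom / (1 - p.eps_het) * (1 - p.f) / p.f
        assert r == pytest.approx(expect, rel=1e-12)

    def test_prior_odds_no_data_false_het(self):
        p = params()
        r = odds_false_het(p, DescendantConfig(0, 0, 0))
        expect = p.eps_het / (1 - 2 * p.eps_hom) * p.f / (1 - p.f)
        assert r == pytest.approx(expect, rel=1e-12)

    def test_direct_substitution_matches_log_space(self):
        # K0 = 6: recompute by naive floating-point substitution
        p = params()
        probs = transition_probs(p)
        cfg = DescendantConfig(6, 0, 0)
        naive = (
            p.eps_hom / (1 - p.eps_het) * (1 - p.f) / p.f
            * (probs[1, 0] / probs[0, 0]) ** 6
        )
        assert odds_false_hom(p, cfg) == pytest.approx(naive, rel=1e-10)

    def test_all_het_descendants_favor_false_hom(self):
        # unanimous discordance with the homozygous founder call
        grid = np.logspace(-4, -1, 10)
        for e1, e2 in itertools.product(grid, grid):
            f = f_from_observed(0.115, e1, e2)
            p = params(f=f, eps_hom=e1, eps_het=e2)
            assert odds_false_hom(p, DescendantConfig(0, 6, 0)) > 1.0

    def test_monotone_in_k1_and_k0(self):
        p = params()
        r_vals = [odds_false_hom(p, DescendantConfig(0, k, 0)) for k in range(6)]
        assert all(b > a for a, b in zip(r_vals, r_vals[1:]))
        r_vals = [odds_false_hom(p, DescendantConfig(k, 0, 0)) for k in range(6)]
        assert all(b < a for a, b in zip(r_vals, r_vals[1:]))

    def test_bayes_enumeration_oracle(self):
        # assemble the posterior odds from the independently enumerated
        # transition kernel and a direct Bayes ratio of joint likelihoods
        p = params()
        bf = brute_force_transition_probs(p)
        for k0, k1, k2 in [(3, 2, 1), (0, 4, 2), (5, 0, 1), (0, 6, 0)]:
            cfg = DescendantConfig(k0, k1, k2)
            lik_het = bf[1, 0] ** k0 * bf[1, 1] ** k1 * bf[1, 2] ** k2
            lik_hom = bf[0, 0] ** k0 * bf[0, 1] ** k1 * bf[0, 2] ** k2
            # founder called hom: P(call | truly het) = eps_hom per side,
            # P(call | truly hom) = 1 - eps_het
            oracle_hom = (
                ((1 - p.f) * p.eps_hom * lik_het)
                / (p.f * (1 - p.eps_het) * lik_hom)
            )
            assert odds_false_hom(p, cfg) == pytest.approx(oracle_hom, rel=1e-10)
            # founder called het: P(call | truly hom) = eps_het,
            # P(call | truly het) = 1 - 2 eps_hom
            oracle_het = (
                (p.f * p.eps_het * lik_hom)
                / ((1 - p.f) * (1 - 2 * p.eps_hom) * lik_het)
            )
            assert odds_false_het(p, cfg) == pytest.approx(oracle_het, rel=1e-10)

    def test_zero_prob_gives_infinity(self):
        p = params(mu=0, lam=0, eps_hom=0, eps_het=0)
        r = odds_false_hom(p, DescendantConfig(0, 6, 0))
        assert r == np.inf


class TestFFromObserved:
    def test_zero_errors_identity(self):
        assert f_from_observed(0.115, 0, 0) == pytest.approx(0.115)

    def test_single_reference_regime(self):
        got = f_from_observed(0.115, 0.01, 0.001)
        assert got == pytest.approx((0.115 - 0.01) / 0.989, rel=1e-12)

    def test_round_trip(self, rng):
        for _ in range(100):
            f = float(rng.uniform(0, 1))
            e1 = float(rng.uniform(0, 0.2))
            e2 = float(rng.uniform(0, 0.2))
            f_obs = f * (1 - e2) + (1 - f) * e1
            assert f_from_observed(f_obs, e1, e2) == pytest.approx(f, abs=1e-12)

    def test_infeasible_raises_with_bound_name(self):
        with pytest.raises(ValueError, match="eps_hom"):
            f_from_observed(0.0154, 0.1, 0.001)
        with pytest.raises(ValueError, match="eps_het"):
            f_from_observed(0.9, 0.0, 0.2)


class TestLambdaFromRate:
    def test_paper_value(self):
        assert lambda_from_rate(1.6e-4, 800) == pytest.approx(0.128)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            lambda_from_rate(1e-2, 800)


class TestEstimateFdrs:
    def test_unanimous_hom_descendants_label_false_het(self):
        g = [[HET] + [HOM_P1] * 8]
        hetero, homo, labels = estimate_fdrs([make_family(g)])
        assert hetero.n_false == 1 and hetero.n_eligible == 1
        assert labels[0]["label"] == "false_heterozygous"

    def test_one_discordant_descendant_no_label(self):
        g = [[HET] + [HOM_P1] * 7 + [HET]]
        hetero, _, labels = estimate_fdrs([make_family(g)])
        assert hetero.n_false == 0 and hetero.n_eligible == 1

    def test_mixed_homozygotes_no_label(self):
        g = [[HET] + [HOM_P1] * 4 + [HOM_P2] * 4]
        hetero, _, _ = estimate_fdrs([make_family(g)])
        assert hetero.n_false == 0

    def test_false_hom_unanimity(self):
        g = [[HOM_P1] + [HET] * 6]
        _, homo, labels = estimate_fdrs([make_family(g)])
        assert homo.n_false == 1 and homo.n_eligible == 1

    def test_too_few_descendants_ineligible(self):
        g = [[HET] + [HOM_P1] * 5]
        hetero, _, _ = estimate_fdrs([make_family(g)], min_descendants=6)
        assert hetero.n_eligible == 0
        assert hetero.pooled is None

    def test_missing_descendants_excluded_from_count(self):
        g = [[HET] + [HOM_P1] * 6 + [MISS] * 2]
        hetero, _, _ = estimate_fdrs([make_family(g)])
        assert hetero.n_false == 1

    def test_simulation_recovery(self, rng):
        # known error rates; unanimity labels should land within a wide
        # binomial CI of the truth-derived expectation
        from lohkit.simulate import SimConfig, HybridConfig, default_genome, simulate_experiment

        eps_hom, eps_het = 0.05, 1e-4
        cfg = SimConfig(
            genome=default_genome(2, 400_000),
            hybrids=[
                HybridConfig(
                    name="h0", n_clones=12, iloh_mu=0.0, iloh_alpha=0.0,
                    tloh_mu=0.0, tloh_alpha=0.0,
                )
            ],
            seed=77,
            n_markers=4000,
            eps_hom=eps_hom,
            eps_het=eps_het,
        )
        res = simulate_experiment(cfg)
        fam = res.call_sets["h0"][0].to_family_matrix()
        hetero, homo, _ = estimate_fdrs([fam])
        # founder all-HET truth: a false-het label needs the founder call HET
        # (prob ~1) and all 12 descendants HOM same side -> essentially never
        assert hetero.n_false == 0
        # false-hom labels: founder must be miscalled HOM (prob 2*eps_hom)
        # and all descendants called HET (prob (1-2*eps_hom)^12)
        p_label = 2 * eps_hom * (1 - 2 * eps_hom) ** 12
        n = homo.n_eligible + hetero.n_eligible
        expected = p_label * n
        sd = np.sqrt(expected)
        assert abs(homo.n_false - expected) < 4 * sd + 2

    def test_zero_error_simulated_data_zero_fdr(self):
        from lohkit.simulate import SimConfig, HybridConfig, default_genome, simulate_experiment

        cfg = SimConfig(
            genome=default_genome(2, 300_000),
            hybrids=[HybridConfig(name="h0", n_clones=8)],
            seed=3,
            n_markers=1500,
        )
        res = simulate_experiment(cfg)
        fam = res.call_sets["h0"][0].to_family_matrix()
        hetero, homo, labels = estimate_fdrs([fam])
        assert hetero.n_false == 0
        assert labels == [] or all(
            lab["label"] != "false_heterozygous" for lab in labels
        )

    def test_requires_founder(self):
        fam = make_family([[HET] * 6], founder=None)
        with pytest.raises(ValueError, match="founder"):
            estimate_fdrs([fam])


class TestPermutationPvalue:
    def test_identical_groups_large_p(self):
        from lohkit.error_model import permutation_pvalue

        p = permutation_pvalue([1.0, 2.0, 3.0], [2.0, 1.0, 3.0], n_perm=2000)
        assert p > 0.5

    def test_separated_groups_small_p(self):
        from lohkit.error_model import permutation_pvalue

        p = permutation_pvalue(
            [0.0] * 8, [1.0] * 8, n_perm=5000, seed=1
        )
        assert p < 0.01

    def test_deterministic_given_seed(self):
        from lohkit.error_model import permutation_pvalue

        a = [0.1, 0.5, 0.2, 0.9]
        b = [0.4, 0.3, 0.8, 0.7]
        assert permutation_pvalue(a, b, seed=3) == permutation_pvalue(a, b, seed=3)
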