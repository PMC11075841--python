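"""Contrasts, BM/OU likelihoods, and the calibrated LLR test."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from idr_evosig import (
    PhyloTree,
    calibrate_critical_values,
    contrast_correlation,
    fit_bm,
    fit_ou,
    llr_test,
    phylogenetic_contrasts,
    sample_tree,
    score_rate_per_region,
    simulate_trait_matrix,
)
from idr_evosig.trait_models import BMFit, OUFit, fit_bm_many, type_one_error_curve


class TestContrasts:
    def test_cherry_hand_recursion(self, cherry):
        cset = phylogenetic_contrasts(cherry, {"A": 0.0, "B": 2.0})
        assert abs(cset.contrasts[0]) == pytest.approx(np.sqrt(2.0))
        assert cset.root_estimate == pytest.approx(1.0)

    def test_constant_trait_zero_contrasts(self, three_tip):
        cset = phylogenetic_contrasts(three_tip, {"A": 5.0, "B": 5.0, "C": 5.0})
        assert np.allclose(cset.contrasts, 0.0)
        assert len(cset.contrasts) == 2

    def test_zero_length_siblings_with_unequal_values(self):
        tree = PhyloTree.from_newick("((A:0,B:0):1,C:1);")
        with pytest.raises(ValueError, match="infinite contrast"):
            phylogenetic_contrasts(tree, {"A": 0.0, "B": 1.0, "C": 0.0})

    @pytest.mark.parametrize("seed", range(6))
    def test_mean_square_equals_gls_reml_oracle(self, seed):
        """The mean of squared contrasts equals the GLS REML rate
        (x-mu)' C^-1 (x-mu) / (n-1), computed by brute-force matrix algebra."""
        rng = np.random.default_rng(seed)
        tree = sample_tree(6, seed)
        x = rng.normal(size=6)
        cset = phylogenetic_contrasts(tree, dict(zip(tree.tip_labels, x)))
        C = tree.cov_matrix()
        Cinv = np.linalg.inv(C)
        ones = np.ones(6)
        mu = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
        reml = (x - mu) @ Cinv @ (x - mu) / 5
        assert np.mean(cset.contrasts**2) == pytest.approx(reml, rel=1e-10)


class TestBM:
    def test_two_tip_closed_forms(self, cherry):
        ml = fit_bm(cherry, {"A": 0.0, "B": 2.0})
        assert ml.mu == pytest.approx(1.0) and ml.sigma2 == pytest.approx(1.0)
        unb = fit_bm(cherry, {"A": 0.0, "B": 2.0}, method="contrasts_unbiased")
        assert unb.sigma2 == pytest.approx(2.0)  # ML = (n-1)/n * REML

    def test_constant_trait_flagged_degenerate(self, three_tip):
        fit = fit_bm(three_tip, {"A": 1.0, "B": 1.0, "C": 1.0})
        assert fit.sigma2 == 0.0 and fit.degenerate

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_matches_mvn_density_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = sample_tree(7, seed + 100)
        x = rng.normal(size=7)
        fit = fit_bm(tree, dict(zip(tree.tip_labels, x)))
        direct = multivariate_normal(
            mean=np.full(7, fit.mu), cov=fit.sigma2 * tree.cov_matrix()
        ).logpdf(x)
        assert fit.loglik == pytest.approx(direct, abs=1e-8)

    def test_shift_invariance(self, tree33):
        rng = np.random.default_rng(0)
        x = rng.normal(size=33)
        a = fit_bm(tree33, x)
        b = fit_bm(tree33, x + 10.0)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-8)
        assert b.mu == pytest.approx(a.mu + 10.0, abs=1e-8)


class TestOU:
    @pytest.mark.parametrize("seed", range(4))
    def test_grid_search_oracle_on_5_tip_toys(self, seed):
        """The profiled ML is at least as good (within 1e-3 nats) as an
        exhaustive grid over (log alpha, log sigma2, mu)."""
        rng = np.random.default_rng(seed)
        tree = sample_tree(5, seed + 50)
        x = rng.normal(size=5)
        fit = fit_ou(tree, x)
        d = tree.dist_matrix()
        best = -np.inf
        for la in np.arange(-4, 4.01, 0.2):
            R = np.exp(-(10.0**la) * d)
            for ls in np.arange(-3, 3.01, 0.1):
                s2 = 10.0**ls
                cov = (s2 / (2 * 10.0**la)) * R
                for mu in np.linspace(x.min() - 1, x.max() + 1, 21):
                    ll = multivariate_normal(mean=np.full(5, mu), cov=cov).logpdf(x)
                    best = max(best, ll)
        assert fit.loglik >= best - 1e-3

    def test_strong_selection_stationary_variance_recovery(self):
        tree = sample_tree(50, 3)
        X = simulate_trait_matrix(tree, "OU", {"sigma2": 1.0, "alpha": 100.0, "mu": 0.0}, 1, 7)
        fit = fit_ou(tree, X[0])
        # with alpha large the tips are ~iid N(mu, sigma2/(2 alpha))
        assert fit.stationary_variance == pytest.approx(0.005, rel=0.5)

    def test_alpha_recovery_in_identifiable_regime(self, tree33):
        """log10(alpha/sigma2)=2 at genus-tree depth: alpha recovered within
        half a log unit (median over replicates)."""
        X = simulate_trait_matrix(tree33, "OU", {"sigma2": 0.01, "alpha": 1.0, "mu": 0.0}, 30, 11)
        alphas = [fit_ou(tree33, x).alpha for x in X]
        assert abs(np.median(np.log10(alphas)) - 0.0) < 0.5

    def test_too_few_tips(self, cherry):
        with pytest.raises(ValueError):
            fit_ou(cherry, {"A": 0.0, "B": 1.0})


class TestLLR:
    def _fits(self, llr):
        bm = BMFit(0.0, 1.0, -10.0)
        ou = OUFit(0.0, 1.0, 1.0, -10.0 + llr)
        return bm, ou

    def test_boundary_is_not_significant(self):
        test = llr_test(*self._fits(4.20), {0.05: 2.58, 0.01: 4.20})
        assert test.significant[0.05] and not test.significant[0.01]

    def test_clear_significance(self):
        test = llr_test(*self._fits(5.0), {0.05: 2.58, 0.01: 4.20})
        assert test.significant == {0.05: True, 0.01: True}

    def test_zero_llr(self):
        test = llr_test(*self._fits(0.0), {0.05: 2.58, 0.01: 4.20})
        assert not any(test.significant.values())

    def test_degenerate_is_missing(self):
        bm = BMFit(0.0, 0.0, float("nan"), degenerate=True)
        ou = OUFit(0.0, 1.0, 1.0, -3.0)
        assert llr_test(bm, ou, {0.05: 2.58}).missing


class TestCalibration:
    def test_quantile_monotonicity_and_rate_invariance(self, tree33):
        criticals, per_rate, dropped = calibrate_critical_values(
            tree33, [0.01, 1.0, 100.0], 120, (0.05, 0.01), seed=5
        )
        assert criticals[0.01] >= criticals[0.05]
        assert dropped == 0
        # LLR distribution does not depend on the true BM rate
        from scipy.stats import ks_2samp

        samples = list(per_rate.values())
        for a, b in zip(samples, samples[1:]):
            assert ks_2samp(a, b).pvalue > 0.01

    def test_type_one_curve_self_consistency(self, tree33):
        criticals, per_rate, _ = calibrate_critical_values(
            tree33, [0.1, 10.0], 150, (0.05,), seed=9
        )
        curve = type_one_error_curve(per_rate, criticals[0.05])
        for rate, frac in curve.items():
            assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 150)


class TestContrastCorrelation:
    def test_perfect_correlation(self):
        x = np.random.default_rng(8).normal(size=30)
        r, p = contrast_correlation(x, x, n_permutations=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_joint_sign_flip_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        flips = rng.choice([-1.0, 1.0], size=20)
        r1, _ = contrast_correlation(x, y, n_permutations=99, seed=2)
        r2, _ = contrast_correlation(x * flips, y * flips, n_permutations=99, seed=2)
        assert abs(r1) == pytest.approx(abs(r2), abs=0.2)  # r itself changes, association strength not

    def test_null_p_is_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            x, y = rng.normal(size=15), rng.normal(size=15)
            ps.append(contrast_correlation(x, y, n_permutations=99, seed=int(rng.integers(1 << 30)))[1])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            contrast_correlation([1.0, 2.0], [1.0, 2.0])


class TestScoreRate:
    def test_constant_scores_zero_rate(self, three_tip):
        assert score_rate_per_region(three_tip, {"A": 0.5, "B": 0.5, "C": 0.5}) == 0.0

    def test_quadratic_scaling(self, three_tip):
        vals = {"A": 0.1, "B": 0.5, "C": 0.9}
        doubled = {k: 2 * v for k, v in vals.items()}
        assert score_rate_per_region(three_tip, doubled) == pytest.approx(
            4 * score_rate_per_region(three_tip, vals)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_gls_oracle_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        tree = sample_tree(8, seed + 20)
        C = tree.cov_matrix()
        Cinv = np.linalg.inv(C)
        ones = np.ones(8)
        rates, oracle = [], []
        for _ in range(10):
            x = rng.normal(size=8)
            rates.append(score_rate_per_region(tree, dict(zip(tree.tip_labels, x))))
            mu = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
            oracle.append((x - mu) @ Cinv @ (x - mu) / 7)
        assert np.allclose(sorted(range(10), key=rates.__getitem__), sorted(range(10), key=oracle.__getitem__))
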