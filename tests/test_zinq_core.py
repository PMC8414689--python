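import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zinq import (
    Design,
    fit_null_quantile,
    fit_quantile,
    logistic_presence_test,
    perturb_counts,
    rank_score_test,
    residualize,
    score_covariance,
    standard_rank_score_baseline,
    zinq_marginals,
)

def pinball_loss(w, fitted, tau):
    """Independent pinball-loss evaluator used as a fit oracle."""
    u = np.asarray(w) - np.asarray(fitted)
    return float(np.sum(u * (tau - (u < 0))))


def _intercept_design(c):
    c = np.asarray(c, dtype=float)
    return Design(c, np.ones((c.size, 1)))


class TestPerturbCounts:
    def test_bounds_and_mask(self):
        y = np.array([0.0, 2.0, 2.0, 5.0])
        out = perturb_counts(y, discrete=True, seed=0)
        assert np.all(out.w >= y) and np.all(out.w < y + 1)
        np.testing.assert_array_equal(out.nonzero_mask, y > 0)
        assert len(np.unique(out.w)) == y.size  # ties broken

    def test_continuous_identity(self):
        y = np.array([0.0, 1.5, 2.5])
        out = perturb_counts(y, discrete=False, seed=0)
        np.testing.assert_array_equal(out.w, y)
        assert not out.applied

    def test_seed_determinism(self):
        y = np.arange(10.0)
        a = perturb_counts(y, True, seed=3)
        b = perturb_counts(y, True, seed=3)
        np.testing.assert_array_equal(a.w, b.w)


class TestLogisticPresenceTest:
    def test_score_test_equals_pearson_chi_square(self):
        # 2x2 presence table (20 present / 10 absent) vs (10 / 20):
        # the Rao score test for a single binary covariate is the Pearson
        # chi-square, here 60*(400-100)^2/30^4 = 6.667
        mask = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)] > 0
        design = _intercept_design(np.r_[np.zeros(30), np.ones(30)])
        res = logistic_presence_test(mask, design, method="score")
        assert res.statistic == pytest.approx(20.0 / 3.0, rel=1e-10)
        assert res.p_l == pytest.approx(0.009823, abs=1e-5)

    def test_balanced_presence_gives_zero_score(self):
        mask = np.r_[np.ones(15), np.zeros(15), np.ones(15), np.zeros(15)] > 0
        design = _intercept_design(np.r_[np.zeros(30), np.ones(30)])
        res = logistic_presence_test(mask, design, method="score")
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_l == pytest.approx(1.0)

    @pytest.mark.parametrize("mask_value", [True, False])
    def test_degenerate_masks(self, mask_value):
        mask = np.full(40, mask_value)
        res = logistic_presence_test(mask, _intercept_design(np.arange(40.0)))
        assert res.degenerate and np.isnan(res.p_l)

    @pytest.mark.parametrize("method", ["wald", "score", "lrt"])
    def test_methods_agree_asymptotically(self, method, binary_design):
        rng = np.random.default_rng(1)
        eta = -0.3 + 0.8 * binary_design.variable
        mask = rng.uniform(size=binary_design.n) < 1 / (1 + np.exp(-eta))
        res = logistic_presence_test(mask, binary_design, method=method)
        assert res.p_l < 0.05  # strong presence effect detected by all three


class TestResidualize:
    def test_explicit_projection_example(self):
        # oracle: dense projection-matrix computation on the masked design
        design = _intercept_design([1.0, 0.0, 1.0, 0.0])
        resid = residualize(design, np.array([False, True, True, True]))
        np.testing.assert_allclose(
            resid.c_star, [0.0, -1 / 3, 2 / 3, -1 / 3], atol=1e-12
        )
        assert resid.m == 3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_orthogonality_property(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        z = np.column_stack([np.ones(n), rng.normal(size=n)])
        design = Design(rng.normal(size=n), z)
        mask = rng.uniform(size=n) < 0.7
        if mask.sum() < 3:
            return
        resid = residualize(design, mask)
        z_tilde = z * mask[:, None]
        np.testing.assert_allclose(z_tilde.T @ resid.c_star, 0.0, atol=1e-8)
        assert np.all(resid.c_star[~mask] == 0.0)

    def test_constant_variable_on_nonzeros(self):
        design = _intercept_design([1.0, 1.0, 1.0, 0.0])
        resid = residualize(design, np.array([True, True, True, False]))
        assert resid.degenerate
        np.testing.assert_allclose(resid.c_star, 0.0, atol=1e-12)


class TestFitQuantile:
    def _brute_force_intercept(self, w, tau):
        # the pinball loss is piecewise linear with breakpoints at the data
        candidates = np.asarray(w, dtype=float)
        losses = [pinball_loss(w, np.full(len(w), c), tau) for c in candidates]
        best = min(losses)
        # lower vertex of the minimizing set
        return min(c for c, l in zip(candidates, losses) if l <= best + 1e-12)

    @pytest.mark.parametrize(
        "w,tau",
        [([1.0, 2.0, 3.0], 0.5), ([1.0, 2.0, 3.0], 0.25), ([1, 2, 3, 4], 0.5),
         ([5.0, 1.0, 4.0, 2.0, 9.0], 0.7)],
    )
    def test_intercept_only_matches_brute_force(self, w, tau):
        fitted = fit_quantile(np.asarray(w, float), np.ones((len(w), 1)), tau)
        assert fitted[0] == pytest.approx(self._brute_force_intercept(w, tau))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        w = rng.lognormal(size=21)
        base = fit_quantile(w, np.ones((21, 1)), 0.3)[0]
        shifted = fit_quantile(w + 5.0, np.ones((21, 1)), 0.3)[0]
        assert shifted == pytest.approx(base + 5.0, abs=1e-9)

    def test_lp_path_attains_vertex_enumeration_optimum(self):
        # oracle: a quantile-regression solution interpolates p observations;
        # enumerate all p-subsets, solve each exactly, take the smallest loss
        rng = np.random.default_rng(5)
        n, p = 12, 2
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        w = rng.lognormal(size=n)
        tau = 0.4
        best = np.inf
        for subset in itertools.combinations(range(n), p):
            sub = np.array(subset)
            try:
                coef = np.linalg.solve(x[sub], w[sub])
            except np.linalg.LinAlgError:
                continue
            best = min(best, pinball_loss(w, x @ coef, tau))
        lp = fit_quantile(w, x, tau)
        assert pinball_loss(w, x @ lp, tau) == pytest.approx(best, abs=1e-8)

    def test_null_fit_uses_nonzero_subset(self):
        y = np.array([0.0, 0.0, 1.0, 2.0, 3.0])
        design = _intercept_design(np.zeros(5))
        alpha = fit_null_quantile(y, design, y > 0, 0.5)
        assert alpha[0] == pytest.approx(2.0)


class TestRankScoreTest:
    def test_hand_computed_score(self):
        # Y=(0,1,2,3,4), C=(0,1,0,1,0), intercept-only Z, tau=0.5;
        # alpha_hat = 2 (lower vertex) gives S = -0.5/sqrt(5)
        y = np.array([0.0, 1, 2, 3, 4])
        design = _intercept_design([0.0, 1, 0, 1, 0])
        mask = y > 0
        resid = residualize(design, mask)
        res = rank_score_test(y, design, mask, resid, 0.5)
        assert res.alpha_hat[0] == pytest.approx(2.0)
        assert res.s == pytest.approx(-0.5 / np.sqrt(5), abs=1e-12)

    def test_reduction_to_standard_test_without_zeros(self):
        rng = np.random.default_rng(2)
        n = 80
        y = rng.lognormal(size=n)  # strictly positive, continuous
        design = _intercept_design((rng.uniform(size=n) < 0.5).astype(float))
        mask = np.ones(n, dtype=bool)
        resid = residualize(design, mask)
        for tau, baseline in zip(
            [0.25, 0.5, 0.75],
            standard_rank_score_baseline(y, design, [0.25, 0.5, 0.75],
                                         discrete=False),
        ):
            adjusted = rank_score_test(y, design, mask, resid, tau)
            assert adjusted.s == pytest.approx(baseline.s, abs=1e-10)
            assert adjusted.t == pytest.approx(baseline.t, abs=1e-10)

    def test_constant_variable_gives_na(self):
        y = np.array([0.0, 1, 2, 3])
        design = _intercept_design([1.0, 1, 1, 1])
        resid = residualize(design, y > 0)
        res = rank_score_test(y, design, y > 0, resid, 0.5)
        assert np.isnan(res.p_q)


class TestScoreCovariance:
    def test_printed_formula(self):
        design = _intercept_design([1.0, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        resid = residualize(design, np.ones(10, dtype=bool))
        resid.quadratic_norm = 10.0  # pin C*'C* for the arithmetic check
        cov = score_covariance(np.array([0.25, 0.5]), resid, n=10)
        np.testing.assert_allclose(
            cov.sigma, [[0.1875, 0.125], [0.125, 0.25]], atol=1e-12
        )

    def test_implied_correlation_independent_of_cstar(self):
        for qn in (3.0, 117.0):
            design = _intercept_design(np.arange(8.0))
            resid = residualize(design, np.ones(8, dtype=bool))
            resid.quadratic_norm = qn
            cov = score_covariance(np.array([0.25, 0.5]), resid, n=8).sigma
            corr = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
            assert corr == pytest.approx(0.125 / np.sqrt(0.1875 * 0.25), abs=1e-12)

    def test_positive_semidefinite_on_any_grid(self):
        design = _intercept_design(np.r_[np.zeros(10), np.ones(10)])
        resid = residualize(design, np.ones(20, dtype=bool))
        taus = np.array([0.05, 0.1, 0.25, 0.5, 0.6, 0.75, 0.9, 0.95])
        eig = np.linalg.eigvalsh(score_covariance(taus, resid, 20).sigma)
        assert eig.min() >= -1e-10


class TestZinqMarginals:
    def test_all_zero_taxon(self):
        marg = zinq_marginals(np.zeros(30), _intercept_design(np.arange(30.0)),
                              np.array([0.5]))
        assert marg.flags == ["degenerate"]
        assert marg.logistic is None and not marg.quantile

    def test_zero_free_taxon(self):
        rng = np.random.default_rng(4)
        y = rng.lognormal(size=60)
        design = _intercept_design((rng.uniform(size=60) < 0.5).astype(float))
        marg = zinq_marginals(y, design, np.array([0.25, 0.5, 0.75]),
                              discrete=False)
        assert marg.r_hat == 0.0
        assert marg.logistic is None and "zero_free" in marg.flags
        assert len(marg.quantile) == 3

    def test_baseline_matches_on_zero_free_data_and_is_deterministic(self):
        rng = np.random.default_rng(9)
        y = rng.poisson(6, size=50).astype(float) + 1
        design = _intercept_design((rng.uniform(size=50) < 0.5).astype(float))
        a = standard_rank_score_baseline(y, design, [0.5], seed=11)
        b = standard_rank_score_baseline(y, design, [0.5], seed=11)
        assert a[0].s == b[0].s
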