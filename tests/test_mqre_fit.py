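"""Random-effects M-quantile estimation: oracles and invariants."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import brentq

from mqreg import (
    DataError,
    GroupedDataset,
    MQREOptions,
    MQSpec,
    VarianceComponents,
    asym_psi,
    build_covariance,
    fit_expectile_re,
    fit_gaussian_ml,
    fit_mqre,
    scaled_residuals,
)
from mqreg.estimation import beta_step, variance_step, compute_k2q

from conftest import make_grouped


class TestScaledResiduals:
    def test_exact_beta_zero_noise(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        beta = np.array([2.0, 1.5])
        data = GroupedDataset(
            y=X @ beta,
            X=X,
            group_idx=[0, 0, 0, 1, 1, 1],
            group_labels=[0, 1],
        )
        vc = VarianceComponents(sigma2_gamma=1.0, sigma2_eps=2.0)
        assert np.allclose(scaled_residuals(data, beta, vc), 0.0)

    def test_hand_computed(self):
        data = GroupedDataset(
            y=[1.0, 3.0, 6.0],
            X=np.ones((3, 1)),
            group_idx=[0, 0, 1],
            group_labels=[0, 1],
        )
        vc = VarianceComponents(sigma2_gamma=3.0, sigma2_eps=1.0)
        r = scaled_residuals(data, np.array([2.0]), vc)
        assert np.allclose(r, np.array([-1.0, 1.0, 4.0]) / 2.0, atol=1e-12)


class TestBetaStep:
    def test_fixed_point_at_solution(self, small_grouped):
        fit = fit_mqre(small_grouped, MQSpec(q=0.5, c=1.345))
        beta2, g = beta_step(small_grouped, fit.beta, fit.varcomp, fit.spec)
        assert np.allclose(beta2, fit.beta, atol=1e-7)

    def test_single_newton_step_is_gls_under_squared_loss(self, rng):
        """With a quadratic score the Newton step lands on GLS exactly."""
        data = make_grouped(rng, d=5, nj=2)
        vc = VarianceComponents(sigma2_gamma=2.0, sigma2_eps=1.0)
        spec = MQSpec(q=0.5, c=1e6, loss="squared")
        cov = build_covariance(vc, data)
        gls = np.linalg.solve(
            data.X.T @ cov.solve(data.X), data.X.T @ cov.solve(data.y)
        )
        start = np.array([10.0, -4.0])
        stepped, _ = beta_step(data, start, vc, spec)
        assert np.allclose(stepped, gls, atol=1e-8)


class TestVarianceStep:
    def test_fixed_point_at_solution(self, small_grouped):
        fit = fit_mqre(small_grouped, MQSpec(q=0.5, c=1.345))
        vc2 = variance_step(small_grouped, fit.beta, fit.varcomp, fit.spec)
        assert vc2.sigma2_gamma == pytest.approx(
            fit.varcomp.sigma2_gamma, rel=1e-4
        )
        assert vc2.sigma2_eps == pytest.approx(fit.varcomp.sigma2_eps, rel=1e-4)

    def test_preserves_positivity(self, small_grouped):
        vc = VarianceComponents(sigma2_gamma=0.5, sigma2_eps=0.5)
        beta = np.zeros(2)
        k2 = compute_k2q(0.5, 1.345)
        vc2 = variance_step(small_grouped, beta, vc, MQSpec(q=0.5), k2)
        assert vc2.sigma2_gamma > 0.0 and vc2.sigma2_eps > 0.0


class TestGaussianMLOracle:
    def test_matches_statsmodels_mixedlm(self, nn_replicate):
        """Squared loss at q=0.5 reproduces the ML random-intercepts fit."""
        ours = fit_gaussian_ml(nn_replicate, predict_effects=False)
        ref = sm.MixedLM(
            nn_replicate.y, nn_replicate.X, groups=nn_replicate.group_idx
        ).fit(reml=False)
        assert np.allclose(ours.beta, np.asarray(ref.fe_params), rtol=1e-3)
        assert ours.varcomp.sigma2_gamma == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3
        )
        assert ours.varcomp.sigma2_eps == pytest.approx(ref.scale, rel=1e-3)


class TestSpecialCaseChain:
    def test_expectile_delegates_to_squared_loss(self, small_grouped):
        a = fit_expectile_re(small_grouped, 0.75)
        b = fit_mqre(small_grouped, MQSpec(q=0.75, c=1e6, loss="squared"))
        assert np.allclose(a.beta, b.beta, atol=1e-10)

    def test_expectile_half_is_gaussian_ml(self, nn_replicate):
        a = fit_expectile_re(nn_replicate, 0.5, predict_effects=False)
        b = fit_gaussian_ml(nn_replicate, predict_effects=False)
        assert np.allclose(a.beta, b.beta, atol=1e-10)

    def test_balanced_expectile_re_is_marginal_expectile(self, rng):
        """On a balanced intercept-only design the group weighting cancels
        and the expectile random-effects intercept equals the sample
        marginal expectile (independent root-finding oracle)."""
        d, nj = 40, 6
        idx = np.repeat(np.arange(d), nj)
        y = 3.0 + rng.normal(0, 1.5, d)[idx] + rng.normal(0, 1.0, d * nj)
        data = GroupedDataset(
            y=y, X=np.ones((d * nj, 1)), group_idx=idx, group_labels=np.arange(d)
        )
        q = 0.75
        fit = fit_expectile_re(data, q, predict_effects=False)

        def balance(m):
            u = y - m
            return float(np.sum(2 * np.where(u > 0, q, 1 - q) * u))

        oracle = brentq(balance, y.min(), y.max(), xtol=1e-12)
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-8)

    def test_expectile_intercept_monotone_in_q(self, rng):
        data = make_grouped(rng, d=30, nj=5)
        intercepts = [
            fit_expectile_re(data, q, predict_effects=False).beta[0]
            for q in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert np.all(np.diff(intercepts) > 0)


class TestReductionsAndInvariants:
    def test_fixed_zero_gamma_reduces_to_single_level(self, rng):
        """With sigma2_gamma held at ~0 the multilevel score collapses to
        the single-level M-quantile estimating equation at scale sigma_eps."""
        data = make_grouped(rng, d=10, nj=8, sg=0.0)
        se2 = 1.0
        vc = VarianceComponents(sigma2_gamma=1e-12, sigma2_eps=se2)
        spec = MQSpec(q=0.7, c=1.345)
        fit = fit_mqre(data, spec, fixed_varcomp=vc, predict_effects=False)
        score = data.X.T @ asym_psi(
            data.y - data.X @ fit.beta, spec, np.sqrt(se2 + 1e-12)
        )
        assert np.max(np.abs(score)) < 1e-6 * data.n

    def test_scale_equivariance(self, small_grouped):
        """y -> k y multiplies beta by k and both variances by k^2."""
        k = 3.0
        spec = MQSpec(q=0.75, c=1.345)
        base = fit_mqre(small_grouped, spec, predict_effects=False)
        scaled_data = GroupedDataset(
            y=k * small_grouped.y,
            X=small_grouped.X,
            group_idx=small_grouped.group_idx,
            group_labels=small_grouped.group_labels,
        )
        scaled = fit_mqre(scaled_data, spec, predict_effects=False)
        assert np.allclose(scaled.beta, k * base.beta, rtol=1e-4)
        assert scaled.varcomp.sigma2_gamma == pytest.approx(
            k**2 * base.varcomp.sigma2_gamma, rel=1e-3
        )
        assert scaled.varcomp.sigma2_eps == pytest.approx(
            k**2 * base.varcomp.sigma2_eps, rel=1e-3
        )

    @pytest.mark.parametrize("q", [0.5, 0.9])
    def test_estimating_equations_vanish_at_convergence(self, nn_replicate, q):
        fit = fit_mqre(nn_replicate, MQSpec(q=q, c=1.345), predict_effects=False)
        assert fit.converged
        assert np.all(fit.eq_norms < 1e-6 * nn_replicate.n)

    def test_parameter_recovery(self, rng):
        """Variance components recover the generating values approximately
        (squared loss, Gaussian data: the calibrated equations are exact)."""
        data = make_grouped(rng, d=150, nj=8, sg=np.sqrt(3.0), se=np.sqrt(5.0))
        fit = fit_gaussian_ml(data, predict_effects=False)
        assert fit.varcomp.sigma2_gamma == pytest.approx(3.0, rel=0.30)
        assert fit.varcomp.sigma2_eps == pytest.approx(5.0, rel=0.10)
        assert fit.beta[1] == pytest.approx(0.5, abs=0.05)

    def test_nonconvergence_is_flagged_not_raised(self, small_grouped):
        fit = fit_mqre(
            small_grouped,
            MQSpec(q=0.5, c=1.345),
            MQREOptions(max_outer=1, outer_tol=1e-14),
            predict_effects=False,
        )
        assert not fit.converged

    def test_single_group_rejected(self, rng):
        n = 20
        data = GroupedDataset(
            y=rng.normal(size=n),
            X=np.column_stack([np.ones(n), rng.normal(size=n)]),
            group_idx=np.zeros(n, dtype=int),
            group_labels=[0],
        )
        with pytest.raises(DataError):
            fit_mqre(data, MQSpec(q=0.5))
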