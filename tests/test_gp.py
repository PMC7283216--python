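"""GP core: kernel, posterior, log joint, CCD marginal likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import logsumexp

from pairgp import (
    CCDGrid,
    GPConfig,
    Hyperparameters,
    HyperPriors,
    TimeSeries,
    estimate_log_ml,
    find_mode,
    fit_ccd,
    gp_posterior,
    log_joint,
    predictive_distribution,
    se_kernel,
)
from pairgp.gp import InvalidParameterError, log_marginal_likelihood


class TestSEKernel:
    @pytest.mark.parametrize(
        "t1,t2,ell,sv,expected",
        [
            ([0.0], [0.0], 30.0, 1.0, 1.0),  # zero distance returns the signal variance
            ([0.0], [30.0], 30.0, 2.0, 2.0 * math.exp(-0.5)),
            ([0.0], [1e6], 30.0, 1.0, 0.0),  # decay limit
        ],
    )
    def test_pointwise_values(self, t1, t2, ell, sv, expected):
        hp = Hyperparameters(ell, sv, 0.1)
        K = se_kernel(np.array(t1), np.array(t2), hp)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_gram_matrix_symmetric_psd(self, rng):
        t = rng.uniform(0, 100, 12)
        K = se_kernel(t, t, Hyperparameters(20.0, 1.5, 0.1))
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    @pytest.mark.parametrize("bad", [dict(lengthscale=-1.0), dict(signal_variance=0.0), dict(noise_variance=-0.5)])
    def test_nonpositive_hyperparameters_rejected(self, bad):
        kw = dict(lengthscale=30.0, signal_variance=1.0, noise_variance=0.1)
        kw.update(bad)
        with pytest.raises(InvalidParameterError):
            Hyperparameters(**kw)


class TestGPPosterior:
    def test_matches_dense_inverse_oracle(self, rng):
        """Cholesky-path posterior equals a naive dense-inverse solve."""
        hp = Hyperparameters(25.0, 1.3, 0.2)
        for n in (3, 6, 10):
            t = np.sort(rng.uniform(0, 100, n))
            x = rng.normal(0, 1, n)
            tstar = np.linspace(0, 100, 9)
            post = gp_posterior(TimeSeries(t, x), tstar, hp)
            Kinv = np.linalg.inv(se_kernel(t, t, hp) + hp.noise_variance * np.eye(n))
            Ks = se_kernel(tstar, t, hp)
            mu = Ks @ Kinv @ x
            cov = se_kernel(tstar, tstar, hp) - Ks @ Kinv @ Ks.T
            np.testing.assert_allclose(post.mean, mu, atol=1e-8)
            np.testing.assert_allclose(post.cov, 0.5 * (cov + cov.T), atol=1e-8)

    def test_noiseless_interpolation(self, rng):
        t = np.sort(rng.uniform(0, 50, 5))
        x = rng.normal(0, 1, 5)
        hp = Hyperparameters(30.0, 1.0, 1e-10)
        post = gp_posterior(TimeSeries(t, x), t, hp)
        np.testing.assert_allclose(post.mean, x, atol=1e-4)

    def test_prior_reversion_far_from_data(self):
        hp = Hyperparameters(10.0, 2.0, 0.1)
        data = TimeSeries([0.0, 5.0, 10.0], [1.0, -1.0, 0.5])
        post = gp_posterior(data, [500.0], hp)
        assert abs(post.mean[0]) < 1e-6
        assert post.cov[0, 0] == pytest.approx(hp.signal_variance, rel=1e-6)

    def test_variance_nonnegative_everywhere(self, rng):
        hp = Hyperparameters(15.0, 1.0, 0.05)
        t = np.sort(rng.uniform(0, 100, 8))
        post = gp_posterior(TimeSeries(t, rng.normal(0, 1, 8)), np.linspace(-20, 120, 40), hp)
        assert np.diag(post.cov).min() >= -1e-10

    def test_centring_equivalent_to_constant_mean_gp(self, rng):
        """Centre, fit, un-centre == GP with constant mean at the sample mean."""
        hp = Hyperparameters(20.0, 1.0, 0.1)
        t = np.sort(rng.uniform(0, 80, 6))
        x = rng.normal(3.0, 1.0, 6)
        tstar = np.linspace(0, 80, 11)
        centred, mu = TimeSeries(t, x).centred()
        un_centred_mean = gp_posterior(centred, tstar, hp).mean + mu
        Kinv = np.linalg.inv(se_kernel(t, t, hp) + hp.noise_variance * np.eye(6))
        const_mean = mu + se_kernel(tstar, t, hp) @ Kinv @ (x - mu)
        np.testing.assert_allclose(un_centred_mean, const_mean, atol=1e-10)


class TestLogJoint:
    def test_scalar_closed_form(self, priors):
        """N=1, x=0: likelihood is N(0; 0, sv + nv) exactly."""
        hp = Hyperparameters(30.0, 1.2, 0.05)
        data = TimeSeries([10.0], [0.0])
        expected = stats.norm.logpdf(0.0, scale=math.sqrt(1.2 + 0.05)) + priors.log_density_log_scale(hp.to_log())
        assert log_joint(data, hp, priors) == pytest.approx(expected, abs=1e-10)

    def test_gaussian_scaling_identity(self, rng):
        """Scaling both variances by c and x by sqrt(c) shifts log lik by -(N/2) ln c."""
        t = np.sort(rng.uniform(0, 60, 5))
        x = rng.normal(0, 1, 5)
        c = 3.7
        hp = Hyperparameters(25.0, 1.0, 0.2)
        hp_c = Hyperparameters(25.0, c * 1.0, c * 0.2)
        ll = log_marginal_likelihood(TimeSeries(t, x), hp)
        ll_c = log_marginal_likelihood(TimeSeries(t, math.sqrt(c) * x), hp_c)
        assert ll_c - ll == pytest.approx(-0.5 * 5 * math.log(c), abs=1e-8)

    def test_finite_at_prior_means(self, toy_series, priors):
        hp = Hyperparameters(30.0, 1.0, 0.01)
        assert np.isfinite(log_joint(toy_series, hp, priors))

    @given(st.floats(min_value=0.1, max_value=100.0), st.floats(min_value=0.01, max_value=10.0))
    def test_degenerate_parameters_never_nan(self, ell, sv):
        data = TimeSeries([0.0, 1.0], [0.5, -0.5])
        val = log_joint(data, Hyperparameters(ell, sv, 1e-9), HyperPriors())
        assert not math.isnan(val)


class TestFindMode:
    def test_invariant_to_observation_order(self, toy_series, priors):
        mode1, H1 = find_mode(toy_series, priors)
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        shuffled = TimeSeries(toy_series.times[perm], toy_series.values[perm])
        mode2, H2 = find_mode(shuffled, priors)
        assert mode1.lengthscale == pytest.approx(mode2.lengthscale, rel=1e-5)
        assert mode1.signal_variance == pytest.approx(mode2.signal_variance, rel=1e-5)
        np.testing.assert_allclose(H1, H2, rtol=1e-3, atol=1e-6)

    def test_requires_at_least_one_restart(self, toy_series, priors):
        with pytest.raises(ValueError):
            find_mode(toy_series, priors, restarts=0)


class TestCCD:
    def test_three_dim_design_has_fifteen_points(self, toy_series, priors):
        """mode + 6 star + 8 factorial = 15 for d = 3."""
        grid = fit_ccd(toy_series, priors)
        assert len(grid.points) == 15
        assert grid.points[0] == grid.mode

    def test_weights_positive_and_mode_mass_largest(self, toy_series, priors):
        grid = fit_ccd(toy_series, priors)
        assert np.all(grid.weights > 0)
        mass = grid.posterior_values * grid.weights
        assert mass[0] == mass.max()
        # non-mode split-Gaussian values all sit at exp(-r0^2/2)
        r0 = GPConfig().ccd_scale * math.sqrt(3)
        np.testing.assert_allclose(grid.posterior_values[1:], math.exp(-(r0**2) / 2))

    def test_star_points_axis_aligned_in_whitened_space(self, toy_series, priors):
        grid = fit_ccd(toy_series, priors)
        Lh = np.linalg.cholesky(grid.hessian)
        phi0 = grid.mode.to_log()
        for p in grid.points[1:7]:  # star points follow the mode
            z = Lh.T @ (p.to_log() - phi0)
            nonzero = np.abs(z) > 1e-8 * np.abs(z).max()
            assert nonzero.sum() == 1

    @pytest.mark.parametrize("free_name,fixed", [
        ("noise_variance", {"lengthscale": 30.0, "signal_variance": 1.0}),
        ("signal_variance", {"lengthscale": 30.0, "noise_variance": 0.05}),
        ("lengthscale", {"signal_variance": 1.0, "noise_variance": 0.05}),
    ])
    def test_log_ml_matches_quadrature_oracle(self, free_name, fixed, priors):
        """One free hyperparameter: CCD within 0.5 nats of fine-grid quadrature."""
        data = TimeSeries([0.0, 20.0, 45.0], [0.4, -0.6, 0.3])
        est = estimate_log_ml(data, priors, fixed=fixed)
        names = ("lengthscale", "signal_variance", "noise_variance")
        phis = np.linspace(-12, 6, 3601)
        vals = []
        for p in phis:
            kw = dict(fixed)
            kw[free_name] = math.exp(p)
            vals.append(log_joint(data, Hyperparameters(**{n: kw[n] for n in names}), priors))
        quad = logsumexp(np.array(vals), b=phis[1] - phis[0])
        assert abs(est - quad) < 0.5

    def test_single_point_grid_reduces_to_log_joint(self, toy_series, priors):
        hp = Hyperparameters(30.0, 1.0, 0.05)
        lj = log_joint(toy_series, hp, priors)
        grid = CCDGrid(
            points=[hp],
            posterior_values=np.array([1.0]),
            weights=np.array([1.0]),
            mode=hp,
            hessian=np.eye(3),
            log_joints=np.array([lj]),
        )
        assert estimate_log_ml(toy_series, priors, grid=grid) == pytest.approx(lj, abs=1e-12)

    def test_replicate_gain_bounded_by_best_single_theta(self, priors):
        """Adding an identical replicate cannot raise log ML by more than the
        best single-theta likelihood gain over the grid."""
        base = TimeSeries([0.0, 20.0, 40.0], [0.5, -0.2, 0.4])
        rep = TimeSeries([0.0, 20.0, 40.0, 40.0], [0.5, -0.2, 0.4, 0.4])
        grid_b = fit_ccd(base, priors)
        grid_r = fit_ccd(rep, priors)
        ml_b = estimate_log_ml(base, priors, grid=grid_b)
        ml_r = estimate_log_ml(rep, priors, grid=grid_r)
        best_gain = max(
            log_joint(rep, p, priors) - log_joint(base, p, priors)
            for p in grid_b.points + grid_r.points
        )
        assert ml_r - ml_b <= best_gain + 1e-6


class TestPredictive:
    def test_single_component_equals_posterior_at_mode(self, toy_series, priors):
        hp = Hyperparameters(28.0, 1.1, 0.08)
        grid = CCDGrid(
            points=[hp], posterior_values=np.array([1.0]), weights=np.array([1.0]),
            mode=hp, hessian=np.eye(3), log_joints=np.array([0.0]),
        )
        tstar = np.linspace(0, 100, 12)
        mix = predictive_distribution(toy_series, tstar, grid)
        exact = gp_posterior(toy_series, tstar, hp)
        np.testing.assert_allclose(mix.mean, exact.mean, atol=1e-12)
        np.testing.assert_allclose(mix.cov, exact.cov, atol=1e-12)

    def test_weight_scaling_invariance(self, toy_series, priors):
        grid = fit_ccd(toy_series, priors)
        doubled = CCDGrid(
            points=grid.points, posterior_values=grid.posterior_values,
            weights=2.0 * grid.weights, mode=grid.mode, hessian=grid.hessian,
            log_joints=grid.log_joints, free=grid.free,
        )
        tstar = np.array([10.0, 55.0])
        a = predictive_distribution(toy_series, tstar, grid)
        b = predictive_distribution(toy_series, tstar, doubled)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
        np.testing.assert_allclose(a.cov, b.cov, atol=1e-12)

    def test_two_point_mixture_matches_manual_average(self, toy_series):
        hp1 = Hyperparameters(20.0, 1.0, 0.1)
        hp2 = Hyperparameters(40.0, 2.0, 0.05)
        grid = CCDGrid(
            points=[hp1, hp2], posterior_values=np.array([1.0, 0.5]),
            weights=np.array([2.0, 2.0]), mode=hp1, hessian=np.eye(3),
            log_joints=np.zeros(2),
        )
        tstar = np.array([5.0, 60.0])
        mix = predictive_distribution(toy_series, tstar, grid)
        p1 = gp_posterior(toy_series, tstar, hp1)
        p2 = gp_posterior(toy_series, tstar, hp2)
        w = np.array([2.0, 1.0]) / 3.0  # q * Delta renormalised
        np.testing.assert_allclose(mix.mean, w[0] * p1.mean + w[1] * p2.mean, atol=1e-12)
        np.testing.assert_allclose(mix.cov, w[0] * p1.cov + w[1] * p2.cov, atol=1e-12)

    def test_mixture_covariance_psd(self, toy_series, priors):
        grid = fit_ccd(toy_series, priors)
        mix = predictive_distribution(toy_series, np.linspace(0, 110, 30), grid)
        assert np.linalg.eigvalsh(mix.cov).min() > -1e-8
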