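"""GP regression: kernel construction, MLL fitting, posterior and derivative."""

import numpy as np
import pytest

from gpclust import (
    GPHyperparams,
    TimeCourse,
    derivative_marginals,
    fit_gp,
    marginal_log_likelihood,
    nonstationary_kernel_matrix,
    posterior_marginals,
)
from gpclust.gp import GPModel, default_grid


def dense_mll(y, K, noise_var):
    """Brute-force marginal log likelihood with plain dense algebra."""
    A = K + np.diag(noise_var)
    sign, logdet = np.linalg.slogdet(A)
    assert sign > 0
    return -0.5 * y @ np.linalg.solve(A, y) - 0.5 * logdet - 0.5 * y.size * np.log(2 * np.pi)


class TestKernelMatrix:
    def test_diagonal_is_signal_variance(self):
        h = GPHyperparams(sigma_f=1.7, l_max=3.0, l_min=1.0, c=0.5)
        K = nonstationary_kernel_matrix([1.0, 2.0], [1.0, 2.0], h)
        assert np.allclose(np.diag(K), h.sigma_f**2)

    def test_c_zero_reduces_to_stationary(self):
        h = GPHyperparams(sigma_f=1.3, l_max=5.0, l_min=2.0, c=0.0)
        t = np.linspace(0, 10, 9)
        K = nonstationary_kernel_matrix(t, t, h)
        expected = h.sigma_f**2 * np.exp(-(((t[:, None] - t[None, :]) / h.l_min) ** 2))
        assert np.allclose(K, expected)

    def test_hand_evaluated_entry(self):
        h = GPHyperparams(sigma_f=1.0, l_max=2.0, l_min=2.0, c=0.0)
        K = nonstationary_kernel_matrix([0.0], [2.0], h)
        assert K[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    @pytest.mark.parametrize("transform", ["parametric", "log"])
    def test_symmetric_psd(self, transform):
        rng = np.random.default_rng(0)
        h = GPHyperparams(sigma_f=2.0, l_max=4.0, l_min=1.5, c=0.3)
        for _ in range(5):
            t = np.sort(rng.uniform(0.1, 20.0, size=15))
            K = nonstationary_kernel_matrix(t, t, h, transform=transform)
            assert np.allclose(K, K.T)
            ev = np.linalg.eigvalsh(K)
            assert ev.min() >= -1e-6 * np.trace(K)

    def test_log_transform_rejects_nonpositive_times(self):
        h = GPHyperparams(sigma_f=1.0, l_max=2.0, l_min=1.0, c=0.1)
        with pytest.raises(ValueError):
            nonstationary_kernel_matrix([0.0, 1.0], [1.0], h, transform="log")

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            GPHyperparams(sigma_f=1.0, l_max=-1.0, l_min=0.5, c=0.0)
        with pytest.raises(ValueError):
            GPHyperparams(sigma_f=1.0, l_max=1.0, l_min=2.0, c=0.0)


class TestMLL:
    def test_matches_dense_evaluation_on_random_instances(self):
        rng = np.random.default_rng(5)
        for n in (5, 17, 50):
            t = np.sort(rng.uniform(0, 20, size=n))
            t += np.arange(n) * 1e-6  # guard against ties
            y = rng.standard_normal((n, 1))
            nv = rng.uniform(0.05, 0.5, size=n)
            tc = TimeCourse("g", "c", t, y, noise_var=nv)
            h = GPHyperparams(sigma_f=1.4, l_max=5.0, l_min=2.0, c=0.2)
            K = nonstationary_kernel_matrix(t, t, h)
            assert marginal_log_likelihood(tc, h) == pytest.approx(
                dense_mll(y[:, 0], K, nv), rel=1e-9
            )

    def test_fitted_mll_recomputable(self, smooth_model):
        assert smooth_model.mll == pytest.approx(
            marginal_log_likelihood(smooth_model.timecourse, smooth_model.hyper),
            rel=1e-7,
        )


class TestFit:
    def test_reproducible_given_seed(self, smooth_model):
        refit = fit_gp(smooth_model.timecourse, seed=2)
        assert refit.hyper == smooth_model.hyper
        assert refit.mll == smooth_model.mll

    def test_beats_random_hyperparameter_draws(self, smooth_model):
        rng = np.random.default_rng(11)
        tc = smooth_model.timecourse
        for _ in range(100):
            lmin = rng.uniform(0.1, 10.0)
            h = GPHyperparams(
                sigma_f=rng.uniform(0.05, 10.0),
                l_max=lmin + rng.uniform(0.0, 10.0),
                l_min=lmin,
                c=rng.uniform(0.0, 2.0),
            )
            assert marginal_log_likelihood(tc, h) <= smooth_model.mll + 1e-8

    def test_recovers_known_hyperparameters(self):
        # simulate from a stationary GP with known theta and refit
        rng = np.random.default_rng(21)
        t = np.linspace(0, 20, 40)
        true = GPHyperparams(sigma_f=2.0, l_max=3.0, l_min=3.0, c=0.0)
        K = nonstationary_kernel_matrix(t, t, true)
        y = np.linalg.cholesky(K + 1e-10 * np.eye(40)) @ rng.standard_normal(40)
        noise = 0.05
        yobs = y + noise * rng.standard_normal(40)
        tc = TimeCourse("sim", "c", t, yobs[:, None], noise_var=np.full(40, noise**2))
        model = fit_gp(tc, seed=0, stationary=True, n_restarts=5)
        assert abs(model.hyper.sigma_f - true.sigma_f) / true.sigma_f < 0.5
        assert abs(model.hyper.l_max - true.l_max) / true.l_max < 0.5

    def test_requires_two_time_points(self):
        tc = TimeCourse("g", "c", [1.0], [[1.0, 1.1]])
        with pytest.raises(ValueError):
            fit_gp(tc)


class TestPosterior:
    def test_matches_direct_formula(self, smooth_model):
        tc = smooth_model.timecourse
        h = smooth_model.hyper
        grid = np.linspace(0.2, 11.5, 23)
        Kst = nonstationary_kernel_matrix(grid, tc.times, h)
        A = nonstationary_kernel_matrix(tc.times, tc.times, h) + np.diag(tc.noise_var)
        Ainv = np.linalg.inv(A)
        mu = Kst @ Ainv @ tc.mean_values
        Kss = nonstationary_kernel_matrix(grid, grid, h)
        var = np.diag(Kss - Kst @ Ainv @ Kst.T)
        pm = posterior_marginals(smooth_model, grid)
        assert np.allclose(pm.mean, mu, atol=1e-8)
        assert np.allclose(pm.var, np.clip(var, 0, None), atol=1e-8)

    def test_noiseless_gp_interpolates(self):
        t = np.linspace(0, 5, 6)
        y = np.array([0.0, 1.0, 0.5, -0.2, 0.3, 0.8])
        tc = TimeCourse("g", "c", t, y[:, None], noise_var=np.full(6, 1e-10))
        h = GPHyperparams(sigma_f=1.0, l_max=2.0, l_min=2.0, c=0.0)
        model = GPModel(hyper=h, timecourse=tc, mll=marginal_log_likelihood(tc, h))
        pm = posterior_marginals(model, t)
        assert np.allclose(pm.mean, y, atol=1e-4)

    def test_variance_bounded_by_prior(self, smooth_model):
        pm = posterior_marginals(smooth_model, default_grid(0, 12, 0.5))
        assert np.all(pm.var <= smooth_model.hyper.sigma_f**2 + 1e-10)

    def test_variance_shrinks_with_more_observations(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 10, 11)
        y = rng.standard_normal(11)
        h = GPHyperparams(sigma_f=1.0, l_max=3.0, l_min=3.0, c=0.0)
        grid = np.linspace(0, 10, 31)
        variances = []
        for n in (4, 7, 11):
            tc = TimeCourse("g", "c", t[:n], y[:n, None], noise_var=np.full(n, 0.1))
            m = GPModel(hyper=h, timecourse=tc, mll=marginal_log_likelihood(tc, h))
            variances.append(posterior_marginals(m, grid).var)
        assert np.all(variances[1] <= variances[0] + 1e-9)
        assert np.all(variances[2] <= variances[1] + 1e-9)

    def test_noisy_variant_adds_noise_level(self, smooth_model):
        grid = smooth_model.timecourse.times
        plain = posterior_marginals(smooth_model, grid)
        noisy = posterior_marginals(smooth_model, grid, include_noise=True)
        assert np.all(noisy.var >= plain.var)
        assert np.allclose(
            noisy.var - plain.var, smooth_model.timecourse.noise_var, atol=1e-10
        )

    def test_empty_grid_rejected(self, smooth_model):
        with pytest.raises(ValueError):
            posterior_marginals(smooth_model, [])


class TestDerivative:
    def test_slope_recovered_on_linear_data(self, linear_model):
        grid = np.linspace(1.0, 9.0, 17)
        dm = derivative_marginals(linear_model, grid)
        assert np.all(np.abs(dm.mean - 2.0) < 0.1)

    def test_constant_data_gives_zero_derivative(self):
        t = np.linspace(0, 8, 9)
        tc = TimeCourse("g", "c", t, np.full((9, 3), 3.0), noise_var=np.full(9, 1e-4))
        m = fit_gp(tc, seed=0)
        dm = derivative_marginals(m, np.linspace(1, 7, 13))
        assert np.all(np.abs(dm.mean) < 1e-3)

    def test_matches_central_finite_differences(self, smooth_model):
        grid = np.linspace(0.5, 11.5, 23)
        dm = derivative_marginals(smooth_model, grid)
        h = 1e-5
        up = posterior_marginals(smooth_model, grid + h).mean
        dn = posterior_marginals(smooth_model, grid - h).mean
        fd = (up - dn) / (2 * h)
        assert np.allclose(dm.mean, fd, atol=1e-5)

    def test_variance_nonnegative(self, smooth_model):
        dm = derivative_marginals(smooth_model, np.linspace(0, 12, 25))
        assert np.all(dm.var >= 0)


def test_model_serialization_roundtrip(smooth_model):
    text = smooth_model.to_text()
    kv = dict(line.split("\t") for line in text.strip().splitlines())
    assert float(kv["sigma_f"]) == pytest.approx(smooth_model.hyper.sigma_f)
    assert float(kv["mll"]) == pytest.approx(smooth_model.mll)
    assert kv["gene_id"] == "smooth"
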