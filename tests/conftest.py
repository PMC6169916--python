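import numpy as np
import pytest

from gpclust import (
    GPHyperparams,
    MarginalCurve,
    TimeCourse,
    fit_gp,
    posterior_marginals,
)


@pytest.fixture(scope="session")
def linear_model():
    """GP fitted to a nearly noiseless straight line of slope 2."""
    rng = np.random.default_rng(7)
    times = np.linspace(0.0, 10.0, 15)
    reps = 5.0 + 2.0 * times[:, None] + 0.02 * rng.standard_normal((15, 3))
    tc = TimeCourse("lin", "case", times, reps)
    return fit_gp(tc, seed=1)


@pytest.fixture(scope="session")
def smooth_model():
    """GP fitted to a smooth oscillating time course."""
    rng = np.random.default_rng(3)
    times = np.linspace(0.0, 12.0, 20)
    y = np.sin(times / 2.0) + 0.5 * np.cos(times / 3.0)
    reps = y[:, None] + 0.05 * rng.standard_normal((20, 3))
    tc = TimeCourse("smooth", "case", times, reps)
    return fit_gp(tc, seed=2)


@pytest.fixture(scope="session")
def curve_pair(smooth_model, linear_model):
    """Two marginal curves on one shared grid."""
    grid = np.linspace(0.5, 9.5, 37)
    return (
        posterior_marginals(smooth_model, grid),
        posterior_marginals(linear_model, grid),
    )


def random_gaussian_pairs(n, seed=0, mu_scale=3.0, var_range=(0.05, 4.0)):
    """Random (mu1, var1, mu2, var2) tuples for kernel property checks."""
    rng = np.random.default_rng(seed)
    mu = mu_scale * rng.standard_normal((n, 2))
    var = rng.uniform(*var_range, size=(n, 2))
    return mu[:, 0], var[:, 0], mu[:, 1], var[:, 1]


def make_curve(grid, mean, var):
    return MarginalCurve(np.asarray(grid, float), np.asarray(mean, float), np.asarray(var, float))
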