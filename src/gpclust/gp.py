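"""Gaussian-process regression of time-course expression.

Each gene/condition time course is modelled as ``y_t = f(t) + eps_t`` with a
GP prior ``f ~ N(0, K)`` and heteroscedastic observation noise
``eps_t ~ N(0, omega_t^2)`` taken from the replicate variances.  The prior
covariance is the non-stationary squared-exponential

    K(t, t') = sigma_f^2 exp(-(u(t) - u(t'))^2),

where the warped time is ``u(t) = t / l(t)`` with the parametric lengthscale
schedule ``l(t) = l_max - (l_max - l_min) e^(-c t)`` (the default), or
``u(t) = log(t) / l_max`` for strictly positive times.  With ``c = 0`` the
parametric schedule collapses to a stationary kernel with lengthscale
``l_min``.  Hyperparameters are learned by maximizing the marginal log
likelihood with multi-start L-BFGS-B in log-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .kernels import interval_weights
from .timecourse import TimeCourse

__all__ = [
    "GPHyperparams",
    "GPModel",
    "MarginalCurve",
    "FittingError",
    "nonstationary_kernel_matrix",
    "marginal_log_likelihood",
    "fit_gp",
    "posterior_marginals",
    "derivative_marginals",
    "default_grid",
]


class FittingError(RuntimeError):
    """Raised when optimization fails on every restart.

    Carries the best model found so far in ``best`` (may be ``None``).
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class GPHyperparams:
    """Kernel hyperparameters theta = (sigma_f, l_max, l_min, c).

    ``sigma_f`` is the signal standard deviation, ``l_max``/``l_min`` the
    asymptotic and initial lengthscales in days, and ``c`` (1/days) the rate
    at which the lengthscale relaxes from ``l_min`` at t=0 to ``l_max``.
    """

    sigma_f: float
    l_max: float
    l_min: float
    c: float = 0.0

    def __post_init__(self):
        if not all(np.isfinite([self.sigma_f, self.l_max, self.l_min, self.c])):
            raise ValueError("hyperparameters must be finite")
        if self.sigma_f <= 0 or self.l_max <= 0 or self.l_min <= 0:
            raise ValueError("sigma_f, l_max, l_min must be positive")
        if self.l_min > self.l_max * (1 + 1e-12):
            raise ValueError("l_min must not exceed l_max")
        if self.c < 0:
            raise ValueError("curvature c must be non-negative")


@dataclass
class MarginalCurve:
    """A GP summarized by its marginal moments on a prediction grid.

    ``weights`` are the interval lengths Delta t_i used by the GP kernels;
    they sum to ``span``, the total window length.
    """

    grid: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    weights: np.ndarray = field(default=None)
    span: float = field(default=None)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.clip(np.asarray(self.var, dtype=float), 0.0, None)
        if not (self.grid.shape == self.mean.shape == self.var.shape):
            raise ValueError("grid, mean and var must have equal shapes")
        if self.weights is None:
            self.weights, self.span = interval_weights(self.grid)
        else:
            self.weights = np.asarray(self.weights, dtype=float)

    def restrict(self, start: float, end: float) -> "MarginalCurve":
        """Restrict the curve to grid points inside ``[start, end]``."""
        sel = (self.grid >= start - 1e-12) & (self.grid <= end + 1e-12)
        if sel.sum() < 2:
            raise ValueError(f"window [{start}, {end}] contains fewer than 2 grid points")
        return MarginalCurve(self.grid[sel], self.mean[sel], self.var[sel])


def default_grid(start: float = 0.0, stop: float = 24.0, step: float = 0.25) -> np.ndarray:
    """Default prediction grid: days 0 to 24 in steps of 0.25."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


# ---------------------------------------------------------------------------
# kernel construction


def _lengthscale(t, hyper: GPHyperparams):
    return hyper.l_max - (hyper.l_max - hyper.l_min) * np.exp(-hyper.c * t)


def _warp(t, hyper: GPHyperparams, transform: str):
    t = np.asarray(t, dtype=float)
    if transform == "parametric":
        return t / _lengthscale(t, hyper)
    if transform == "log":
        if np.any(t <= 0):
            raise ValueError("log transform requires strictly positive times")
        return np.log(t) / hyper.l_max
    raise ValueError(f"unknown transform {transform!r}")


def _warp_deriv(t, hyper: GPHyperparams, transform: str):
    """du/dt of the time warp."""
    t = np.asarray(t, dtype=float)
    if transform == "parametric":
        l = _lengthscale(t, hyper)
        dl = hyper.c * (hyper.l_max - hyper.l_min) * np.exp(-hyper.c * t)
        return (l - t * dl) / l**2
    if transform == "log":
        if np.any(t <= 0):
            raise ValueError("log transform requires strictly positive times")
        return 1.0 / (t * hyper.l_max)
    raise ValueError(f"unknown transform {transform!r}")


def nonstationary_kernel_matrix(
    times_a, times_b, hyper: GPHyperparams, transform: str = "parametric"
) -> np.ndarray:
    """Non-stationary squared-exponential kernel matrix between two time sets.

    Entries are ``sigma_f^2 exp(-(u(t) - u(t'))^2)``; symmetric when the two
    time sets coincide, and equal to a stationary Gaussian kernel with
    lengthscale ``l_min`` when ``c = 0``.
    """
    ua = _warp(np.asarray(times_a, float), hyper, transform)
    ub = _warp(np.asarray(times_b, float), hyper, transform)
    d = ua[:, None] - ub[None, :]
    return hyper.sigma_f**2 * np.exp(-(d**2))


# ---------------------------------------------------------------------------
# marginal likelihood


def _noisy_cov(tc: TimeCourse, hyper, transform):
    K = nonstationary_kernel_matrix(tc.times, tc.times, hyper, transform)
    return K, K + np.diag(tc.noise_var)


def _chol_with_jitter(A: np.ndarray):
    """Cholesky with escalating diagonal jitter; raises if still singular."""
    scale = np.trace(A) / A.shape[0]
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return cho_factor(A + jitter * scale * np.eye(A.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix singular even after jitter")


def marginal_log_likelihood(
    tc: TimeCourse, hyper: GPHyperparams, transform: str = "parametric"
) -> float:
    """Marginal log likelihood log p(y | T, theta) of the replicate means."""
    y = tc.mean_values
    _, A = _noisy_cov(tc, hyper, transform)
    cf = _chol_with_jitter(A)
    alpha = cho_solve(cf, y)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * y.size * np.log(2 * np.pi))


@dataclass
class GPModel:
    """A fitted GP regression model for one time course."""

    hyper: GPHyperparams
    timecourse: TimeCourse
    mll: float
    transform: str = "parametric"

    def __post_init__(self):
        K, A = _noisy_cov(self.timecourse, self.hyper, self.transform)
        self._cf = _chol_with_jitter(A)
        self._alpha = cho_solve(self._cf, self.timecourse.mean_values)

    def to_text(self) -> str:
        """Serialize hyperparameters and fit summary as key/value lines."""
        h = self.hyper
        lines = [
            f"gene_id\t{self.timecourse.gene_id}",
            f"condition\t{self.timecourse.condition}",
            f"transform\t{self.transform}",
            f"sigma_f\t{h.sigma_f:.10g}",
            f"l_max\t{h.l_max:.10g}",
            f"l_min\t{h.l_min:.10g}",
            f"c\t{h.c:.10g}",
            f"mll\t{self.mll:.10g}",
        ]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# fitting

_BOUNDS = {
    "sigma_f": (1e-3, 1e3),
    "l_min": (0.05, 50.0),
    "gap": (1e-4, 100.0),
    "c": (1e-4, 10.0),
}


def _pack(hyper: GPHyperparams, stationary: bool) -> np.ndarray:
    if stationary:
        return np.log([hyper.sigma_f, hyper.l_min])
    gap = max(hyper.l_max - hyper.l_min, _BOUNDS["gap"][0])
    return np.log([hyper.sigma_f, hyper.l_min, gap, max(hyper.c, _BOUNDS["c"][0])])


def _unpack(x: np.ndarray, stationary: bool) -> GPHyperparams:
    v = np.exp(x)
    if stationary:
        return GPHyperparams(sigma_f=v[0], l_max=v[1], l_min=v[1], c=0.0)
    return GPHyperparams(sigma_f=v[0], l_max=v[1] + v[2], l_min=v[1], c=v[3])


def _mll_and_grad(x, tc: TimeCourse, stationary: bool, transform: str):
    """Negative MLL and its gradient in the log-space parametrization.

    Uses d(MLL)/d(theta_j) = 1/2 tr((alpha alpha^T - A^{-1}) dK/dtheta_j)
    with analytic kernel derivatives.
    """
    hyper = _unpack(x, stationary)
    y = tc.mean_values
    t = tc.times
    K, A = _noisy_cov(tc, hyper, transform)
    cf = _chol_with_jitter(A)
    alpha = cho_solve(cf, y)
    Ainv = cho_solve(cf, np.eye(t.size))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    nll = 0.5 * y @ alpha + 0.5 * logdet + 0.5 * y.size * np.log(2 * np.pi)

    W = np.outer(alpha, alpha) - Ainv  # d(MLL)/dK weight matrix (x2)
    u = _warp(t, hyper, transform)
    D = u[:, None] - u[None, :]

    def du_dtheta(dl_dtheta):
        # u = t / l(t)  =>  du/dtheta = -t * dl/dtheta / l^2
        l = _lengthscale(t, hyper)
        return -t * dl_dtheta / l**2

    grads = []
    # d/d log sigma_f : dK = 2K
    grads.append(0.5 * np.sum(W * (2.0 * K)))
    ect = np.exp(-hyper.c * t)
    gap = hyper.l_max - hyper.l_min
    if stationary:
        if transform == "log":
            du = -np.log(t) / hyper.l_max**2
        else:
            du = du_dtheta(np.ones_like(t))
        dK = K * (-2.0 * D) * (du[:, None] - du[None, :])
        grads.append(0.5 * np.sum(W * dK) * hyper.l_min)  # chain rule for log l
    else:
        if transform == "log":
            raise ValueError("log transform supports stationary fitting only")
        # l(t) = l_min + gap * (1 - e^{-ct})
        for dl, theta in (
            (np.ones_like(t), hyper.l_min),  # d/d l_min
            (1.0 - ect, gap),  # d/d gap
            (gap * t * ect, max(hyper.c, _BOUNDS["c"][0])),  # d/d c
        ):
            du = du_dtheta(dl)
            dK = K * (-2.0 * D) * (du[:, None] - du[None, :])
            grads.append(0.5 * np.sum(W * dK) * theta)
    return nll, -np.asarray(grads)


def _default_init(tc: TimeCourse) -> GPHyperparams:
    y = tc.mean_values
    span = float(tc.times[-1] - tc.times[0])
    sf = float(np.std(y)) or 1.0
    return GPHyperparams(sigma_f=sf, l_max=span / 3.0, l_min=span / 6.0, c=0.2)


def fit_gp(
    tc: TimeCourse,
    hyper_init: GPHyperparams | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    transform: str = "parametric",
    stationary: bool = False,
    maxiter: int = 200,
) -> GPModel:
    """Fit kernel hyperparameters by multi-start L-BFGS-B on the MLL.

    The first start is ``hyper_init`` (or a data-driven default); the
    remaining ``n_restarts - 1`` starts are log-uniform draws from the box
    bounds, seeded by ``seed``.  ``stationary=True`` fixes ``c = 0`` and
    ``l_min = l_max``, fitting only (sigma_f, l).  Returns the restart with
    the highest achieved MLL; deterministic given the seed.
    """
    if tc.n_times < 2:
        raise ValueError("need at least 2 time points to fit a GP")
    if hyper_init is None:
        hyper_init = _default_init(tc)
    rng = np.random.default_rng(seed)
    if stationary:
        names = ("sigma_f", "l_min")
    else:
        names = ("sigma_f", "l_min", "gap", "c")
    lo = np.log([_BOUNDS[n][0] for n in names])
    hi = np.log([_BOUNDS[n][1] for n in names])
    starts = [_pack(hyper_init, stationary)]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.uniform(lo, hi))

    best = None
    n_fail = 0
    for x0 in starts:
        res = minimize(
            _mll_and_grad,
            np.clip(x0, lo, hi),
            args=(tc, stationary, transform),
            method="L-BFGS-B",
            jac=True,
            bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter},
        )
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FittingError("optimizer failed on every restart", best=None)
    hyper = _unpack(best.x, stationary)
    mll = -float(best.fun)
    # never return worse than the explicit initial point
    mll_init = marginal_log_likelihood(tc, hyper_init, transform)
    if mll_init > mll:
        hyper, mll = hyper_init, mll_init
    return GPModel(hyper=hyper, timecourse=tc, mll=mll, transform=transform)


# ---------------------------------------------------------------------------
# prediction


def posterior_marginals(
    model: GPModel, grid, include_noise: bool = False
) -> MarginalCurve:
    """Marginal posterior mean and variance of the latent function on a grid.

    With ``include_noise=True`` the observational noise variance
    (interpolated between observed time points) is added to the marginal
    variances, giving the complete noisy kinetic model.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty prediction grid")
    tc = model.timecourse
    Kst = nonstationary_kernel_matrix(grid, tc.times, model.hyper, model.transform)
    mean = Kst @ model._alpha
    v = cho_solve(model._cf, Kst.T)
    var = model.hyper.sigma_f**2 - np.einsum("ij,ji->i", Kst, v)
    if include_noise:
        var = var + np.interp(grid, tc.times, tc.noise_var)
    return MarginalCurve(grid=grid, mean=mean, var=var)


def derivative_marginals(model: GPModel, grid) -> MarginalCurve:
    """Marginal mean and variance of the derivative GP df/dt on a grid.

    Differentiation is a linear operator, so the derivative process is again
    a GP whose cross-covariance with the observations is the analytic
    derivative of the kernel with respect to the prediction time.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty prediction grid")
    tc = model.timecourse
    h, tr = model.hyper, model.transform
    ug = _warp(grid, h, tr)
    uo = _warp(tc.times, h, tr)
    dug = _warp_deriv(grid, h, tr)
    D = ug[:, None] - uo[None, :]
    Kst = h.sigma_f**2 * np.exp(-(D**2))
    dKst = -2.0 * D * dug[:, None] * Kst  # d/dt_star K(t_star, t_obs)
    mean = dKst @ model._alpha
    # prior derivative variance: d2/dt dt' K at t=t' -> 2 sigma_f^2 u'(t)^2
    prior = 2.0 * h.sigma_f**2 * dug**2
    v = cho_solve(model._cf, dKst.T)
    var = prior - np.einsum("ij,ji->i", dKst, v)
    return MarginalCurve(grid=grid, mean=mean, var=var)
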