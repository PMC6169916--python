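"""Similarity kernels between Gaussian processes.

Two GPs summarized by their marginal means and variances on a shared time
grid are compared by a time-weighted mean of a pointwise kernel between the
marginal Gaussians,

    K_N(p, p') = (1/DT) sum_i Dt_i K(p_i, p'_i),

with interval weights ``Dt_i = (t_{i+1} - t_{i-1})/2`` (half intervals at the
ends) and ``DT`` the window span.  Pointwise families:

* ``BH``  - Bhattacharyya kernel, the probability-product kernel with
  exponent 1/2; self-similarity 1.
* ``EL``  - expected-likelihood kernel, exponent 1 (the expectation of one
  density under the other); not normalized.
* ``KL``  - symmetric Kullback-Leibler divergence, exponentiated at the
  curve level as ``exp(-alpha/(2 DT) sum_i Dt_i d_i + beta)``.
* ``OVL`` - overlapping coefficient, the integral of the pointwise minimum
  of the two densities; in [0, 1], computed in closed form from at most two
  density crossing points.

A mixture kernel blends the value kernel with the same kernel applied to
the derivative GPs, comparing both the variable and its rate of change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "KernelSpec",
    "GPKernelMatrix",
    "interval_weights",
    "pointwise_kernel",
    "gp_kernel",
    "mixture_kernel",
    "kernel_matrix",
    "resample_curve",
]

_FAMILIES = ("OVL", "BH", "EL", "KL")
_EQ_TOL = 1e-12  # branch tolerance for the OVL special cases


@dataclass(frozen=True)
class KernelSpec:
    """Configuration of a GP kernel family.

    ``kl_alpha``/``kl_beta`` are the scale and shift of the exponentiated
    symmetric-KL kernel; ``mixture_ratio`` is the weight on the value kernel
    in the value/derivative mixture (1 = values only).
    """

    family: str = "OVL"
    kl_alpha: float = 1.0
    kl_beta: float = 0.0
    mixture_ratio: float = 1.0
    use_derivatives: bool = False

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.kl_alpha <= 0:
            raise ValueError("kl_alpha must be positive")
        if not 0.0 <= self.mixture_ratio <= 1.0:
            raise ValueError("mixture_ratio must lie in [0, 1]")

    def to_config(self) -> str:
        return (
            f"family\t{self.family}\nkl_alpha\t{self.kl_alpha:.10g}\n"
            f"kl_beta\t{self.kl_beta:.10g}\nmixture_ratio\t{self.mixture_ratio:.10g}\n"
            f"use_derivatives\t{int(self.use_derivatives)}\n"
        )

    @classmethod
    def from_config(cls, text: str) -> "KernelSpec":
        kv = dict(line.split("\t") for line in text.strip().splitlines())
        return cls(
            family=kv["family"],
            kl_alpha=float(kv.get("kl_alpha", 1.0)),
            kl_beta=float(kv.get("kl_beta", 0.0)),
            mixture_ratio=float(kv.get("mixture_ratio", 1.0)),
            use_derivatives=bool(int(kv.get("use_derivatives", 0))),
        )


def interval_weights(grid) -> tuple[np.ndarray, float]:
    """Interval lengths Dt_i for the time-weighted kernel mean.

    Interior points get ``(t_{i+1} - t_{i-1})/2``; the first and last points
    get half of their single adjacent interval.  The weights sum to the span
    ``DT = t_N - t_1``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be 1-D with at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    w = np.empty_like(grid)
    w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    return w, float(grid[-1] - grid[0])


# ---------------------------------------------------------------------------
# pointwise kernels between 1-D Gaussians (vectorized)


def _bhattacharyya(mu1, var1, mu2, var2):
    s = var1 + var2
    return np.sqrt(2.0 * np.sqrt(var1 * var2) / s) * np.exp(-((mu1 - mu2) ** 2) / (4.0 * s))


def _expected_likelihood(mu1, var1, mu2, var2):
    s = var1 + var2
    return np.exp(-((mu1 - mu2) ** 2) / (2.0 * s)) / np.sqrt(2.0 * np.pi * s)


def _sym_kl(mu1, var1, mu2, var2):
    """Two-way symmetric KL divergence; the log-variance terms cancel."""
    d2 = (mu1 - mu2) ** 2
    return 0.5 * ((d2 + var1) / var2 + (d2 + var2) / var1 - 2.0)


def _ovl(mu1, var1, mu2, var2):
    """Overlapping coefficient of two Gaussians, closed form.

    General case: the two densities cross at the roots z1 < z2 of a
    quadratic; the overlap is assembled from the smaller CDF mass on each of
    the three intervals.  Equal variances give a single crossing, and fully
    identical parameters give 1 — both handled as explicit branches.
    """
    mu1, var1, mu2, var2 = np.broadcast_arrays(
        *map(np.asarray, (mu1, var1, mu2, var2))
    )
    mu1 = mu1.astype(float); var1 = var1.astype(float)
    mu2 = mu2.astype(float); var2 = var2.astype(float)
    out = np.empty(mu1.shape, dtype=float)

    eqv = np.abs(var1 - var2) < _EQ_TOL
    eqm = eqv & (np.abs(mu1 - mu2) < _EQ_TOL)

    # equal-variance branch: single crossing at the midpoint of the means
    sd = np.sqrt(np.where(var1 > 0, var1, 1.0))
    out_eq = 2.0 * ndtr(-np.abs(mu1 - mu2) / (2.0 * sd))

    # general branch (safe denominators where eqv)
    v1 = np.where(eqv, var1 + 1.0, var1)
    v2 = np.where(eqv, var2 + 2.0, var2)
    A = 0.5 / v2 - 0.5 / v1
    B = mu1 / v1 - mu2 / v2
    C = mu2**2 / (2.0 * v2) - mu1**2 / (2.0 * v1) + 0.5 * np.log(v2 / v1)
    disc = np.sqrt(np.clip(B**2 - 4.0 * A * C, 0.0, None))
    r1 = (-B - disc) / (2.0 * A)
    r2 = (-B + disc) / (2.0 * A)
    z1 = np.minimum(r1, r2)
    z2 = np.maximum(r1, r2)
    s1 = np.sqrt(v1)
    s2 = np.sqrt(v2)
    F1a = ndtr((z1 - mu1) / s1)
    F1b = ndtr((z2 - mu1) / s1)
    F2a = ndtr((z1 - mu2) / s2)
    F2b = ndtr((z2 - mu2) / s2)
    gen = (
        np.minimum(F1a, F2a)
        + np.minimum(F1b - F1a, F2b - F2a)
        + np.minimum(1.0 - F1b, 1.0 - F2b)
    )
    out = np.where(eqv, out_eq, gen)
    out = np.where(eqm, 1.0, out)
    return np.clip(out, 0.0, 1.0)


_POINTWISE = {
    "BH": _bhattacharyya,
    "EL": _expected_likelihood,
    "OVL": _ovl,
    "KL": _sym_kl,
}


def pointwise_kernel(mu1, var1, mu2, var2, family: str = "OVL", **params):
    """Pointwise kernel (or, for ``KL``, divergence) between two Gaussians.

    ``BH`` and ``OVL`` are 1 for identical Gaussians; ``EL`` is an
    unnormalized density value; ``KL`` returns the symmetric KL divergence
    (>= 0, zero iff identical), which the curve-level kernel exponentiates.
    """
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}")
    if np.any(np.asarray(var1) <= 0) or np.any(np.asarray(var2) <= 0):
        raise ValueError("variances must be positive")
    val = _POINTWISE[family](
        np.asarray(mu1, float), np.asarray(var1, float),
        np.asarray(mu2, float), np.asarray(var2, float),
    )
    return float(val) if np.ndim(val) == 0 else val


# ---------------------------------------------------------------------------
# curve-level kernels


def _check_grids(*curves):
    g0 = curves[0].grid
    for c in curves[1:]:
        if c.grid.shape != g0.shape or not np.allclose(c.grid, g0, atol=1e-9):
            raise ValueError("curves must share an identical grid (no silent resampling)")


def _curve_kernel_arrays(mu1, var1, mu2, var2, weights, span, spec: KernelSpec):
    """Weighted kernel along the last (grid) axis; broadcasts leading axes."""
    if spec.family == "KL":
        d = 2.0 * _sym_kl(mu1, var1, mu2, var2)
        dbar = np.sum(weights * d, axis=-1)
        return np.exp(-spec.kl_alpha / (2.0 * span) * dbar + spec.kl_beta)
    k = _POINTWISE[spec.family](mu1, var1, mu2, var2)
    return np.sum(weights * k, axis=-1) / span


def gp_kernel(a, b, spec: KernelSpec) -> float:
    """Time-weighted kernel between two marginal curves on one grid."""
    _check_grids(a, b)
    if np.any(a.var <= 0) or np.any(b.var <= 0):
        raise ValueError("marginal variances must be positive")
    w, span = a.weights, a.span
    return float(_curve_kernel_arrays(a.mean, a.var, b.mean, b.var, w, span, spec))


def mixture_kernel(a, b, a_deriv, b_deriv, spec: KernelSpec) -> float:
    """Convex mixture of the value kernel and the derivative kernel."""
    _check_grids(a, b, a_deriv, b_deriv)
    r = spec.mixture_ratio
    return r * gp_kernel(a, b, spec) + (1.0 - r) * gp_kernel(a_deriv, b_deriv, spec)


def resample_curve(curve, new_grid):
    """Explicitly resample a marginal curve onto a new grid (linear)."""
    from .gp import MarginalCurve

    new_grid = np.asarray(new_grid, dtype=float)
    mean = np.interp(new_grid, curve.grid, curve.mean)
    var = np.interp(new_grid, curve.grid, curve.var)
    return MarginalCurve(grid=new_grid, mean=mean, var=var)


@dataclass
class GPKernelMatrix:
    """A symmetric kernel matrix over a set of objects."""

    object_ids: list
    values: np.ndarray
    spec: KernelSpec
    psd_repaired: bool = False

    def to_tsv(self, path=None):
        df = pd.DataFrame(self.values, index=self.object_ids, columns=self.object_ids)
        if path is None:
            buf = StringIO()
            df.to_csv(buf, sep="\t")
            return buf.getvalue()
        df.to_csv(path, sep="\t")
        return None

    @classmethod
    def from_tsv(cls, path, spec: KernelSpec | None = None) -> "GPKernelMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            object_ids=[str(i) for i in df.index],
            values=df.to_numpy(dtype=float),
            spec=spec or KernelSpec(),
        )


def kernel_matrix(
    curves,
    spec: KernelSpec,
    deriv_curves=None,
    object_ids=None,
    repair_tol: float = 1e-8,
    block: int = 128,
) -> GPKernelMatrix:
    """Pairwise kernel matrix over marginal curves on a common grid.

    If ``spec.use_derivatives`` and derivative curves are supplied, each
    entry is the mixture kernel.  A numerically indefinite matrix (the KL
    family with small ``alpha`` can produce one) is repaired by clipping
    negative eigenvalues to zero; the repair is recorded in
    ``psd_repaired``.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    _check_grids(*curves)
    if np.any([np.any(c.var <= 0) for c in curves]):
        raise ValueError("marginal variances must be positive")
    w, span = curves[0].weights, curves[0].span
    M = np.stack([c.mean for c in curves])
    V = np.stack([c.var for c in curves])
    n = len(curves)

    def pairwise(Mv, Vv):
        out = np.empty((n, n))
        for i0 in range(0, n, block):
            i1 = min(i0 + block, n)
            out[i0:i1] = _curve_kernel_arrays(
                Mv[i0:i1, None, :], Vv[i0:i1, None, :],
                Mv[None, :, :], Vv[None, :, :], w, span, spec,
            )
        return out

    K = pairwise(M, V)
    if spec.use_derivatives and deriv_curves is not None:
        dc = list(deriv_curves)
        _check_grids(curves[0], *dc)
        Md = np.stack([c.mean for c in dc])
        Vd = np.stack([c.var for c in dc])
        K = spec.mixture_ratio * K + (1.0 - spec.mixture_ratio) * pairwise(Md, Vd)
    K = 0.5 * (K + K.T)  # enforce exact symmetry

    repaired = False
    evals = np.linalg.eigvalsh(K)
    if evals[0] < -repair_tol:
        lam, Q = np.linalg.eigh(K)
        K = (Q * np.clip(lam, 0.0, None)) @ Q.T
        K = 0.5 * (K + K.T)
        repaired = True
    if object_ids is None:
        object_ids = [getattr(c, "gene_id", str(i)) for i, c in enumerate(curves)]
    return GPKernelMatrix(
        object_ids=list(object_ids), values=K, spec=spec, psd_repaired=repaired
    )
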