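"""Spectral clustering with an outlier-resistant k-means variant.

A kernel matrix K over objects is turned into a graph Laplacian
``L = D - K`` (or its symmetric normalization ``D^{-1/2} L D^{-1/2}``); the
objects are embedded as rows of the k eigenvectors with smallest
eigenvalues, optionally row-normalized to unit length, and clustered there.

Clustering methods:

* ``kmeans``       - standard k-means (the trimmed loop with 0 outliers);
* ``kmeans_minus`` - k-means--: at each iteration the l points farthest
  from their nearest center are set aside as outliers, the rest are
  re-assigned, and centers are recomputed from the retained points;
* ``em``           - an EM mixture of k diagonal Gaussians plus one uniform
  outlier component over the bounding box of the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

__all__ = [
    "OUTLIER",
    "SpectralEmbedding",
    "ClusterResult",
    "graph_laplacian",
    "spectral_embed",
    "kmeans_minus",
    "em_outlier_cluster",
    "spectral_cluster",
]

#: Sentinel label for objects flagged as outliers.
OUTLIER = -1


@dataclass
class SpectralEmbedding:
    points: np.ndarray  # n x k rows = objects
    eigenvalues: np.ndarray  # k smallest Laplacian eigenvalues, ascending
    normalized: bool
    row_normalized: bool


@dataclass
class ClusterResult:
    """Labels (0..k-1 or OUTLIER), centers in embedding space, objective."""

    labels: np.ndarray
    centers: np.ndarray
    objective: float

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == OUTLIER))


def graph_laplacian(K: np.ndarray, normalized: bool = True, object_ids=None) -> np.ndarray:
    """Graph Laplacian L = D - K, optionally D^{-1/2} L D^{-1/2}."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("K must be symmetric")
    if np.any(K < -1e-12):
        raise ValueError("K must have nonnegative entries")
    d = K.sum(axis=1)
    zero = np.where(d <= 1e-300)[0]
    if zero.size:
        name = object_ids[zero[0]] if object_ids is not None else str(zero[0])
        raise ValueError(f"isolated vertex with zero degree: {name}")
    L = np.diag(d) - K
    if normalized:
        dinv = 1.0 / np.sqrt(d)
        L = dinv[:, None] * L * dinv[None, :]
    return 0.5 * (L + L.T)


def spectral_embed(
    K: np.ndarray,
    k: int,
    normalized: bool = True,
    row_normalize: bool = True,
    object_ids=None,
) -> SpectralEmbedding:
    """Embed objects as rows of the k smallest-eigenvalue eigenvectors.

    Column signs are fixed by making the entry of largest magnitude
    positive; rows are optionally scaled to unit length (the classical
    weighting step applied in the spectral domain).
    """
    n = K.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    L = graph_laplacian(K, normalized=normalized, object_ids=object_ids)
    w, V = eigh(L, subset_by_index=(0, k - 1))
    # deterministic column signs
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(k)])
    signs[signs == 0] = 1.0
    V = V * signs
    if row_normalize:
        norms = np.linalg.norm(V, axis=1, keepdims=True)
        V = np.where(norms > 1e-12, V / np.where(norms > 0, norms, 1.0), V)
    return SpectralEmbedding(
        points=V, eigenvalues=w, normalized=normalized, row_normalized=row_normalize
    )


# ---------------------------------------------------------------------------
# k-means-- in the embedding


def _kmeanspp(
    points: np.ndarray, k: int, rng: np.random.Generator, n_exclude: int = 0
) -> np.ndarray:
    """k-means++ seeding; with trimming active, the ``n_exclude`` currently
    most distant points are barred from becoming centers (they are the
    presumptive outliers, and plain D^2 sampling would otherwise pick them
    almost surely)."""
    n = points.shape[0]
    n_exclude = min(n_exclude, max(n - k, 0))
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(n)]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        w = d2.copy()
        if n_exclude > 0:
            w[np.argpartition(d2, n - n_exclude)[n - n_exclude:]] = 0.0
        total = w.sum()
        if total <= 0:
            centers[j] = points[rng.integers(n)]
        else:
            centers[j] = points[rng.choice(n, p=w / total)]
        d2 = np.minimum(d2, np.sum((points - centers[j]) ** 2, axis=1))
    return centers


def _trimmed_lloyd(points, centers, n_out, max_iter):
    """One k-means-- run from given centers; returns (labels, centers, obj)."""
    n, _ = points.shape
    k = centers.shape[0]
    prev = None
    obj = np.inf
    reseeded = False
    for _ in range(max_iter):
        d2 = cdist(points, centers, metric="sqeuclidean")
        nearest = np.argmin(d2, axis=1)
        nd2 = d2[np.arange(n), nearest]
        labels = nearest.copy()
        if n_out > 0:
            # the l points most distant from their nearest centers sit out
            out = np.argpartition(nd2, n - n_out)[n - n_out:]
            labels[out] = OUTLIER
        retained = labels != OUTLIER
        new_obj = float(nd2[retained].sum())
        # monotone except immediately after an empty-cluster re-seed
        assert reseeded or new_obj <= obj + 1e-9, "k-means-- objective increased"
        obj = new_obj
        if prev is not None and np.array_equal(labels, prev):
            break
        prev = labels.copy()
        reseeded = False
        for j in range(k):
            members = retained & (labels == j)
            if members.any():
                centers[j] = points[members].mean(axis=0)
            else:
                # documented fallback: re-seed from the farthest retained point
                far = np.argmax(np.where(retained, nd2, -np.inf))
                centers[j] = points[far]
                reseeded = True
    return labels, centers, obj


def kmeans_minus(
    points: np.ndarray,
    k: int,
    n_outliers: int = 0,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 100,
) -> ClusterResult:
    """Outlier-resistant k-means-- with k-means++ restarts.

    Exactly ``n_outliers`` objects carry the OUTLIER label in the returned
    result; with ``n_outliers=0`` this is plain k-means.  Deterministic
    given the seed; the best of ``n_init`` restarts (by trimmed objective)
    is returned.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= n_outliers < n - k + 1:
        raise ValueError("need n_outliers < n - k + 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers = _kmeanspp(points, k, rng, n_exclude=n_outliers)
        labels, centers, obj = _trimmed_lloyd(points, centers.copy(), n_outliers, max_iter)
        if best is None or obj < best[2]:
            best = (labels, centers, obj)
    labels, centers, obj = best
    return ClusterResult(labels=labels, centers=centers, objective=obj)


# ---------------------------------------------------------------------------
# EM mixture with a uniform outlier component


def em_outlier_cluster(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 3,
    max_iter: int = 200,
    tol: float = 1e-7,
    outlier_weight_init: float = 0.1,
) -> ClusterResult:
    """EM fit of k diagonal Gaussians plus a uniform outlier component.

    The outlier component is uniform over the bounding box of the points;
    objects whose posterior responsibility is highest for it are labelled
    OUTLIER.  Variances are floored (ridge) to avoid degeneracy.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n, d = points.shape
    if k < 1 or k > n:
        raise ValueError("k must be in [1, n]")
    lo, hi = points.min(axis=0), points.max(axis=0)
    widths = np.maximum(hi - lo, 1e-6)
    log_unif = -float(np.sum(np.log(widths)))
    var_floor = 1e-6 * float(np.mean(widths) ** 2)
    rng = np.random.default_rng(seed)

    best = None
    n_presumed_out = max(1, int(round(outlier_weight_init * n)))
    for _ in range(n_init):
        means = _kmeanspp(points, k, rng, n_exclude=n_presumed_out)
        var = np.tile(np.maximum(points.var(axis=0), var_floor), (k, 1))
        w = np.full(k + 1, (1.0 - outlier_weight_init) / k)
        w[-1] = outlier_weight_init
        prev_ll = -np.inf
        for _ in range(max_iter):
            logp = np.empty((n, k + 1))
            for j in range(k):
                diff2 = (points - means[j]) ** 2 / var[j]
                logp[:, j] = -0.5 * (diff2.sum(axis=1) + np.log(2 * np.pi * var[j]).sum())
            logp[:, k] = log_unif
            logp += np.log(w)
            m = logp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
            ll = float(lse.sum())
            resp = np.exp(logp - lse[:, None])
            nk = resp.sum(axis=0)
            w = nk / n
            for j in range(k):
                if nk[j] < 1e-12:
                    means[j] = points[rng.integers(n)]
                    var[j] = np.maximum(points.var(axis=0), var_floor)
                    continue
                means[j] = resp[:, j] @ points / nk[j]
                var[j] = np.maximum(
                    resp[:, j] @ (points - means[j]) ** 2 / nk[j], var_floor
                )
            if ll - prev_ll < tol * max(1.0, abs(ll)):
                prev_ll = ll
                break
            prev_ll = ll
        if best is None or prev_ll > best[0]:
            best = (prev_ll, means.copy(), resp.copy())
    ll, means, resp = best
    comp = np.argmax(resp, axis=1)
    labels = np.where(comp == k, OUTLIER, comp)
    return ClusterResult(labels=labels, centers=means, objective=-ll)


def spectral_cluster(
    K: np.ndarray,
    k: int,
    n_outliers: int = 0,
    method: str = "kmeans_minus",
    seed: int = 0,
    normalized: bool = True,
    row_normalize: bool = True,
    n_init: int = 10,
    object_ids=None,
) -> ClusterResult:
    """Spectral embedding of a kernel matrix followed by clustering."""
    emb = spectral_embed(
        K, k, normalized=normalized, row_normalize=row_normalize, object_ids=object_ids
    )
    if method == "kmeans":
        return kmeans_minus(emb.points, k, n_outliers=0, seed=seed, n_init=n_init)
    if method == "kmeans_minus":
        return kmeans_minus(emb.points, k, n_outliers=n_outliers, seed=seed, n_init=n_init)
    if method == "em":
        return em_outlier_cluster(emb.points, k, seed=seed)
    raise ValueError(f"unknown method {method!r}")
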