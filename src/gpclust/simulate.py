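"""Simulated benchmarks for GP kernels and clustering methods.

The cluster generator draws, for each of ``n_clusters`` clusters, kernel
hyperparameters from Gamma distributions,

    sigma_f_mu ~ Gam(4, 1/4),   sigma_f_cov ~ Gam(2, 1/2),
    l_mu ~ Gam(4, 3/2),         l_cov ~ Gam(4, 3/2)   (shape, scale),

then a cluster mean curve ``mu_i ~ N(0, sigma_f_mu K_{l_mu})`` and a cluster
covariance ``Sigma_i = sigma_f_cov^2 K_{l_cov}``, where ``K_l`` is the unit
Gaussian kernel ``exp(-((t-t')/l)^2)`` on the simulation grid.  Member time
series are multivariate-normal draws from their cluster; outlier series are
drawn the same way from fresh singleton clusters.  At the default sizes
(50 clusters, 300 members, 100 outliers) the outlier fraction is 25%.

Clusterings are scored by pair counting: precision is the fraction of
predicted co-clustered pairs that are truly co-clustered, recall the
fraction of true co-clustered pairs recovered, F1 their harmonic mean;
outliers count as singletons on both sides.  Metric-versus-k curves over a
sweep of cluster counts are summarized by the trapezoid area normalized by
the swept span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gp import MarginalCurve, fit_gp, posterior_marginals
from .kernels import KernelSpec, kernel_matrix
from .spectral import OUTLIER, ClusterResult, kmeans_minus, spectral_embed
from .timecourse import TimeCourse

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "BenchmarkTable",
    "simulate_dataset",
    "pair_metrics",
    "auc_over_k",
    "run_benchmark",
    "simulate_expression_study",
]


def _default_grid() -> np.ndarray:
    return np.linspace(0.0, 24.0, 25)


@dataclass(frozen=True)
class SimulationConfig:
    """Benchmark generator settings; Gamma parameters are (shape, scale)."""

    n_clusters: int = 50
    n_members: int = 300
    n_outliers: int = 100
    grid: np.ndarray = field(default_factory=_default_grid)
    sigma_f_mu: tuple = (4.0, 0.25)
    sigma_f_cov: tuple = (2.0, 0.5)
    l_mu: tuple = (4.0, 1.5)
    l_cov: tuple = (4.0, 1.5)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_clusters, self.n_members) < 1 or self.n_outliers < 0:
            raise ValueError("counts must be positive")
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "grid", g)


@dataclass
class SimulatedDataset:
    series: np.ndarray  # (n_members + n_outliers) x |grid|
    true_labels: np.ndarray  # cluster index or OUTLIER
    cluster_params: list  # per-cluster (mean vector, covariance)
    grid: np.ndarray


def _sq_kernel(grid: np.ndarray, l: float) -> np.ndarray:
    d = grid[:, None] - grid[None, :]
    return np.exp(-((d / l) ** 2))


def _mvn_draw(rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray, size=None):
    """Cholesky-based MVN sampling with jitter for borderline-PSD covariances."""
    n = cov.shape[0]
    scale = max(np.trace(cov) / n, 1e-12)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(cov + jitter * scale * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError("sampled covariance not PSD even after jitter")
    if size is None:
        return mean + L @ rng.standard_normal(n)
    return mean + rng.standard_normal((size, n)) @ L.T


def _draw_cluster(rng: np.random.Generator, cfg: SimulationConfig):
    sfm = rng.gamma(*cfg.sigma_f_mu)
    sfc = rng.gamma(*cfg.sigma_f_cov)
    lm = rng.gamma(*cfg.l_mu)
    lc = rng.gamma(*cfg.l_cov)
    mean = _mvn_draw(rng, np.zeros(cfg.grid.size), sfm * _sq_kernel(cfg.grid, lm))
    cov = sfc**2 * _sq_kernel(cfg.grid, lc)
    return mean, cov


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw the GP-cluster benchmark dataset described in the module docs.

    Members are spread uniformly at random over the clusters; each outlier
    is a single draw from its own fresh singleton cluster.
    """
    rng = np.random.default_rng(cfg.seed)
    clusters = [_draw_cluster(rng, cfg) for _ in range(cfg.n_clusters)]
    assign = rng.integers(cfg.n_clusters, size=cfg.n_members)
    series = np.empty((cfg.n_members + cfg.n_outliers, cfg.grid.size))
    labels = np.empty(cfg.n_members + cfg.n_outliers, dtype=int)
    for i, ci in enumerate(assign):
        mean, cov = clusters[ci]
        series[i] = _mvn_draw(rng, mean, cov)
        labels[i] = ci
    for j in range(cfg.n_outliers):
        mean, cov = _draw_cluster(rng, cfg)
        series[cfg.n_members + j] = _mvn_draw(rng, mean, cov)
        labels[cfg.n_members + j] = OUTLIER
    return SimulatedDataset(
        series=series, true_labels=labels, cluster_params=clusters, grid=cfg.grid
    )


# ---------------------------------------------------------------------------
# clustering metrics


def _co_pair_counts(labels: np.ndarray):
    """(number of co-clustered pairs, per-label member indicator matrix)."""
    labels = np.asarray(labels)
    valid = labels != OUTLIER
    vals, counts = np.unique(labels[valid], return_counts=True)
    return counts @ (counts - 1) // 2, dict(zip(vals.tolist(), counts.tolist()))


def pair_metrics(pred, truth) -> tuple[float, float, float]:
    """Pair-counting precision, recall and F1 of a clustering.

    Outlier-flagged objects are treated as singletons on both sides, so
    they contribute no co-clustered pairs.
    """
    pred_labels = pred.labels if isinstance(pred, ClusterResult) else np.asarray(pred)
    truth = np.asarray(truth)
    if pred_labels.shape != truth.shape:
        raise ValueError("prediction and truth must cover the same objects")
    both = (pred_labels != OUTLIER) & (truth != OUTLIER)
    n_pred, _ = _co_pair_counts(pred_labels)
    n_true, _ = _co_pair_counts(truth)
    # pairs co-clustered on both sides, via the contingency table
    inter = 0
    if both.any():
        df = pd.DataFrame({"p": pred_labels[both], "t": truth[both]})
        cell = df.value_counts().to_numpy()
        inter = int(cell @ (cell - 1) // 2)
    if n_pred == 0:
        precision = 1.0 if n_true == 0 else 0.0
    else:
        precision = inter / n_pred
    recall = 1.0 if n_true == 0 else inter / n_true
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return float(precision), float(recall), float(f1)


def auc_over_k(metric_values, k_values) -> float:
    """Trapezoid area under a metric-versus-k curve, normalized by the span."""
    m = np.asarray(metric_values, dtype=float)
    k = np.asarray(k_values, dtype=float)
    if k.size < 2 or m.size != k.size:
        raise ValueError("need >= 2 swept k values matching the metric values")
    if np.any(np.diff(k) <= 0):
        raise ValueError("k values must be strictly increasing")
    return float(np.trapezoid(m, k) / (k[-1] - k[0]))


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkTable:
    """Per-(kernel, method, repetition) metric curves and AUC summaries."""

    curves: pd.DataFrame  # columns: family, method, rep, k, precision, recall, f1
    summary: pd.DataFrame  # columns: family, method, auc_precision, auc_recall, auc_f1

    def mean_auc(self, family: str, method: str, metric: str = "f1") -> float:
        row = self.summary[
            (self.summary.family == family) & (self.summary.method == method)
        ]
        return float(row[f"auc_{metric}"].iloc[0])


def fit_series_gps(
    dataset: SimulatedDataset,
    seed: int = 0,
    noise_fraction: float = 0.6,
    stationary: bool = True,
    n_restarts: int = 2,
) -> list[MarginalCurve]:
    """Fit one GP per simulated series and return its marginal curve.

    Each series is a single replicate, so the observation-noise variance is
    set to ``noise_fraction`` of the series' sample variance (floored at
    1e-4).  The default fraction 0.6 is the member-level share of series
    variance implied by the generator's Gamma priors,
    E[sigma_f_cov^2] / (E[sigma_f_mu] + E[sigma_f_cov^2]) = 1.5 / 2.5.
    The simulated processes are stationary, so the stationary limit of the
    kernel is fitted by default.
    """
    curves = []
    for i, y in enumerate(dataset.series):
        nv = max(noise_fraction * float(np.var(y)), 1e-4)
        tc = TimeCourse(
            gene_id=f"s{i}",
            condition="sim",
            times=dataset.grid,
            replicates=y[:, None],
            noise_var=np.full(dataset.grid.size, nv),
        )
        model = fit_gp(tc, n_restarts=n_restarts, seed=seed + i, stationary=stationary)
        curves.append(posterior_marginals(model, dataset.grid))
    return curves


def _sweep_cluster(K, k_values, method, n_outliers, seed, n_init, max_iter=50):
    """Cluster a kernel matrix at every swept k, re-using one eigenbasis."""
    from scipy.linalg import eigh

    from .spectral import graph_laplacian

    kmax = int(max(k_values))
    L = graph_laplacian(K, normalized=True)
    _, V = eigh(L, subset_by_index=(0, kmax - 1))
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs
    results = {}
    for k in k_values:
        P = V[:, :k]
        norms = np.linalg.norm(P, axis=1, keepdims=True)
        P = np.where(norms > 1e-12, P / np.where(norms > 0, norms, 1.0), P)
        l = n_outliers if method == "kmeans_minus" else 0
        results[k] = kmeans_minus(
            P, k, n_outliers=l, seed=seed, n_init=n_init, max_iter=max_iter
        )
    return results


def run_benchmark(
    config: SimulationConfig,
    kernel_specs=None,
    methods=("kmeans",),
    k_sweep=None,
    reps: int = 10,
    seed: int = 0,
    n_init: int = 3,
    fit_n_restarts: int = 2,
    progress: bool = False,
) -> BenchmarkTable:
    """Simulate, fit, build kernel matrices, cluster over a k sweep, score.

    For every repetition a fresh dataset is drawn (seed offset by the
    repetition index), a GP is fitted per series, one kernel matrix per
    family is built from the marginal curves, and each clustering method is
    run at every swept k.  ``kmeans_minus`` trims the true outlier count.
    Deterministic given ``seed``.
    """
    if kernel_specs is None:
        kernel_specs = [KernelSpec(family=f) for f in ("OVL", "BH", "EL", "KL")]
    if k_sweep is None:
        k_sweep = list(range(2, 101, 2))
    k_sweep = sorted(int(k) for k in k_sweep)
    rows = []
    n_total = config.n_members + config.n_outliers
    trim = config.n_outliers  # true outlier count
    for rep in range(reps):
        cfg = replace(config, seed=config.seed + seed + 1000 * rep)
        ds = simulate_dataset(cfg)
        curves = fit_series_gps(ds, seed=seed + 7 * rep, n_restarts=fit_n_restarts)
        for spec in kernel_specs:
            km = kernel_matrix(curves, spec, object_ids=[str(i) for i in range(n_total)])
            for method in methods:
                res = _sweep_cluster(
                    km.values, k_sweep, method, trim, seed=seed + rep, n_init=n_init
                )
                for k in k_sweep:
                    p, r, f1 = pair_metrics(res[k], ds.true_labels)
                    rows.append((spec.family, method, rep, k, p, r, f1))
        if progress:
            print(f"rep {rep + 1}/{reps} done")
    curves_df = pd.DataFrame(
        rows, columns=["family", "method", "rep", "k", "precision", "recall", "f1"]
    )
    summary_rows = []
    for (family, method), grp in curves_df.groupby(["family", "method"], sort=True):
        aucs = {m: [] for m in ("precision", "recall", "f1")}
        for _, g in grp.groupby("rep"):
            g = g.sort_values("k")
            for m in aucs:
                aucs[m].append(auc_over_k(g[m].to_numpy(), g["k"].to_numpy()))
        summary_rows.append(
            (family, method, *[float(np.mean(aucs[m])) for m in ("precision", "recall", "f1")])
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=["family", "method", "auc_precision", "auc_recall", "auc_f1"],
    )
    return BenchmarkTable(curves=curves_df, summary=summary)


# ---------------------------------------------------------------------------
# synthetic two-condition expression study (window-pipeline stand-in)


def simulate_expression_study(
    seed: int = 0,
    times=(0.5, 1, 2, 3, 4, 7, 14, 21),
    n_replicates: int = 3,
    group_windows=((1.0, 5.0), (7.0, 12.0), (14.0, 19.0)),
    group_folds=(2.5, 0.35, 3.2),
    group_size: int = 3,
    n_null: int = 9,
    noise_sd: float = 0.01,
    sample_sd: float = 0.10,
):
    """Generate a two-condition replicate qPCR-like study with planted groups.

    Mimics the shape of the real study (two conditions, 8 observation times
    between 0.5 and 21 days, 3 replicates) with expression on a positive
    linear scale around a baseline of 1.  Each planted group of
    ``group_size`` genes shares a sustained fold-change of ``fold`` inside
    its window under the case condition; null genes are identical in both
    conditions.

    Noise is multiplicative log-normal with two components mirroring a
    low-density-array design: a sample-level effect of standard deviation
    ``sample_sd`` shared by every gene measured on the same (condition,
    time, replicate) RNA sample — which moves co-expressed genes together —
    and an independent per-measurement effect of standard deviation
    ``noise_sd``.

    Returns ``(table, truth)`` where ``table`` is a long-format DataFrame
    (gene_id, condition, time_days, replicate, value) and ``truth`` maps
    each planted group name to its gene list and window.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    rows = []
    truth = {}
    # one RNA sample per (condition, time, replicate), shared by all genes
    sample_eff = {
        cond: sample_sd * rng.standard_normal((times.size, n_replicates))
        for cond in ("case", "control")
    }

    def emit(gene, profile_case, profile_ctrl):
        for cond, prof in (("case", profile_case), ("control", profile_ctrl)):
            for j, t in enumerate(times):
                for r in range(n_replicates):
                    eps = sample_eff[cond][j, r] + noise_sd * rng.standard_normal()
                    rows.append((gene, cond, t, r, prof[j] * np.exp(eps)))

    flat = np.ones_like(times)
    gid = 0
    for g, ((w0, w1), fold) in enumerate(zip(group_windows, group_folds)):
        genes = []
        # smooth entry/exit over half a day keeps the GP fits well-behaved
        ramp = np.clip(np.minimum(times - w0, w1 - times) / 0.5 + 1.0, 0.0, 1.0)
        prof = 1.0 * (1.0 + (fold - 1.0) * ramp)
        for _ in range(group_size):
            gene = f"G{g + 1}_{gid:02d}"
            genes.append(gene)
            emit(gene, prof, flat)
            gid += 1
        truth[f"group{g + 1}"] = {"genes": genes, "window": (w0, w1), "fold": fold}
    for _ in range(n_null):
        emit(f"NULL_{gid:02d}", flat, flat)
        gid += 1
    table = pd.DataFrame(
        rows, columns=["gene_id", "condition", "time_days", "replicate", "value"]
    )
    return table, truth
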