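"""Functional-data clustering of transcription-factor occurrence profiles.

From a window-cluster table and a motif prediction table (gene, motif, TF,
BBLS, FDR), each TF gets a daily occurrence profile: the number of clusters
active on a day that contain at least one gene carrying the TF's motif.
Profiles are normalized to unit sample standard deviation, decomposed by
discretized functional PCA (a Karhunen-Loeve expansion with quadrature
weights on the day grid), and the leading scores — enough components to
explain a target fraction of variance, conventionally 95% — are clustered
with hierarchical complete linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .kernels import interval_weights

__all__ = [
    "OccurrenceProfile",
    "FPCAResult",
    "read_motif_table",
    "occurrence_profiles",
    "normalize_profiles",
    "fpca",
    "cluster_profiles",
    "tf_profile_pipeline",
]


@dataclass
class OccurrenceProfile:
    """Per-day prediction counts for one transcription factor."""

    tf_name: str
    times: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.times.shape:
            raise ValueError("counts and times must align")
        if np.any(self.counts < 0):
            raise ValueError("occurrence counts must be non-negative")


def read_motif_table(
    path_or_df, bbls_min: float = 1.0, fdr_max: float = 0.1, sep: str = "\t"
) -> pd.DataFrame:
    """Read and filter a motif/TF prediction table.

    Expected columns: ``gene_id``, ``motif_id``, ``tf_name``, ``BBLS``,
    ``FDR``.  Rows are kept at BBLS >= ``bbls_min`` and FDR <= ``fdr_max``.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep=sep)
    required = {"gene_id", "motif_id", "tf_name", "BBLS", "FDR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"motif table missing columns: {sorted(missing)}")
    return df[(df["BBLS"] >= bbls_min) & (df["FDR"] <= fdr_max)].reset_index(drop=True)


def occurrence_profiles(
    cluster_table: pd.DataFrame, days=None, motif_table: pd.DataFrame | None = None
) -> list[OccurrenceProfile]:
    """Daily TF occurrence counts from window clusters.

    ``cluster_table`` needs ``window_start``/``window_end`` plus either a
    ``tfs`` column (comma-separated TF names per cluster) or a ``gene_ids``
    column joined against ``motif_table`` to derive the TF list (a TF
    belongs to a cluster when it has a motif on at least one member gene).
    The count of a TF on a day is the number of clusters whose window
    contains the day and whose TF list includes it.
    """
    rows = cluster_table.reset_index(drop=True)
    for col in ("window_start", "window_end"):
        if col not in rows.columns:
            raise ValueError(f"cluster table missing column {col!r}")
    if days is None:
        lo = int(np.floor(rows["window_start"].min()))
        hi = int(np.ceil(rows["window_end"].max()))
        days = np.arange(lo, hi + 1, dtype=float)
    days = np.asarray(days, dtype=float)

    gene_to_tfs: dict[str, set] = {}
    if motif_table is not None:
        for g, grp in motif_table.groupby("gene_id"):
            gene_to_tfs[str(g)] = set(grp["tf_name"].astype(str))

    counts: dict[str, np.ndarray] = {}
    for idx, row in rows.iterrows():
        w0, w1 = float(row["window_start"]), float(row["window_end"])
        if not w0 < w1:
            raise ValueError(f"cluster row {idx}: malformed window [{w0}, {w1}]")
        if "tfs" in rows.columns and isinstance(row.get("tfs"), str):
            tfs = {t.strip() for t in row["tfs"].split(",") if t.strip()}
        elif motif_table is not None:
            genes = [g.strip() for g in str(row["gene_ids"]).split(",")]
            tfs = set().union(*[gene_to_tfs.get(g, set()) for g in genes]) if genes else set()
        else:
            raise ValueError("need a 'tfs' column or a motif table")
        inside = (days >= w0 - 1e-9) & (days <= w1 + 1e-9)
        for tf in tfs:
            counts.setdefault(tf, np.zeros(days.size))[inside] += 1
    return [
        OccurrenceProfile(tf_name=tf, times=days, counts=c)
        for tf, c in sorted(counts.items())
    ]


def normalize_profiles(profiles) -> list[OccurrenceProfile]:
    """Scale each profile to unit sample standard deviation over time.

    Constant (zero-variance) profiles carry no temporal information and are
    excluded with a warning rather than failing.
    """
    out = []
    for p in profiles:
        if p.times.size < 2:
            raise ValueError(f"{p.tf_name}: need at least 2 time points")
        sd = float(np.std(p.counts, ddof=1))
        if sd == 0.0:
            warnings.warn(f"excluding constant profile {p.tf_name!r}", stacklevel=2)
            continue
        out.append(
            OccurrenceProfile(
                tf_name=p.tf_name, times=p.times, counts=p.counts,
                normalized=p.counts / sd,
            )
        )
    return out


@dataclass
class FPCAResult:
    """Discretized Karhunen-Loeve decomposition of a profile ensemble."""

    grid: np.ndarray
    mean_curve: np.ndarray
    eigenfunctions: np.ndarray  # columns phi_k, orthonormal in the weighted product
    eigenvalues: np.ndarray  # descending, >= 0
    scores: np.ndarray  # profiles x components
    n_components: int
    explained: np.ndarray  # cumulative explained-variance fractions
    profile_names: list

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        m = self.eigenvalues.size if n_components is None else n_components
        return self.mean_curve + self.scores[:, :m] @ self.eigenfunctions[:, :m].T


def fpca(
    profiles, variance_threshold: float = 0.95, weights: str = "trapezoid"
) -> FPCAResult:
    """Functional PCA of normalized occurrence profiles on a common grid.

    The covariance of the centered curves is eigendecomposed with
    quadrature weights (trapezoid by default, or uniform); eigenfunctions
    are orthonormal under the corresponding weighted inner product and
    scores are the weighted projections.  ``n_components`` is the smallest
    count whose eigenvalues explain at least ``variance_threshold`` of the
    total variance.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("FPCA needs at least 2 profiles")
    grid = profiles[0].times
    for p in profiles[1:]:
        if p.times.shape != grid.shape or not np.allclose(p.times, grid):
            raise ValueError("profiles must share a common grid")
    X = np.stack([
        p.normalized if p.normalized is not None else p.counts for p in profiles
    ])
    n, G = X.shape
    if weights == "trapezoid":
        w, _ = interval_weights(grid)
    elif weights == "uniform":
        w = np.ones(G)
    else:
        raise ValueError("weights must be 'trapezoid' or 'uniform'")
    mean = X.mean(axis=0)
    Xc = X - mean
    sw = np.sqrt(w)
    A = (Xc * sw) / np.sqrt(max(n - 1, 1))  # (n, G); A^T A = weighted covariance
    # eigendecomposition via SVD for stability
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    lam = s**2
    phi = (Vt.T / sw[:, None])  # back to function values; weighted-orthonormal
    # deterministic signs: largest-magnitude entry of each eigenfunction positive
    idx = np.argmax(np.abs(phi), axis=0)
    signs = np.sign(phi[idx, np.arange(phi.shape[1])])
    signs[signs == 0] = 1.0
    phi = phi * signs
    scores = (Xc * w) @ phi
    total = lam.sum()
    explained = np.cumsum(lam) / total if total > 0 else np.ones_like(lam)
    n_comp = int(np.searchsorted(explained, variance_threshold - 1e-12) + 1)
    n_comp = min(n_comp, lam.size)
    return FPCAResult(
        grid=grid,
        mean_curve=mean,
        eigenfunctions=phi,
        eigenvalues=lam,
        scores=scores,
        n_components=n_comp,
        explained=explained,
        profile_names=[p.tf_name for p in profiles],
    )


def cluster_profiles(scores: np.ndarray, n_clusters: int, return_linkage: bool = False):
    """Complete-linkage clustering of the retained FPCA scores.

    Returns 1-based cluster labels (and optionally the linkage matrix for
    dendrogram export).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}]")
    Z = linkage(scores, method="complete", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return (labels, Z) if return_linkage else labels


def tf_profile_pipeline(
    cluster_table: pd.DataFrame,
    motif_table: pd.DataFrame | None = None,
    days=None,
    n_clusters: int = 4,
    variance_threshold: float = 0.95,
) -> pd.DataFrame:
    """End-to-end TF occurrence-profile clustering.

    Builds daily occurrence profiles, normalizes them, runs FPCA at the
    explained-variance threshold, and cuts a complete-linkage hierarchy of
    the retained scores at ``n_clusters``.  Returns a DataFrame with one
    row per TF: its cluster label and peak occurrence day.
    """
    profiles = normalize_profiles(occurrence_profiles(cluster_table, days, motif_table))
    res = fpca(profiles, variance_threshold=variance_threshold)
    labels = cluster_profiles(res.scores[:, : res.n_components], n_clusters)
    peak = [float(p.times[int(np.argmax(p.counts))]) for p in profiles]
    return pd.DataFrame(
        {
            "tf_name": res.profile_names,
            "cluster": labels,
            "peak_day": peak,
        }
    ).sort_values(["cluster", "tf_name"]).reset_index(drop=True)
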