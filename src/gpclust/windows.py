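"""Time-window clustering of differential expression curves.

The analysis engine for two-condition replicate time courses: fit a GP per
gene and condition, call genes differential when the log2 fold-change
between the condition posterior means stays beyond a ratio threshold for a
minimum duration, enumerate candidate time windows, cluster the
window-restricted curves of the differential genes with the overlap
(OVL) kernel and outlier-resistant spectral k-means--, keep clusters whose
mean pairwise OVL (mean fit) exceeds a threshold, and prune clusters that
are exact sub-windows of another cluster with the same gene set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gp import MarginalCurve, default_grid, fit_gp, posterior_marginals
from .kernels import KernelSpec, kernel_matrix
from .spectral import OUTLIER, spectral_cluster
from .timecourse import TimeCourse, read_expression_table

__all__ = [
    "TimeWindow",
    "DifferentialCall",
    "WindowCluster",
    "PipelineConfig",
    "PipelineReport",
    "differential_genes",
    "enumerate_windows",
    "cluster_window",
    "mean_fit",
    "prune_subwindows",
    "run_pipeline",
]


@dataclass(frozen=True, order=True)
class TimeWindow:
    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, other: "TimeWindow") -> bool:
        return self.start <= other.start + 1e-9 and other.end <= self.end + 1e-9


@dataclass
class DifferentialCall:
    gene_id: str
    spans: list  # disjoint, ordered TimeWindows passing the duration rule
    max_abs_logratio: float


@dataclass
class WindowCluster:
    """A gene set co-expressed within a time window (one report row)."""

    window: TimeWindow
    gene_ids: tuple
    mean_fit: float

    def __post_init__(self):
        self.gene_ids = tuple(sorted(self.gene_ids))
        if len(self.gene_ids) < 2:
            raise ValueError("a window cluster needs at least 2 genes")


def differential_genes(
    case_curves: dict,
    control_curves: dict,
    ratio_threshold: float = 1.5,
    min_duration_days: float = 1.0,
    floor: float = 1e-6,
) -> list[DifferentialCall]:
    """Select genes with a sustained fold-change between condition curves.

    A gene is called differential when ``|log2(case/control)|`` of the
    posterior means (floored at a small positive value) stays at or above
    ``log2(ratio_threshold)`` over a contiguous grid span of at least
    ``min_duration_days``.  Returns one call per selected gene with its
    qualifying maximal spans.
    """
    thr = math.log2(ratio_threshold)
    calls = []
    for gene in sorted(case_curves):
        if gene not in control_curves:
            raise ValueError(f"gene {gene!r} missing the control condition")
        a, b = case_curves[gene], control_curves[gene]
        if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
            raise ValueError(f"gene {gene!r}: case/control grids differ")
        lr = np.log2(np.maximum(a.mean, floor) / np.maximum(b.mean, floor))
        mask = np.abs(lr) >= thr
        spans = []
        i = 0
        n = mask.size
        while i < n:
            if mask[i]:
                j = i
                while j + 1 < n and mask[j + 1]:
                    j += 1
                if a.grid[j] - a.grid[i] >= min_duration_days - 1e-9:
                    spans.append(TimeWindow(float(a.grid[i]), float(a.grid[j])))
                i = j + 1
            else:
                i += 1
        if spans:
            calls.append(
                DifferentialCall(
                    gene_id=gene, spans=spans, max_abs_logratio=float(np.max(np.abs(lr)))
                )
            )
    return calls


def enumerate_windows(
    t_min: float,
    t_max: float,
    min_len: float = 1.0,
    max_len: float = 8.0,
    start_step: float = 1.0,
) -> list[TimeWindow]:
    """All candidate windows [s, s+d] with integer-step lengths.

    Starts run on the ``start_step`` grid from the first integer day at or
    after ``t_min`` (plus ``t_min`` itself when fractional); lengths take
    integer-day steps from ``min_len`` to ``max_len``; windows must end by
    ``t_max``.
    """
    if not t_min < t_max:
        raise ValueError("t_min must precede t_max")
    if not 0 < min_len <= max_len:
        raise ValueError("need 0 < min_len <= max_len")
    first = math.ceil(t_min - 1e-9)
    starts = list(np.arange(first, t_max, start_step, dtype=float))
    if t_min < first:
        starts = [float(t_min)] + starts
    lengths = list(np.arange(min_len, max_len + 1e-9, 1.0))
    windows = [
        TimeWindow(float(s), float(s + d))
        for s in starts
        for d in lengths
        if s + d <= t_max + 1e-9
    ]
    if not windows:
        raise ValueError("window enumeration produced no windows")
    return sorted(windows, key=lambda w: (w.start, w.end))


def mean_fit(gene_ids, K, object_ids=None) -> float:
    """Mean kernel value over all unordered distinct pairs of a gene set."""
    genes = list(gene_ids)
    if len(genes) < 2:
        raise ValueError("mean fit needs at least 2 genes")
    values = getattr(K, "values", K)
    ids = object_ids if object_ids is not None else getattr(K, "object_ids", None)
    if ids is None:
        idx = list(genes)  # assume integer indices
    else:
        lookup = {g: i for i, g in enumerate(ids)}
        idx = [lookup[g] for g in genes]
    sub = np.asarray(values)[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def cluster_window(
    curves: dict,
    window: TimeWindow,
    k_sweep=None,
    outlier_ratio: float = 0.25,
    seed: int = 0,
    spec: KernelSpec | None = None,
    n_init: int = 10,
) -> list[WindowCluster]:
    """Candidate clusters of window-restricted curves, over a sweep of k.

    The OVL kernel is computed on the grid points inside the window and
    spectral k-means-- is run for every swept k; every non-outlier cluster
    of size >= 2 is emitted with its mean fit, deduplicated by gene set.
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 genes to cluster a window")
    spec = spec or KernelSpec(family="OVL")
    genes = sorted(curves)
    restricted = [curves[g].restrict(window.start, window.end) for g in genes]
    km = kernel_matrix(restricted, spec, object_ids=genes)
    n = len(genes)
    if k_sweep is None:
        k_sweep = range(1, min(n, 16))
    n_out = int(round(outlier_ratio * n))
    out: dict[tuple, WindowCluster] = {}
    for k in k_sweep:
        if k >= n:
            continue
        trim = min(n_out, n - k)  # keep the trimmed-k-means precondition
        res = spectral_cluster(
            km.values, k, n_outliers=trim, method="kmeans_minus", seed=seed, n_init=n_init
        )
        for lab in np.unique(res.labels):
            if lab == OUTLIER:
                continue
            members = tuple(sorted(np.asarray(genes)[res.labels == lab]))
            if len(members) < 2 or members in out:
                continue
            out[members] = WindowCluster(
                window=window, gene_ids=members, mean_fit=mean_fit(members, km)
            )
    return list(out.values())


def prune_subwindows(clusters) -> list[WindowCluster]:
    """Drop clusters whose gene set recurs in a containing window.

    A cluster is removed when another cluster has the identical gene set
    and a window containing its own; exact (gene set, window) duplicates
    keep only their first occurrence.  Order is otherwise preserved.
    """
    clusters = list(clusters)
    keep = []
    for i, c in enumerate(clusters):
        dominated = False
        for j, d in enumerate(clusters):
            if i == j or c.gene_ids != d.gene_ids:
                continue
            same = d.window == c.window
            if same and j < i:
                dominated = True  # duplicate; first occurrence wins
                break
            if not same and d.window.contains(c.window):
                dominated = True
                break
        if not dominated:
            keep.append(c)
    return keep


@dataclass(frozen=True)
class PipelineConfig:
    ratio_threshold: float = 1.5
    min_duration_days: float = 1.0
    mean_fit_threshold: float = 0.8
    t_min: float = 0.5
    t_max: float = 21.0
    min_window_len: float = 1.0
    max_window_len: float = 8.0
    window_start_step: float = 1.0
    grid_step: float = 0.25
    grid_stop: float = 24.0
    outlier_ratio: float = 0.25
    curve_source: str = "case"  # or "difference"
    transform: str = "parametric"
    n_restarts: int = 5
    seed: int = 0


@dataclass
class PipelineReport:
    clusters: list  # final WindowClusters
    differential: list  # DifferentialCalls
    n_genes: int
    clustered_genes: set = field(init=False)
    singletons: list = field(init=False)

    def __post_init__(self):
        self.clustered_genes = set()
        for c in self.clusters:
            self.clustered_genes.update(c.gene_ids)
        diff = [d.gene_id for d in self.differential]
        self.singletons = sorted(set(diff) - self.clustered_genes)

    @property
    def outlier_ratio(self) -> float:
        n_diff = len(self.differential)
        if n_diff == 0:
            return 0.0
        return 1.0 - len(self.clustered_genes) / n_diff

    def clusters_table(self) -> pd.DataFrame:
        rows = [
            (
                i + 1,
                c.window.start,
                c.window.end,
                c.window.duration,
                ",".join(c.gene_ids),
                c.mean_fit,
            )
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id", "window_start", "window_end", "duration",
                "gene_ids", "mean_fit",
            ],
        )

    def per_day_counts(self) -> pd.DataFrame:
        """Active clusters / clustered genes / differential genes per day."""
        if self.clusters:
            lo = math.floor(min(c.window.start for c in self.clusters))
            hi = math.ceil(max(c.window.end for c in self.clusters))
        else:
            lo, hi = 0, 0
        rows = []
        for day in range(lo, hi + 1):
            active = [c for c in self.clusters if c.window.start <= day <= c.window.end]
            genes = set().union(*[set(c.gene_ids) for c in active]) if active else set()
            diff = sum(
                any(s.start <= day <= s.end for s in d.spans) for d in self.differential
            )
            rows.append((day, len(active), len(genes), diff))
        return pd.DataFrame(
            rows, columns=["day", "n_clusters", "n_clustered_genes", "n_differential_genes"]
        )


def run_pipeline(table, config: PipelineConfig | None = None) -> PipelineReport:
    """Run the full window-clustering analysis on a two-condition table.

    ``table`` is a long-format expression DataFrame/TSV path (see
    :func:`gpclust.timecourse.read_expression_table`) with conditions
    ``case`` and ``control``.
    """
    config = config or PipelineConfig()
    tcs = table if isinstance(table, list) else read_expression_table(table)
    grid = default_grid(0.0, config.grid_stop, config.grid_step)
    by_cond: dict[str, dict[str, MarginalCurve]] = {"case": {}, "control": {}}
    for tc in tcs:
        if tc.condition not in by_cond:
            raise ValueError(f"unexpected condition {tc.condition!r}")
        model = fit_gp(
            tc,
            n_restarts=config.n_restarts,
            seed=config.seed,
            transform=config.transform,
        )
        by_cond[tc.condition][tc.gene_id] = posterior_marginals(model, grid)

    calls = differential_genes(
        by_cond["case"],
        by_cond["control"],
        ratio_threshold=config.ratio_threshold,
        min_duration_days=config.min_duration_days,
    )
    diff_genes = [d.gene_id for d in calls]

    if config.curve_source == "difference":
        curves = {
            g: MarginalCurve(
                grid,
                by_cond["case"][g].mean - by_cond["control"][g].mean,
                by_cond["case"][g].var + by_cond["control"][g].var,
            )
            for g in diff_genes
        }
    else:
        curves = {g: by_cond["case"][g] for g in diff_genes}

    windows = enumerate_windows(
        config.t_min,
        config.t_max,
        config.min_window_len,
        config.max_window_len,
        config.window_start_step,
    )
    candidates = []
    if len(diff_genes) >= 3:
        for wi, win in enumerate(windows):
            candidates.extend(
                cluster_window(
                    curves,
                    win,
                    outlier_ratio=config.outlier_ratio,
                    seed=config.seed + wi,
                )
            )
    passed = [c for c in candidates if c.mean_fit > config.mean_fit_threshold]
    final = prune_subwindows(passed)
    final.sort(key=lambda c: (c.window.start, c.window.end, c.gene_ids))
    return PipelineReport(clusters=final, differential=calls, n_genes=len(by_cond["case"]))
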