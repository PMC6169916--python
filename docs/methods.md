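# Methods

This note documents the models implemented in `gpclust`, the numerical
choices behind them, and what the synthetic benchmarks do and do not show.

## GP regression of time courses

Each gene × condition time course is modelled as `y_t = f(t) + ε_t` with
independent Gaussian noise `ε_t ~ N(0, ω_t²)`. The observation vector is
the per-time replicate mean and `ω_t²` is the replicate sample variance
(ddof 1), floored at `max(1e−6, 1e−3 × median variance)` so that identical
replicates cannot make the noise matrix singular. Data are assumed
normalized so the perturbation occurs at time 0; negative times only
trigger a warning, since the normalization is the caller's responsibility.

The prior covariance is the non-stationary squared-exponential
`K(t,t') = σ_f² exp(−(u(t) − u(t'))²)` with warped time `u(t) = t / l(t)`
and lengthscale schedule `l(t) = l_max − (l_max − l_min) e^(−ct)`:

| parameter | units  | meaning | default treatment |
|-----------|--------|---------|-------------------|
| σ_f       | signal | prior amplitude | fitted, bounds 1e−3..1e3 |
| l_max     | days   | late-time lengthscale | fitted as l_min + gap, gap ∈ 1e−4..100 |
| l_min     | days   | lengthscale at t = 0 | fitted, bounds 0.05..50 |
| c         | 1/days | relaxation rate of l(t) | fitted, bounds 1e−4..10 |

With `c = 0` the kernel collapses to a stationary Gaussian kernel with
lengthscale `l_min`; `stationary=True` fits only (σ_f, l) in that limit. A
log warp `u(t) = log(t)/l_max` is available for strictly positive times
(stationary fitting only); the parametric warp is the default.

Fitting maximizes the marginal log likelihood
`−½ yᵀA⁻¹y − ½ log|A| − (N/2) log 2π`, `A = K + Ω`, with L-BFGS-B in
log-parameter space using analytic gradients (the trace identity with
closed-form ∂K/∂θ). Multi-start: the data-driven initial point plus
`n_restarts − 1` log-uniform draws from the box bounds (default 5 starts,
seeded). The returned model is never worse than the explicit initial
point. Cholesky factorizations receive escalating diagonal jitter
(0 → 1e−4 of the mean diagonal) before failing.

Posterior marginals on a prediction grid (default days 0–24, step 0.25)
use the standard GP formulas; variances are clipped at 0 from below.
`include_noise=True` adds the (linearly interpolated) observation noise,
giving the complete noisy kinetic model. The derivative GP uses the
analytic kernel derivatives `∂K/∂t★ = −2(u(t★)−u(t)) u'(t★) K` and prior
derivative variance `2 σ_f² u'(t)²`; derivative means agree with central
finite differences of the posterior mean to O(h²) (tested).

## Kernels between GPs

Only the marginal variances (the diagonal of the posterior covariance)
enter the comparison. The curve-level kernel is the interval-weighted mean
`K_N(p,p') = (1/ΔT) Σ Δt_i K(p_i, p'_i)` with `Δt_i = (t_{i+1}−t_{i−1})/2`
and half-intervals at the two ends, so `Σ Δt_i = ΔT` exactly. Refining the
grid changes the value by < 1e−3 on smooth curves (the GP-convergence
property, tested).

Pointwise families between `N(μ, σ²)` and `N(μ', σ'²)`:

* **BH** `√(2σσ'/(σ²+σ'²)) · exp(−(μ−μ')²/(4(σ²+σ'²)))` — normalized,
  self-kernel 1.
* **EL** `N(μ−μ'; 0, σ²+σ'²)` — the expectation of one density under the
  other; not normalized.
* **KL** symmetric divergence
  `½[((μ−μ')²+σ²)/σ'² + ((μ−μ')²+σ'²)/σ² − 2]`; the log-variance terms of
  the one-way divergences cancel exactly under symmetrization, so this
  closed form is exact. Curve level:
  `exp(−(α/2ΔT) Σ Δt_i d_i + β)` with defaults α = 1, β = 0 (the study the
  defaults mirror discusses α, β but never fixes them).
* **OVL** `∫ min{p, p'}` assembled from the normal CDFs on the (at most
  three) intervals bounded by the density crossing points, the roots of
  the quadratic in z obtained from `log p = log p'`. Branches: equal
  variances (|σ²−σ'²| < 1e−12) use the single crossing at the mean
  midpoint; additionally equal means return 1. The branches are continuous
  limits of the general formula (tested by ε-perturbation). All three
  closed forms match adaptive quadrature of their defining integrals to
  better than 1e−6 on random parameter draws (tested on 1,000 pairs).

The mixture kernel `α K(y,y') + (1−α) K(y_∂, y_∂')` combines final kernel
values (not divergences) of the value and derivative curves; default
α = 1 (values only). Kernel matrices are symmetrized exactly; an
indefinite matrix (possible for KL with small α) is repaired by clipping
negative eigenvalues to zero, with the repair recorded on the result.
Grids are never resampled implicitly — a resampler exists but must be
called explicitly.

## Spectral k-means−−

From a nonnegative symmetric kernel matrix, `L = D − K` or the symmetric
normalization `D^(−1/2) L D^(−1/2)` (default); isolated vertices raise an
error naming the object. Objects are embedded as rows of the k
eigenvectors of smallest eigenvalue; column signs are fixed by making the
largest-magnitude entry positive, and rows are normalized to unit length
by default (the classical weighting step in the spectral domain; both
toggleable).

k-means−− iterates: (i) set aside the `l` points farthest from their
nearest centers, (ii) assign the rest to nearest centers, (iii) recompute
centers as means. The trimmed objective is monotone non-increasing
(asserted in-loop, except immediately after the documented empty-cluster
re-seed, which moves a memberless center to the farthest retained point).
Initialization is k-means++-style with one twist: while trimming is
active, the `l` currently most distant points are barred from being chosen
as centers. Plain D²-sampling all but surely seeds a center on the very
outlier the loop is meant to trim, which wedges the algorithm in a local
optimum; seeding on the trimmed set removes that failure mode without
touching the iteration itself. Default 10 restarts keep the best trimmed
objective; with `l = 0` the procedure is exactly standard k-means (same
seeding, tested against scikit-learn on separated blobs).

The EM alternative fits k diagonal-covariance Gaussians plus one uniform
component over the embedding's bounding box; responsibilities are computed
in log space, variances are floored (ridge) at 1e−6 of the squared mean
box width, and objects assigned to the uniform component are flagged as
outliers. Its centers are seeded the same trim-aware way (presuming
`round(0.1 n)` outliers).

## Simulation benchmark

Each of 50 cluster-generating GPs draws `σ_fμ ~ Gam(4, ¼)`,
`σ_fΣ ~ Gam(2, ½)`, `l_μ, l_Σ ~ Gam(4, 3/2)` (shape, scale), a mean curve
`μ_i ~ N(0, σ_fμ K_{l_μ})` and covariance `Σ_i = σ_fΣ² K_{l_Σ}` on a
25-point grid over days 0–24. 300 member series are multivariate-normal
draws assigned uniformly at random over clusters; 100 outliers are drawn
the same way from fresh singleton clusters (outlier fraction exactly 25%).

Benchmark protocol: one stationary GP fit per series with the observation
noise set to 60% of the series variance — the member-level share of
variance implied by the generator's own priors,
`E[σ_fΣ²]/(E[σ_fμ] + E[σ_fΣ²]) = 1.5/2.5` — then one kernel matrix per
family, spectral clustering over k = 2..100 (step 2), pair-counting
precision/recall/F1 against the true labels (outliers count as singletons
on both sides), and the trapezoid area under each metric-versus-k curve
normalized by the swept span. Ten repetitions are averaged; everything is
seed-deterministic. For runtime the per-series fits use 2 restarts and the
k-means runs 3 restarts; the defaults elsewhere are 5 and 10.

What this shows — and does not. The benchmark reproduces the qualitative
findings: BH ≥ OVL > EL > KL in mean F1-AUC, and the trimmed k-means−−
trades recall for precision against plain k-means on the same datasets.
The absolute F1-AUC level depends strongly on protocol details that the
original description leaves open (the fitting-noise model for replicate-
free series, the exact k sweep and AUC normalization, the spectral
weighting scheme); under the conditions fixed here the mean F1-AUCs come
out near 0.12–0.16 rather than 0.19–0.26. The generative design places
the member-level deviation scale (σ_fΣ ~ 1) at the same magnitude as the
cluster-mean spread (√σ_fμ ~ 1), which intrinsically caps pairwise
precision; the acceptance script reports whatever the run computes.

## Window pipeline

Curves for both conditions are fitted per gene; a gene is differential
when |log₂(case/control)| of the posterior means (floored at 1e−6) stays
≥ log₂(1.5) over a contiguous span of ≥ 24 h (both thresholds
configurable; the fold rule is applied on the log₂ scale to reconcile
"log-threshold" and "ratio threshold" phrasings). Candidate windows run
from day 0.5 to 21 with integer-day starts (plus the fractional start
itself) and integer lengths 1–8 days. Within each window the case curves
(optionally case-minus-control difference curves, with summed variances)
are restricted to the window's grid points, the OVL matrix is built, and
spectral k-means−− is swept over k = 1..min(n, 15) with 25% of the genes
trimmed; every non-outlier cluster of ≥ 2 genes is a candidate, scored by
its mean pairwise OVL over distinct pairs (self-similarities excluded —
they are identically 1 and would inflate the score). Candidates with mean
fit > 0.8 (0.75 variant selectable) survive; clusters whose gene set
recurs with a containing window are pruned, exact duplicates keep their
first occurrence. The report lists clusters (window, duration, genes,
mean fit), per-day active-cluster and gene counts, unclustered singleton
genes and the resulting outlier ratio.

The synthetic two-condition study used to exercise the pipeline mimics an
8-time-point (0.5–21 d) triplicate qPCR panel on a positive linear scale:
three planted groups of three genes share sustained fold-changes
(2.5×, 0.35×, 3.2×) in distinct windows; nine null genes are identical
across conditions. Noise is log-normal with a sample-level component
(sd 0.10) shared by all genes on the same (condition, time, replicate)
RNA sample plus per-measurement technical noise (sd 0.01) — on
low-density-array qPCR the shared RNA-sample variation dominates
same-card technical noise, and it is exactly what moves co-expressed
genes together. What passing recovery tests show: the pipeline finds
tightly co-expressed planted groups under realistic shared-sample noise.
What they do not show: performance under gene-specific biological
variability comparable to the group signal, cross-hybridization, or
missing replicates — real panels will cluster fewer genes (the original
study clustered 49 of 78 differential genes, a 37% singleton ratio).

## TF occurrence profiles and FPCA

From a cluster table and a motif prediction table (filtered at BBLS ≥ 1,
FDR ≤ 0.1), a TF's occurrence count on a day is the number of clusters
whose window contains the day and whose gene set carries the TF's motif.
Profiles are normalized to unit sample standard deviation over time
(constant profiles are excluded with a warning — they carry no temporal
information). The discretized Karhunen–Loève decomposition eigensolves the
quadrature-weighted covariance of the centered curves (trapezoid weights
by default, uniform available; computed via SVD for stability);
eigenfunctions are orthonormal under the weighted inner product, scores
are weighted projections, and the component count is the smallest
explaining ≥ 95% of variance. No spline smoothing or measurement-error
correction is applied — the profiles are already daily counts on a common
grid. Retained scores are clustered by complete-linkage on Euclidean
distance (scipy hierarchy), cut at 4 clusters by default to match the
four canonical temporal archetypes (early / short-intermediate / late /
long-intermediate); the linkage matrix is exposed so other cuts can be
inspected.

## Determinism and degenerate inputs

All stochastic steps take explicit integer seeds (numpy Generator);
repeated runs are bit-identical. Degenerate cases are handled explicitly:
identical replicates (noise floor), singular covariances (jitter then
error), empty k-means clusters (re-seed at the farthest retained point),
zero-variance TF profiles (excluded), all-identical curves (OVL branch
returns exactly 1), indefinite KL matrices (eigenvalue clipping with a
flag), windows with fewer than two grid points (error).
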