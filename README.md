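# gpclust

Gaussian-process kernels and outlier-resistant spectral clustering for
time-course gene expression.

## The problem

Time-course expression experiments (for instance qPCR panels measured at a
handful of days after a perturbation, in triplicate) produce noisy, sparse
curves per gene and condition. Grouping genes with similar temporal
behaviour requires a similarity measure that respects both the estimated
dynamics *and* the uncertainty of the estimate, plus a clustering method
that tolerates the many genes that genuinely belong to no group.

`gpclust` addresses this in three layers:

1. **GP regression.** Each gene × condition time course `y_t = f(t) + ε_t`,
   `ε_t ~ N(0, ω_t²)` (replicate variances), gets a GP prior with the
   non-stationary squared-exponential kernel

   `K(t, t') = σ_f² exp(−(t/l(t) − t'/l(t'))²)`,
   `l(t) = l − (l − l_min) e^(−ct)`,

   so early post-perturbation dynamics can be faster than late ones.
   Hyperparameters θ = (σ_f, l, l_min, c) maximize the marginal log
   likelihood by multi-start L-BFGS-B; the fit yields marginal means μ_i
   and variances σ_i² on a prediction grid, and the derivative process
   (rate of change) in closed form.

2. **Kernels between GPs.** Two GPs summarized on a shared grid are
   compared by the time-weighted mean of a pointwise kernel between their
   marginal Gaussians, `K_N(p, p') = (1/ΔT) Σ_i Δt_i K(p_i, p'_i)` with
   `Δt_i = (t_{i+1} − t_{i−1})/2`. Four pointwise families: the overlap
   coefficient (OVL, `∫ min{p, p'}`, computed exactly from the density
   crossing points), Bhattacharyya (BH, probability-product exponent ½),
   expected likelihood (EL, exponent 1), and the exponentiated symmetric
   Kullback–Leibler divergence (KL). OVL and BH are 1 for identical curves;
   OVL lower-bounds BH. A mixture kernel
   `α K(y, y') + (1−α) K(y_∂, y_∂')` blends values and derivatives.

3. **Spectral k-means−−.** The kernel matrix becomes a graph Laplacian
   `L = D − K` (normalized by default); objects are embedded in its leading
   eigenvectors and clustered with k-means−−: each iteration trims the `l`
   points farthest from their nearest center before re-assigning and
   re-averaging, producing explicit outlier flags. A plain k-means and an
   EM mixture with a uniform outlier component are provided for comparison.

On top sit a **simulation benchmark** (GP-generated clusters plus 25%
outlier series, scored by pair-counting precision/recall/F1 over a sweep of
cluster counts), a **time-window pipeline** (sustained-fold-change
differential calls, per-window OVL clustering, mean-fit filtering,
sub-window pruning), and **FPCA clustering** of transcription-factor
occurrence profiles (Karhunen–Loève scores at a 95% explained-variance
rule, complete-linkage).

## Worked example

```python
from gpclust.simulate import simulate_expression_study
from gpclust.windows import run_pipeline, PipelineConfig

table, truth = simulate_expression_study(seed=0)   # 2 conditions x 18 genes
report = run_pipeline(table, PipelineConfig(seed=0))
print(f"differential genes: {len(report.differential)}")
print(f"final clusters:     {len(report.clusters)}")
print(report.clusters_table().head(5).to_string(index=False))
```

prints

```
differential genes: 9
final clusters:     107
 cluster_id  window_start  window_end  duration                      gene_ids  mean_fit
          1           0.5         1.5       1.0                   G2_03,G3_08  0.916743
          2           0.5         2.5       2.0                   G2_03,G2_05  0.943310
          3           0.5         3.5       3.0                   G2_03,G2_04  0.963163
          4           0.5         4.5       4.0 G2_03,G2_04,G3_06,G3_07,G3_08  0.824753
          5           0.5         5.5       5.0                   G3_06,G3_07  0.950380
```

The nine planted differential genes (three co-expressed groups of three)
are all detected; none of the nine null genes is called. Each row is a gene
set co-expressed within a time window, with `mean_fit` the average pairwise
OVL similarity inside the cluster (the filter keeps clusters above 0.8).
The three planted gene trios appear among the final clusters in their
planted windows.

A command-line interface mirrors the library:

```sh
gpclust simulate --seed 1 --out-prefix sim       # benchmark dataset
gpclust benchmark --reps 10 --out bench.tsv      # kernel/method comparison
gpclust cluster-kernel K.tsv --k 50 --outliers 100 --method kmeans_minus
gpclust pipeline expression.tsv                  # window clustering
gpclust tf-profiles clusters.tsv --motifs motifs.tsv
```

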