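# Methods

This note documents the models implemented in `devconnectome`, the design
decisions taken where the methodology left choices open, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Weighted network metrics

Connectomes are symmetric nonnegative matrices `W` (FA×FN-style weights,
unitless, zero diagonal).  Edge length is the reciprocal weight `1/w`;
distances `d_ij` are Dijkstra shortest paths over those lengths, with
disconnected pairs at infinity contributing zero to efficiencies.

- **Global efficiency** — mean over ordered pairs of `1/d_ij`.
- **Nodal efficiency** — per-node mean of `1/d_ij`; its average equals the
  global efficiency exactly (asserted in tests at 1e-12).
- **(Nodal) local efficiency** — global efficiency of the subgraph induced
  on a node's neighbors, node removed, original weights kept; nodes with
  fewer than two neighbors contribute zero (the standard Latora–Marchiori
  convention).
- **Characteristic path length** — mean `d_ij` over connected ordered
  pairs; if any pair is disconnected the mean is restricted to finite pairs
  and a warning is logged (empirical group networks are connected; this is
  a degenerate-input policy, not an expected path).
- **Strength** — row sums `k_i = Σ_j w_ij` and their network mean.
- **Clustering** — Onnela geometric-mean form with weights scaled by the
  network-wide maximum and the *binary* degree in the denominator; nodes
  with binary degree ≤ 1 get zero.
- **Betweenness** — weighted shortest-path betweenness with credit split
  across tied shortest paths (path multiplicities) and the
  `1/((n−1)(n−2))` normalization, computed via networkx; a brute-force
  exhaustive-path oracle in the test suite checks every metric on random
  graphs with up to 7 nodes to 1e-9.

**Small-world nulls.**  Matched random networks preserve the binary degree
sequence exactly (Maslov–Sneppen double edge swaps, 10·|E| attempted swaps)
and the weight multiset exactly (weights randomly permuted onto the rewired
topology).  Weight–degree coupling is deliberately *not* preserved; the null is
defined by matching nodes, edges and the degree distribution only.
γ and λ are the clustering and path-length ratios to the null-ensemble
means; σ = γ/λ.  Default ensemble size is 5000, configurable (tests and
the pipeline default to 100, which puts the Monte-Carlo error of the null
means near 1%).

## Edge taxonomy

On the group-average network (edge kept iff nonzero in ≥ 75% of scans —
"less than 75%" zeroed, so 3-of-4 survives; kept weights are means over all
scans including zeros, so prevalence alone guards against rarely observed
edges), hubs are nodes whose strength *or* betweenness exceeds the mean
plus one sample standard deviation.  Edges partition into
rich-club/feeder/local by endpoint hub status, within/between by
functional-module labels, and short/long by the support-wide mean
streamline length (ties short).  Per-scan, per-type mean strengths average
over the *group* support including scan-level zeros, making the quantity
comparable across scans; global network strength is the intended covariate
when these are fed to the trajectory model.

## Developmental trajectory models

Each response is fitted by maximum likelihood (not REML: AICs are compared
across fixed-effect structures) with statsmodels `MixedLM`:

- fixed effects: intercept, age (mean-centered internally; slopes reported
  on the original scale, for the quadratic model via β_age − 2·c·β_age²),
  sex, total brain volume (standardized internally, coefficient mapped
  back), acquisition-centre dummies (first level reference), optional
  extras (head motion, global strength);
- random effects: subject intercept + age slope, unstructured covariance;
  the quadratic model adds a random age² slope.

The 3×3 random structure is numerically fragile: L-BFGS frequently stalls
on it, so fitting cascades L-BFGS → Powell and keeps the best finite
log-likelihood; if no structure converges the random slope is dropped with
a warning (logged fallback), and cohorts without repeated scans fall back
to a random intercept directly.  Wald 95% intervals and normal p-values
come from the ML fit; a parametric bootstrap (simulate from the fitted
model, refit, percentile interval) is available as
`TrajectoryLMM.bootstrap_ci_age` for interval estimation that does not
lean on the Wald approximation.  AIC ties resolve toward the simpler
model.

**Slope maps.**  Nodal metrics are z-scored across all scans (not within
wave), fitted region-wise with the linear model, and Bonferroni-corrected
across regions (`p_bonf = min(1, p·R)`).  Spatial gradients of the slope
map are tested by two-sample t-tests between groups split at the
coordinate median (posterior–anterior: y; inferior–superior: z;
medial–lateral: |x| split per hemisphere) — a region-level adaptation of a
voxel-slice analysis, since this package has no voxel data.

## Spatially autocorrelated surrogate maps

All map-level inference uses variogram-matched surrogates: permute the
map, smooth with exponential distance kernels over a 20-value log-spaced
bandwidth grid (extending to twice the largest pairwise distance so that
near-uniform kernels are available), and choose per surrogate the
bandwidth and nonnegative affine recombination with white noise whose
binned variogram best matches the source map's.  Conventions that matter:

- 25 distance bins up to the 70th percentile of pairwise centroid
  distances;
- the fit is **generalized least squares** over bins: the empirical
  variogram estimator has variance ≈ γ²·2/n_pairs per bin, so bins are
  weighted by `n_pairs/γ²` — short-lag bins (small γ, strong
  autocorrelation) are matched tightly and sparse bins (< 10 pairs)
  are excluded, because with the 1/γ² factor a near-empty low bin would
  otherwise dominate;
- each surrogate's mean and variance are pinned exactly to the source
  map's (mean and overall variance carry no autocorrelation information,
  and every downstream statistic is a correlation, so this is
  inference-neutral);
- a constant map yields constant surrogates.

This configuration was frozen after a calibration study against Gaussian
process fields of known length scale: uniform-weight variogram fitting
selects surrogates with flatter spatial spectra than the source maps,
which deflates the permutation null of projection statistics and inflates
false positives, while the GLS weighting restores nominal behavior — the
test suite verifies both the null rejection rate (binomially consistent
with α = 0.05) and the power at planted coupling r = 0.5 (≥ 80%) of the
component-1 PLS correlation test under this generator.  Residual known
limitation: the generator conditions on the *realized* variogram of a
single map, so surrogates of an individual non-autocorrelated map
reproduce that map's chance short-lag dips; averaged across many maps the
surrogate/permutation variogram ratio must stay within [0.85, 1.10] (no
systematic smoothing), which the test suite checks directly.

Permutation p-values are two-sided add-one everywhere:
`p = (1 + #{|stat_null| ≥ |stat_obs|})/(n + 1)`; the minimum attainable p
is `1/(n+1)`.

## PLS imaging transcriptomics

With a univariate response, PLS correlation and PLS regression coincide at
the first component up to scaling; the implementation extracts components
from the SVD of the cross-covariance `X'y` with deflation (PLS1), after
within-gene z-scoring of expression and z-scoring of the map (constant
genes dropped with a warning).  Components are sign-flipped so scores
correlate positively with the response; per-component explained fractions
of var(y) use the mutually orthogonal scores, so they sum to at most 1.
Significance of the component-1 score–map correlation r₁ is the surrogate
permutation p above, with PLS refitted to every surrogate map.

Gene inference bootstraps **regions** (the observation unit of the spatial
regression) with replacement, refits component 1, aligns each replicate's
sign to the full-data component, and forms `z = w/SD_boot` with two-sided
normal p-values; selection applies a Bonferroni cut at 1% (strict
`p·G < α`).  Defaults: 10 000 surrogates, 1000 bootstrap replicates
(scaled down with fixed seeds in tests).  Known limitation: under
spatially autocorrelated gene noise, region resampling sees a chance
spatial association as stable signal, so far-tail p-values are
anti-conservative and the empirical false-discovery rate of the 1%
Bonferroni cut sits near 5% on the synthetic default rather than well
below it; a spatially blocked bootstrap would tighten this but is not the
procedure implemented by the published analyses this package follows.

## Enrichment

- **Cell classes** (astrocytes, endothelial, excitatory, inhibitory,
  microglia, oligodendrocytes, OPC; disjoint per gene): observed overlap
  of the selected list with each class against overlaps of size-matched
  uniform draws from the PLS universe; one-sided add-one p (enrichment
  direction), BH-FDR across classes.  Empty classes/selections report NaN.
- **Categories** (GMT-style gene sets): observed mean component-1 weight
  per category against the same means recomputed from PLS weights
  refitted to each surrogate map; two-sided around the null center
  (weights are signed), BH-FDR across categories.

## Cytoarchitecture

Spearman correlations between the slope map and per-region cortical maps
(myelin, L1–L6 laminar thickness, cortical thickness), p-values from
surrogates of the slope map (documented asymmetry: ρ is symmetric in the
arguments, p is not).  Laminar specificity: all maps rank-transformed, the
slope and target lamina residualized on the other five by least squares,
residuals Pearson-correlated; surrogates are pushed through the identical
residualization.  A condition-number guard (10⁸) rejects collinear
controls.

## Synthetic generator

The generator produces every input with planted ground truth, at a
desk-scale default of R = 90 regions (one-tenth the pair count of a
246-region atlas), 200 subjects, up to 3 annual waves, 500 genes.

- **Geometry** — centroids sampled in a 140×170×120 mm hemisphere box and
  mirrored across the midline; the deepest 10% of regions are flagged
  subcortical; 7 cortical modules by spatial k-means plus the subcortical
  module.
- **Cohort** — baseline edge weights decay exponentially with distance
  (λ = 60 mm) and are thresholded to 15% density (keeping the strongest,
  i.e. shortest, pairs); a smooth nodal slope field *f* (Gaussian process,
  length scale 20 mm, mean 0.02, SD 0.015 per year) drives edge slopes
  `(f_a+f_b)/2`; subjects carry a shared random intercept
  (σ_u = 0.08) and age slope (σ_b = 0.01) applied to every edge, plus
  edge-level scan noise (σ_ε = 0.04); ages are uniform 6–11 at wave 1
  plus one year per wave with 30% per-wave dropout; weights truncate at
  zero (rate logged, < 1% at defaults).  Between-subject variance
  deliberately dominates scan noise, as in real FA×FN connectomes, which
  also makes the z-scored slope map approximately degree-invariant.
- **Expression** — one planted component: the latent equals the
  standardized cortical slope field mixed with an orthogonalized
  independent field so that corr(latent, slope) is exactly the requested
  coupling (default 0.5); 50 support genes at weights ±1 (half positive);
  noise is **low-rank spatially autocorrelated** — 3 shared GP factor
  fields (length scale 20 mm, SD 0.35) with per-gene Gaussian loadings —
  plus white measurement noise (SD 0.25).  Low-rank noise mirrors the
  dominant shared spatial gradients of real regional transcriptomes; with
  one independent spatial field per gene the expression matrix would span
  all of region space and the component-1 score could reconstruct *any*
  map, making the planted component undetectable by construction.
- **Annotations** — every gene in exactly one of the 7 classes; 80% of
  positive-support genes concentrated in one designated class.  Categories
  contain the positive and negative support halves separately (a signed
  mean-score statistic cancels over a balanced ± set) plus random decoys.
- **Cortical maps** — each map is ρ·(standardized slope field) plus an
  orthogonalized independent GP field; six laminar maps with exactly one
  conditionally dependent target (default L5, ρ = 0.6).

What the generator does **not** emulate: empirical FA×FN weight
distributions, atlas-specific module boundaries, AHBA donor structure or
probe-level noise, scanner/site effects beyond a categorical intercept, and
motion artifacts.  Passing recovery tests therefore demonstrates that the
estimators recover the model they assume at realistic sizes and noise —
not robustness to real-data pathologies outside that model.

## Validation problem sizes

The study-level test module runs, per property: 200 random graphs (≤ 7
nodes) against the brute-force oracle; 100-network null ensembles for
small-world checks; 200 cohorts of 200 subjects for CI coverage; 30 + 30
cohorts of 120 subjects for AIC selection; a default-scale cohort for
slope-map recovery plus 80 null cohorts (16 regions, 50 subjects) for the
family-wise error; 50 + 50 expression replicates with 500 surrogates for
SAC calibration and power; 10 replicates for gene recovery/ranking/FDR; 20
scaled-down replicates (200 surrogates) for category enrichment; 100
replicates (150 surrogates) for Spearman calibration; and two full
pipeline runs for byte-level determinism.  These sizes keep the suite
within a desktop coffee break while leaving every binomial acceptance band
meaningfully narrow.
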