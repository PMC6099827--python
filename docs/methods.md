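# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `lgflow`, in the order the pipeline runs them.

## Genotype model and QC

Individuals are diploid with `L` codominant loci; a locus is either fully
called (two integer allele sizes) or fully missing — half-called loci are
rejected at construction. QC removes individuals missing more than
`max_missing_loci` loci (default 5, matched to a 15-locus panel) and then
exact multilocus duplicates, keeping the first occurrence. Duplicate
removal is a deliberate simplification of laboratory-side error screening
(allele dropout, multi-capture matching), which is out of scope here: the
package consumes genotypes that are assumed correct.

## Differentiation statistics

For a pair of clusters (`k = 2`), per locus:
`H_S = mean over the two groups of (1 − Σ p²)` and `H_T = 1 − Σ p̄²` with
`p̄` the unweighted mean frequency. Multilocus values average `H_S` and
`H_T` across loci *before* forming ratios (the Nei convention; loci without
data in either group are dropped for that pair). Then

- `G_ST = (H_T − H_S)/H_T` (0 when `H_T = 0`),
- `G'_ST = G_ST (k − 1 + H_S)/((k − 1)(1 − H_S))` (Hedrick),
- `D = ((H_T − H_S)/(1 − H_S)) · k/(k − 1)` (Jost),

all clamped to [0, 1]; negative point estimates clamp to 0 so downstream
regressions see a bounded response.

**Estimator choice.** The default is the plug-in (no sample-size
correction). A `bias_correction` flag switches to the Nei–Chesser
small-sample estimators: `H_S` scaled by `2ñ/(2ñ−1)` (ñ = harmonic mean
sample size of the pair) and `H_T + H_S/(2ñk)`. The plug-in statistic has
an upward bias of order `1/(4n)` at zero true differentiation (amplified
roughly by `(1+H_S)/(1−H_S)` in `G'_ST`, i.e. ≈ 0.05–0.08 at n = 30 and
H_S ≈ 0.75); the corrected estimator is near-unbiased and is what the
generator-calibration tests use. Both are exposed because neither is
canonically "the" field choice.

Bray–Curtis dissimilarity between individuals is computed on allele-count
vectors over loci called in both individuals (each called locus contributes
two counts); pairs sharing no called locus are flagged missing and excluded
from model fits. Probability of identity per locus is
`Σ p_i⁴ + Σ_{i<j} (2 p_i p_j)²`, multiplied across loci.

## Lek clustering

Complete-linkage agglomeration via `scipy.cluster.hierarchy` (whose
`complete` method is the Lance–Williams recurrence with α = 0.5, β = 0,
γ = 0.5) on Euclidean distances over projected coordinates. The dendrogram
is cut so that merges are allowed only while the merged cluster's diameter
stays ≤ the cut (default 25 km, a dispersal-scale seasonal movement
distance): separations strictly greater than the cut split clusters. For
complete linkage the merge height *is* the cluster diameter, so the cut
guarantees a maximum within-cluster distance. Clusters below the minimum
(default 8 individuals) are removed and their individuals excluded.

## Resistance surfaces

Thresholding is binary: habitat cells get resistance 1, nonhabitat cells
`r > 1`. Boundary inclusion is symmetric — `≥ threshold` is habitat for
positively associated variables, `≤ threshold` for negatively associated
ones. Percentile-mode thresholds ("top X% of cell mass") are empirical
quantiles with linear interpolation, suited to heavily zero-skewed
abundance kernels. A circular focal mean (6.44-km windows in the field
setting) and bilinear coarsening to the 1.2-km analysis resolution are
provided for preparing percent-cover layers; NoData propagates through
both.

The combined ("landsum") surface is `1 + Σ (r_s − 1)`: excess resistances
add, and cells that are habitat everywhere keep the baseline of 1. Naive
summation would give habitat cells a resistance equal to the number of
surfaces, silently rescaling the baseline — the excess-sum preserves it
while remaining strictly additive.

**Resistance-value search.** For each variable, the three
threshold-specific pairwise-resistance matrices are computed at candidate
nonhabitat values {5, 10, 20}; the first selected value is the smallest
whose matrices' mean Pearson correlation (upper-triangle entries) with the
geographic null is ≤ 0.7 in at least one zone. The second value repeats
the rule over {50, 100, 200} against the first value's matrices. If no
candidate passes, the largest is used with a logged warning — on landscapes
where the variable is rare or mild, resistances simply stay
distance-dominated, and the audit table records every correlation examined
so either reading of the screen (vs distance, vs each other) can be
applied after the fact.

## Circuit engine

Non-masked cells are graph nodes; neighbor edges (8-neighborhood by
default, 4 available) get conductance `mean(1/r_a, 1/r_b)`, diagonals
divided by √2 for the longer span. Lek clusters are contracted into
supernodes (zero internal resistance), matching the treatment of lek
clusters as circuit nodes; a centroid-cell mode can be emulated by passing
single-cell node sets. Pairwise effective resistance grounds one supernode
per connected component, factorizes the reduced Laplacian once with
`splu`, reuses the factorization across all sources in that component, and
assembles `R(s,t) = x_s[s] − x_s[t] − x_t[s] + x_t[t]`. Pairs in different
components are non-finite and excluded from regressions (assigning a large
constant instead would impose an arbitrary scale on the fits).

The geographic-distance null is the identical computation on an all-ones
surface with the same mask — distance "through the study area" rather than
straight-line distance.

All-to-one flow: for each focal cluster, ground it, inject one unit of
current at every other cluster in its component, solve, and accumulate
per-cell current as half the sum of absolute currents on incident edges;
the map is the mean over focal clusters. One engine computes both pairwise
resistances and flow maps, so the two outputs are always numerically
consistent with each other.

## MLPE model

`y_ij = β₀ + Σ β_k x_k,ij + u_i + u_j + ε_ij` with `u ~ N(0, σ_u²)` iid per
cluster and `ε ~ N(0, σ²)` iid per pair; the incidence matrix `Z` has
exactly two ones per row, giving marginal covariance `σ²(I + φ ZZᵀ)` with
`φ = σ_u²/σ²`. One eigendecomposition of `ZZᵀ` per pair structure turns
every likelihood evaluation into O(n·p) work; the profiled (restricted)
log-likelihood is maximized over `log φ` by bounded scalar minimization
(tolerance 1e-10, bounds e^±12) with the `φ = 0` boundary checked
explicitly. Predictors are z-scored by default so coefficients are
standardized effect sizes; the response is left untransformed (a
`standardize_y` flag exists). Wald 95% intervals come from
`σ̂²(XᵀV⁻¹X)⁻¹`.

ML is the default because the selection procedures compare models with
different fixed effects; REML is available and is the right choice when
the variance components themselves are the target (the parameter-recovery
checks use REML on the variance scale, where it is near-unbiased — ML's
`σ_u` estimate is biased low by O(1/k) at modest cluster counts). AIC uses
`p = #fixed + 2` (both variance components counted); AICc uses `n =`
number of pairs, the modeled observations.

Significance over distance follows the two-model rule: the predictor is
significant iff its standardized-slope 95% CI excludes zero from below in
both `y ~ RD` and `y ~ RD + distance`. Predictors correlated with the
null at |r| > 0.999 are declared collinear and not significant rather than
fitted (the two-predictor GLS would be numerically meaningless). Ties in
AIC break lexicographically by surface label for reproducibility.

## Cross-validation

The split unit is the pairwise observation (80% train / 20% test, 100
iterations by default), the most literal reading of "split the data"; a
cluster-level split mode is provided because pair splits leak
shared-cluster information between train and test. Test predictions use
fixed effects only — the random effects of held-out structure are
unobservable by construction. Absolute errors are binned into five
equal-width bins over the observed differentiation range, shared across
iterations; a bin empty in every iteration is reported missing, not zero.
The individual-based rerun expands cluster-level predictors to individual
pairs by cluster-pair lookup, excludes within-cluster pairs, and refits
the between-variable table with per-individual random effects.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
not the biology that produced it:

- **Landscape**: white Gaussian noise smoothed by a Gaussian kernel
  (`autocorr_range` cells; range 1 = no smoothing) and rank-transformed to
  uniform [0, 1], so the habitat threshold is simultaneously an areal
  quantile and every value is in range by construction.
- **Lek clusters**: centroids rejection-sampled on above-median habitat
  with enforced pairwise spacing (the pipeline passes cut/cell_size + 6
  cells so that generated clusters cannot merge under the downstream cut);
  each cluster holds 1–5 lek cells nearest its centroid.
- **Genotypes**: the target pairwise differentiation is
  `clamp(drift_scale·R_ij + u_i + u_j + ε_ij, 0, 0.95)` — exactly the MLPE
  structure the fitting stage assumes. Targets are realized by a
  double-centering construction: converted from the G'_ST to the G_ST
  scale at the panel's expected heterozygosity, treated as squared
  distances between cluster frequency vectors, Gower-centered into a
  cross-cluster covariance (effective resistance is a negative-type
  metric, so the centered matrix is PSD up to eigenvalue clipping), and
  sampled as correlated Gaussian perturbations of Dirichlet base
  frequencies with allele-wise scale `√(p₀(1−p₀))`. Individuals are
  Hardy–Weinberg draws from cluster frequencies. The mapping is
  approximate — simplex clipping shrinks extreme targets — but monotone,
  which is what rank-based checks require. A per-cluster Dirichlet
  concentration was considered and rejected: it can only realize additive
  (star-shaped) pairwise structure, not an arbitrary resistance-shaped
  target matrix.

Defaults are the study conditions at desk scale: 90×90 cells at 1.2 km,
10 clusters (the smallest field zone had 15), 20 individuals per cluster
(field means 18.8–25.9), 15 loci, and a drift scale that yields mean
pairwise G'_ST ≈ 0.16 (field zone means 0.14–0.36). What the generator
does *not* emulate: linkage, mutation, spatially continuous
isolation-by-distance within clusters, temporal sampling, and genotyping
error. Passing tests therefore demonstrate that the pipeline recovers the
structure it models, not that the model is correct for any particular
field system.

## Problem sizes and determinism

Simulation-based checks run at 50×50–90×90 grids with 6–10 clusters and
50–100 replicates, sizes at which the full pipeline runs in seconds per
replicate on one core. All randomness flows through explicit
`numpy.random.default_rng` seeds (the pipeline derives stage seeds by
fixed offsets), so identical configurations reproduce outputs
bit-for-bit; output directories carry a config-hash provenance sidecar.

## Known limitations

- Binary resistance surfaces only; continuous (e.g. negative-exponential)
  habitat-to-resistance transforms are out of scope.
- GeoTIFF is not supported; rasters are ESRI ASCII grid (plain text) with
  a JSON metadata sidecar for surface provenance.
- The MLPE solver is dense in the number of pairs (one `n_pairs²`
  eigendecomposition per pair structure); comfortable to a few thousand
  pairs, not intended for tens of thousands.
- Genepop files carry no coordinates, so tables read from Genepop need
  coordinates merged in before clustering.
- The decorrelation search follows the "vs distance / vs first set" rule;
  the full audit table is emitted so alternative screens can be applied.
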