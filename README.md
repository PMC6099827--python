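# lgflow

**Landscape-genetics connectivity analysis: from genotypes and habitat
rasters to resistance surfaces, circuit-theory distances, MLPE model
selection, and current-flow maps.**

`lgflow` implements a complete isolation-by-resistance pipeline of the kind
used to quantify functional connectivity for lekking grouse and other
patchily distributed species. It is aimed at landscape geneticists who have
(a) multilocus codominant genotypes (microsatellite-style) with projected
coordinates and (b) continuous raster layers describing habitat quality or
landscape structure, and who want to ask: *which landscape features, at
which thresholds, best explain pairwise genetic differentiation — and do
they explain it better than geographic distance alone?*

## The method

1. **Lek clustering.** Sampling locations are grouped by complete-linkage
   hierarchical clustering (Lance–Williams recurrence) with a fixed cut
   (default 25 km); clusters with fewer than 8 genotyped individuals are
   dropped, and individuals missing more than 5 loci are removed first.
2. **Differentiation.** Pairwise differentiation between clusters is
   Hedrick's standardized G'ST (with Nei's GST and Jost's D as
   alternatives): per pair, H_S and H_T are averaged across loci and

   G_ST = (H_T − H_S)/H_T,  G'_ST = G_ST (k−1+H_S)/((k−1)(1−H_S)),  k = 2.

3. **Resistance surfaces.** Each continuous raster is split at three
   candidate thresholds into binary habitat (resistance 1) / nonhabitat
   (resistance r > 1) surfaces. The two nonhabitat resistance values are
   chosen by a decorrelation search over {5, 10, 20} then {50, 100, 200}:
   the smallest value whose pairwise-resistance matrices reach mean Pearson
   r ≤ 0.7 with the geographic null (and with the first value's matrices).
4. **Circuit theory.** Surfaces become conductance-weighted raster graphs
   (8-neighborhood, mean-conductance edges, diagonals ÷ √2); lek clusters
   are contracted into supernodes and pairwise effective resistance is
   computed from the reduced graph Laplacian by sparse factorization. The
   "geographic distance" null is the same computation on an all-ones
   surface, so it respects the study-area shape.
5. **MLPE model selection.** Differentiation is regressed on resistance
   with a maximum-likelihood population-effects mixed model
   (y_ij = β₀ + β₁x_ij + u_i + u_j + ε_ij): each pair carries the random
   effects of both clusters. A surface is *significant over distance* when
   the 95% CI of its standardized coefficient stays above zero in both
   `y ~ RD` and `y ~ RD + distance`. Within-variable selection picks the
   best threshold/resistance by AIC; between-variable selection ranks the
   significant predictors (plus an additive combined landscape surface) in
   one AICc table with Akaike weights.
6. **Validation and mapping.** Monte Carlo cross-validation (100 iterations,
   80% train) compares the top surface's out-of-sample prediction error
   against distance across five differentiation bins; an individual-based
   rerun uses Bray–Curtis dissimilarity between individuals. Finally an
   all-to-one circuit solve maps averaged current density — the spatial
   pattern of expected gene flow.

A synthetic-data module generates autocorrelated habitat landscapes,
spaced lek clusters, and Hardy–Weinberg genotypes whose pairwise
differentiation tracks effective resistance, so the whole pipeline is
testable without any field data.

## Worked example

Run the full synthetic study (90×90 landscape at 1.2-km resolution, 10 lek
clusters, 20 individuals each, 15 loci) end-to-end:

```bash
lgflow all --seed 1 --outdir demo_out
```

or in Python:

```python
from lgflow import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, outdir="demo_out")
cfg.synthetic.seed = 1
result = run_pipeline(cfg)
print(result.summary)
print(result.between)
```

With seed 1 this produces 10 recovered lek clusters (200 individuals), a
mean pairwise G'ST of 0.181 (maximum 0.329) — squarely in the range
reported for wild grouse management zones — and a between-variable AICc
table in which the habitat-derived surface beats the geographic-distance
null by ΔAICc ≈ 26.7 with a standardized slope of 0.051. The decorrelation
search selects nonhabitat resistances (20, 200), G'ST and GST are
rank-correlated at 0.995 across cluster pairs, and cross-validated mean
absolute prediction error is 0.0234 for the top surface vs 0.0572 for
distance alone. The output directory
contains the genotype table, differentiation and resistance matrices
(labeled CSV), the selection audit tables, the CV summary and bar chart,
and the current-flow map (`flow_map.asc`).

Every stage is also available as a library function or CLI subcommand
(`simulate`, `cluster`, `diff`, `surface`, `resist`, `fit`, `cv`, `flow`)
operating on the same text formats.

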