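# spatiomic

Statistical tools for spatiotemporal analysis of plant-associated
microbiome surveys — the kind of study that samples root and bulk-soil
communities of a perennial crop across several field sites and
repeatedly through a growing season, and asks how much of the community
turnover is explained by site, collection date, spatial distance,
nitrogen addition, and measured environmental covariates, and which taxa
persist across all of it.

The package is aimed at microbial ecologists working with OTU/ASV count
tables and nested field designs (sites > plots > treatment subplots >
cores). It covers the full workflow:

- **Community tables** — TSV/BIOM 2.1 I/O, validation, rarefaction to a
  common depth, richness and inverse Simpson diversity
  (D = 1/Σ pᵢ²), and an interquartile-range outlier filter
  (flag values outside [Q1 − 3·IQR, Q3 + 3·IQR]) for covariates.
- **Distances** — Bray-Curtis dissimilarity
  (d = Σ|xᵢ − xⱼ| / Σ(xᵢ + xⱼ)), Euclidean geographic distance on UTM
  coordinates, calendar-day temporal distance, and a lagged root-vs-soil
  similarity comparison (1 − BC against soil collected the same day or
  two weeks earlier).
- **Nested PERMANOVA** — distance-based multivariate ANOVA for
  split-plot designs with type III (marginal) sums of squares,
  pseudo-F ratios against the correct error stratum (whole-plot factors
  over the plot-within-site×N mean square), ω² effect sizes
  (ω² = (SS − df·MS_err)/(SS_total + MS_err)), restricted
  Freedman-Lane permutation p-values, and PERMDISP-style beta
  dispersion around group spatial medians.
- **Ordination concordance** — non-metric MDS and Procrustes/PROTEST:
  one ordination is translated, scaled, and rotated onto another to
  minimise m² (the normalized sum of squared deviations); concordance
  t = √(1 − m²) is tested by permuting sample identities.
- **Generalized dissimilarity models** — Bray-Curtis turnover regressed
  on monotone I-spline transforms of predictors through
  d = 1 − exp(−(α + Σₚ |fₚ(xᵢ) − fₚ(xⱼ)|)), fit by non-negative
  minimisation of the binomial deviance; permutation variable importance
  with backward selection, deviance partitioning over predictor groups
  by inclusion-exclusion, and bootstrap spline bands with 30% of samples
  withheld.
- **Core microbiome** — abundance-occupancy ranking of taxa, cumulative
  Bray-Curtis contribution curve, "last 5% increase" core cutoff, Sloan
  neutral-model fitting (occupancy = 1 − BetaCDF(1/N; Nmp̄, Nm(1−p̄)))
  with above/neutral/below classification, root-vs-soil differential
  family abundance (log2 ratio of median proportions, Wilcoxon, BH FDR),
  and fungal guild grouping.
- **Synthetic data** — a generator that emulates the nested field design
  (5 sites × 4 plots × 2 N subplots × 3 cores; or a single-site series
  of 15 biweekly soil and 6 monthly root collections) with configurable
  site, seasonal, spatial-decay, N-addition, core, and neutral
  components, plus ground truth for every taxon.

## Worked example

Simulate a regional survey (five sites, nested plots and N subplots,
three cores per subplot), rarefy, and run the nested PERMANOVA:

```python
from spatiomic import (
    SimulationConfig, simulate_design, simulate_community,
    rarefy, bray_curtis, permanova, mle_design,
)

cfg = SimulationConfig(design="mle", seed=7)
meta = simulate_design(cfg)
soil = meta[meta["niche"] == "soil"]
table, truth = simulate_community(cfg, soil)
rare, dropped = rarefy(table, depth=10_000, seed=7)
result = permanova(bray_curtis(rare), meta, mle_design(), n_perm=999, seed=7)
print(result.round(3))
```

```
               df     SS     MS  pseudo_F     R2  omega2  p_perm
term
Site            4  4.891  1.223    26.306  0.695   0.664   0.001
N add           1  0.033  0.033     0.711  0.005  -0.002   0.755
Site*N add      4  0.053  0.013     0.283  0.007  -0.019   1.000
Plot(Site*N)   28  1.301  0.046     4.625  0.185   0.145   0.001
Residual       76  0.764  0.010       NaN  0.108     NaN     NaN
Total         113  7.041    NaN       NaN  1.000     NaN     NaN
```

Site dominates (ω² = 0.664, p = 0.001 at 999 permutations) while the
weak simulated N effect is undetectable — the degrees of freedom mirror
the field design (4 site, 1 N, 4 interaction, 28 plot-within-site×N).
Continuing with core selection on the same rarefied table:

```python
from spatiomic import occupancy_abundance, rank_taxa, bc_contribution_curve, select_core, fit_neutral

stats = occupancy_abundance(rare, meta, group_by="site")
ranked = rank_taxa(stats)
curve = bc_contribution_curve(rare, list(ranked.index))
core = select_core(curve, rare, threshold=0.05)
nm = fit_neutral(stats, N=10_000, n_samples=rare.n_samples)
```

prints a core of 18 of 400 taxa (4.5% of OTUs carrying 52.0% of reads)
and a Sloan fit of m = 0.291 with R² = 0.764: a small, persistent,
high-abundance core — the pattern these selection rules are designed to
expose.

The same stages are scriptable from the shell (`spatiomic simulate`,
`rarefy`, `alpha`, `distance`, `permanova`, `protest`, `gdm`, `core`,
`run regional|season`); `spatiomic run` executes a whole analysis bundle
and writes per-stage TSVs plus a manifest with seeds and a config hash.

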