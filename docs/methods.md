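# Methods

This note records the statistical models implemented in `spatiomic`,
the assumptions they make, the defaults and numerical choices, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Study design the package assumes

The analyses target a two-level field design:

* **Regional** ("mle" scaffold): five sites, four plots per site (one
  site with three, its first block decommissioned), each plot split into
  an N-addition and a control subplot, three soil cores and three
  adjacent root samples per subplot, one collection date. 114 samples
  per niche; 38 plot-by-treatment subplot cells in 10 site-by-treatment
  cells.
* **Growing season** ("lux_arbor" scaffold): one site, four plots, two
  subplots, three cores, soils collected on 15 biweekly dates and roots
  on 6 of those dates (every 28 days), each root date having a soil
  collection exactly 14 days earlier. 24 samples per niche per
  collection effort.

Coordinates are UTM meters; core positions are fixed per subplot and
shared between niches and dates, matching a protocol in which roots are
taken adjacent to permanent soil sampling points.

## Community tables

Counts are validated as non-negative integers with unique sample and
taxon ids and positive row sums. Rarefaction subsamples each sample to
a common depth **without replacement** (multivariate hypergeometric),
drops and reports samples below depth, and retains all-zero taxa so
matrices stay alignable across niches; one seeded generator governs all
samples. Alpha diversity is richness (taxa with count > 0) and inverse
Simpson 1/Σpᵢ² on per-sample relative abundances.

The covariate outlier filter flags values outside
[Q1 − 3·IQR, Q3 + 3·IQR] with quartiles by linear interpolation
between order statistics (numpy's default, identical to R's type-7
`quantile`, the convention of the tooling this filter mirrors). NaNs
are never flagged; at least four finite values are required.

## Distances and lagged similarity

Bray-Curtis is computed on rarefied counts (equivalent to the
relative-abundance form at equal depth, which is why rarefaction comes
first). Geographic distance is Euclidean on (easting, northing);
temporal distance is |Δdate| in whole days.

The root-soil comparison pairs each root sample with (a) its spatially
nearest soil core of the same subplot on the same date and (b) the
**mean** similarity (1 − BC) over all soil samples of the same subplot
collected `lag_days` (default 14) earlier. Because field collections
drift, the soil collection nearest to (root date − lag) within ±4 days
is used; with no qualifying collection the record is flagged missing
rather than fabricated.

## Nested PERMANOVA

Sums of squares come from the Gower-centered inner-product matrix
G = −½ J D² J. Fixed factors are encoded with sum-to-zero contrasts,
interactions as contrast products, and the nested random factor
(plot-within-site×N, or plot-within-N across dates) as raw cell
dummies. A term's SS is the trace difference of projector fits: for
fixed terms the marginal (type III) difference between the full fixed
model and the model without that term; for the random term the
difference made by its dummies after all fixed terms. Degrees of
freedom are rank differences of the same projectors, which reproduces
both nested-df patterns of the target designs (28 and 6) without any
special-casing.

Pseudo-F uses the error stratum appropriate to a split-plot design:
whole-plot fixed effects over the plot mean square, the plot term over
the residual mean square — the standard expected-mean-squares logic for
a random nested factor. ω² = (SS − df·MS_err)/(SS_total + MS_err),
reported as computed (it may be negative near the null, and never
exceeds R²).

Permutation p-values use Freedman-Lane permutation of reduced-model
residuals: for each term, G is residualized on the *other fixed terms*
(the random term is deliberately left out so the error-stratum
variation survives residualization and can form the permuted
denominator), the residual matrix is permuted, and the full F ratio is
recomputed. Whole-plot terms permute intact subplot blocks (equal-sized
exchangeable units); the plot term and one-factor designs permute
samples freely. p = (b + 1)/(n_perm + 1); exhaustive enumeration of all
n! relabelings is available for small free-permutation designs and
matches Monte-Carlo in the limit.

Type III SS are additive (ΣSS + residual = total) only for balanced
designs; the regional design is mildly unbalanced (one site with three
plots), where marginal SS are reported as computed, matching the
behaviour of split-plot PERMANOVA software generally.

Beta dispersion embeds G by eigendecomposition; axes with negative
eigenvalues contribute imaginary coordinates whose squared distances
are subtracted (negative results truncated at zero with a warning). The
group centre is the spatial median, computed by damped Weiszfeld
iteration separately on the real and imaginary subspaces. Group
differences in the per-sample distances are tested by a permutation
F-test. Groups of size one are excluded with a warning.

## Ordination and PROTEST

Non-metric MDS (k = 2 by default, 20 random restarts, convergence at
stress change < 1e−6) minimizes Kruskal stress-1; metric principal
coordinates are available as a deterministic fallback. Procrustes
superimposition translates, uniformly scales, and orthogonally rotates
the second configuration onto the first, minimizing m² normalized by
the target's sum of squares, so m² ∈ [0, 1], t = √(1 − m²), and the
per-sample squared residuals sum to m². The fit is asymmetric in
orientation (fungal onto bacterial, by convention here) though the
normalized m² itself is symmetric under role swap. Significance
permutes the sample identities of the second configuration.

## Generalized dissimilarity models

Predicted dissimilarity is d̂ = 1 − exp(−η) with
η = α + Σₚ |fₚ(xᵢ) − fₚ(xⱼ)|, each fₚ a non-negative combination of
monotone I-splines (default 3 basis functions, knots at the predictor's
min/median/max — integrated degree-1 M-splines, i.e. piecewise
quadratic). Predictors measured per sample enter as
|fₚ(xᵢ) − fₚ(xⱼ)|; predictors that are already pairwise distances
(geographic meters, temporal days) enter as fₚ(dᵢⱼ). Coefficients are
fit by minimizing the binomial deviance
D = Σ 2[y ln(y/μ) + (1−y) ln((1−y)/(1−μ))] (0·ln 0 ≡ 0; observed
d = 1 shrunk by 1e−9) under α, β ≥ 0, using L-BFGS-B with analytic
gradients from both a zero start and a non-negative least-squares warm
start on the link scale; the deviance is convex in the coefficients for
this link, so the better of the two converged fits is taken. Percent
deviance explained is 100(D₀ − D)/D₀ against the intercept-only model.

Variable importance permutes one predictor's sample values (for
pairwise predictors, the sample identities of its matrix) and refits;
importance is the mean drop in percent deviance explained (percentage
points, so a sole predictor's importance equals the model's deviance
explained), and the p-value is the fraction of permutations that
explain at least as much as the observed model. Backward elimination
drops the least-important non-significant predictor (α = 0.05; ties by
smaller coefficient sum, then name) and refits until all retained
predictors are significant. Spline knots are held at the full-data
quantiles during permutations and bootstrap refits so curves remain
comparable.

Deviance partitioning fits a GDM on every non-empty subset of predictor
groups and solves the inclusion-exclusion system for the Venn-region
values; negative shared components are reported, not clipped, and the
regions sum exactly to the full model's deviance explained. Bootstrap
uncertainty refits the model 100 times with 30% of *samples* (not
pairs) withheld and reports 95% pointwise bands per spline; more than
20% failed refits aborts.

## Core microbiome and the neutral model

Taxa are ranked by the mean of (i) mean per-group occupancy (groups =
sites or dates) and (ii) replicate consistency (share of groups where
the taxon occurs in every sample), ties broken by mean relative
abundance then taxon id. The contribution curve accumulates per-taxon
|xᵢ − xⱼ| sums over ranked prefixes against the fixed full-table
denominator Σ(xᵢ + xⱼ), making contributions additive, the curve
monotone, and the terminal value exactly 1. The core is the prefix up
to the **last** rank whose inclusion raised the curve by ≥ 5% relative
to the previous value (an absolute-step variant is available behind a
flag); if no step qualifies the core degenerates to the single
top-ranked taxon with a warning. A threshold scan (core richness, read
share, and neutral-model R² across cutoffs) is exported so the
threshold choice stays in configuration.

The Sloan neutral model predicts occupancy from mean relative abundance
p̄ as 1 − BetaCDF(1/N; Nmp̄, Nm(1−p̄)) for communities of N reads
(default 10,000 — the rarefaction depth); the migration rate m is fit
by unweighted least squares on occupancy (the convention of the widely
used implementations of this model), with Wilson 95% binomial intervals
at the realized sample count classifying taxa as above/within/below the
neutral expectation. Fits with R² ≤ 0 or non-convergence are flagged
as failures (two distinct flags).

**Known bias.** When reads are sampled binomially from the Beta
stationary fractions — as real sequencing does and as the generator
does — the detection-limit approximation (indicator at 1/N) makes the
least-squares m̂ overshoot: at N = 10,000, 500 taxa, 100 samples and
m = 0.1 the fit returns ≈ 0.13 (+30%) with R² > 0.97. Replacing the
indicator with the exact beta-binomial detection probability
1 − B(a, b+N)/B(a, b) removes the bias entirely in simulation; the
package keeps the field-standard formula for comparability and
documents the bias here. Interpret fitted m as an index, not an
unbiased rate.

Differential family abundance sums member-taxon proportions per sample,
takes log2 of the ratio of niche medians (a pseudo-proportion of
1/(2N) added to both medians when either is zero, flagged), tests with
two-sided Wilcoxon rank-sum (exact for ≤ 25 per group), and controls
FDR by Benjamini-Hochberg. Guild annotations below "Probable"
confidence are cleared; multi-guild labels are collapsed through a
user-supplied mapping, with unmapped labels kept verbatim and warned.

## Synthetic-data generator

Communities are built from a log-normal baseline abundance pool
(σ = 1.5) partitioned into core (5% of taxa, 20× abundance boost —
present in every sample at depth 10,000 by construction), neutral (30%,
per-sample Beta(Nmp̄, Nm(1−p̄)) fractions then binomial reads at
m = 0.1), and structured taxa carrying multiplicative log-scale
effects: per-site offsets ~ N(0, site_sigma²) (default 1.0), smooth
seasonal sine curves with amplitude 0.5 and random phase, a spatially
autocorrelated Gaussian field with exponential covariance (range 50 m,
σ = 0.5), and an N-addition shift of 0.2 on a random 10% of taxa.
These defaults reproduce the qualitative regime of the motivating
surveys — site as the dominant factor, a real but modest date effect,
within-site distance decay, and a weak N signal. Counts are multinomial
at the configured depth (10,000 reads, the rarefaction convention).
Root samples are a convex mixture of the realized soil composition of
the same subplot lagged 14 days (weight 0.7) and a root-specific taxon
pool (0.3), so the two-week soil-to-root lead in similarity exists by
construction. All randomness flows from one seed.

The generator emulates design structure, effect directions, and
compositional sampling noise. It does **not** emulate phylogenetic or
taxonomic structure, sequencing-error or chimera artifacts, taxon-taxon
interactions, overdispersion beyond the log-normal/multinomial
combination, year-to-year variation, or covariance between the
environmental covariates and the community effects (the pipeline's
synthetic covariates are site-/date-/plot-structured stand-ins).
Passing tests therefore demonstrate correctness of the estimators under
the stated generating processes, not robustness to every property of
real survey data.

## Numerical choices and degenerate inputs

* Rank decisions in projector fits use an SVD cutoff scaled by matrix
  size and leading singular value; aliased terms are reported by name.
* Permutation p-values use (b+1)/(n+1); ties in permuted statistics
  count as exceedances (1e−12 slack).
* Unequal permutation-block sizes fall back to free permutation with a
  warning.
* I-spline knots that collide (short value ranges) are nudged apart;
  constant predictors produce an all-zero basis and can never absorb
  deviance.
* μ is clipped to [1e−10, 1 − 1e−10] inside the GDM deviance and
  gradient; pairs of all-zero samples are a hard error in Bray-Curtis.
* The Weiszfeld iteration damps coincident points at 1e−12 and runs at
  most 500 iterations (tolerance 1e−10).
* Problem sizes in the test and acceptance runs (e.g. 150–500 taxa,
  99-permutation nulls, 20-permutation importance screens) are chosen
  as the smallest sizes at which the checked properties are stable;
  the estimators themselves have no size-dependent switches.

## Limitations

* The split-plot permutation scheme exchanges whole subplot blocks
  rigidly; with strong within-block ordering effects other than those
  modelled, its exactness is approximate (as for restricted permutation
  schemes generally).
* Type III SS non-additivity under imbalance (above).
* The Sloan m̂ bias under binomial read sampling (above).
* Mixed-effects follow-up models (on diversity, dispersion, or
  concordance residuals) and figure rendering are out of scope; the
  package exports plot-ready tables instead.
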