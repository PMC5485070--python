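# Methods

`stresshap` analyses multi-stress phenotypes of an inbred *Arabidopsis
thaliana* accession panel against a marker-derived kinship matrix. This
note documents the models, the numerical choices behind them, what the
synthetic-data generator does and does not emulate, and the problem sizes
used by the shipped tests and the acceptance script.

## Genotypes and kinship

Accessions are fully inbred lines, so genotypes are haploid-coded 0/1
allele dosages; heterozygous or missing calls are rejected rather than
imputed, because the intended input is a post-QC, imputed SNP set. The
default kinship estimator is the VanRaden-type cross-product of the
column-centred, column-scaled call matrix over polymorphic markers,
`K = Z Z' / m`; identity-by-state (proportion of matching calls) is
available as an option. The estimator is recorded on the result object
because heritability and GWAS results are conditional on it. If numerical
error drives the smallest eigenvalue of K below −1e−8, `delta * I` with
`delta = |lambda_min| + 1e−8` is added and the ridge recorded; all
downstream solvers require a PSD K.

The geographic subset filter keeps accessions with latitude ≥ 30°,
longitude in [−50°, 50°] and elevation ≤ 2000 m (all bounds inclusive) —
the standard box that restricts a world-wide panel to Europe.

## Population structure

PCA is computed on the same centred/scaled matrix used for kinship.
Spatial weights are built on raw (longitude, latitude) coordinates:
default a k-nearest-neighbour graph with k = 5, symmetrized by union, then
row-standardized; a Gabriel graph is available. Raw-degree Euclidean
distances match the defaults of the classical spatial-statistics tooling
this mirrors; great-circle distances matter little at the within-Europe
scale but are an obvious extension. The Gabriel test uses the closed-disk
convention: a third point exactly on the circle whose diameter is the
candidate edge blocks that edge (so four points on a square yield the four
sides and no diagonals).

Moran's I per PC uses the analytic randomization-variance normal
approximation by default; a seeded permutation test (two-sided around
E[I] = −1/(n−1)) is provided for exactness at small n. PCs are retained by
a prefix scan: starting from PC1, keep while the Moran p-value is below
alpha (default 0.001), stop at the first failure. The alternative
"any passing PC" rule is behind a flag; the applied rule is recorded in
the result. Ward clustering of the retained PC scores uses the standard
Lance–Williams recurrence (scipy linkage); the group count is a required
parameter (study-like default 10), not selected automatically. The
group-effect test fits `response ~ life_cycle + group` by OLS and reports
the type-II F test for the group factor.

## Bioassay mixed models and stress responses

Each experiment's per-plant model has fixed genotype (GEN), treatment
(TRT) and GEN × TRT terms where a treatment exists (experiments 1–2), and
i.i.d. random effects per positional/temporal term:

* experiment 1: B, R, S, B×R×S, B×R×S×T, B×R×S×T×X, B×R×S×T×Y
* experiment 2: B, B×T, B×T×X, B×T×Y
* experiments 3–4: B, B/SB

Interaction terms are independent effects per observed level combination,
one variance each, no covariances. The REML criterion is profiled over the
residual variance and maximized over log variance ratios
`gamma_k = sigma2_k / sigma2_e` with an analytic gradient; everything is
evaluated from sufficient statistics (X'X, Z'Z, Z'X, Z'y, ...), so the
cost scales with the number of random-effect levels, not plants. L-BFGS-B
(bounds on log gamma of [−20, 12]) is followed by a damped-Newton polish
that pins the stationary point to ~1e−10 gradient so results are invariant
to fixed-effect reparameterization; components below ~2.5e−9 of the
residual are reported as zero. The solver was checked against a dense
`V = sigma2_e I + sum_k sigma2_k Z_k Z_k'` REML oracle and against the
closed-form balanced one-way ANOVA estimators.

Genotypic predicted means are fixed-effect cell means with random terms at
zero; a `shrink_genotype` flag refits with genotype as a random term and
reports BLUP-shrunken means instead (the choice is recorded on the fit).
Stress responses are percentage weight reductions,
`100 (W_baseline − W_stressed)/W_baseline`, with the no-stress control as
baseline — except the combined drought + *Pieris* treatment, whose
baseline is the drought-only treatment. Thrips silver damage (mm²) and
aphid counts pass through unchanged. Negative percentages are valid data
(stressed plants can outgrow controls). A baseline mean ≤ 0 makes the
ratio undefined and is an error for that accession.

Accessions are winter annuals iff flowering time without vernalization is
≥ 75 days (inclusive); plants that never flowered are winter annuals by
definition (censored flag).

## Narrow-sense heritability

`y = mu + g + e`, `g ~ N(0, va K)`, `e ~ N(0, ve I)`, solved by one
eigendecomposition of K and Brent search over `log(va/ve)` in [−10, 10]
(profiled REML), followed by three Newton steps so estimates are exact
under shifting/scaling of the trait. `h2 = va/(va+ve)` always satisfies
the ratio identity; solutions at the search boundary are flagged. An
identity-like kinship makes the profile flat in the ratio — that case is
detected (likelihood range < 1e−6 across the grid) and reported as a
degenerate h2 = 0 with a warning rather than an arbitrary interior value.
Standard errors come from the observed curvature of the profile via the
delta method.

The trait-summary table reports Min/Mean/Max/CV%/N on the scale of the
stored responses (percent, mm², counts) plus h2, va, ve per trait;
per-trait failures (e.g. constant columns) are flagged without aborting
the table.

A caution from the simulations: single-trait h2 estimates under a
deme-structured kinship have large sampling SD (±0.1–0.15 at n = 300)
because the eigen-spectrum is concentrated; means across seeds are
unbiased. The noiseless limit (h2 → 1) is only sharply identified when K
is rank-deficient (fewer markers than accessions), which is how the
property is exercised in the tests.

## Bayesian animal models

All three model types share a Gibbs sampler in the eigenbasis of K, where
the genetic effects have a diagonal prior covariance and every update is
O(n) per iteration:

* fixed effects — flat prior, joint Gaussian conditional;
* variances — a partially collapsed update: the ratio vg/ve is
  slice-sampled from its marginal given the fixed effects, with the
  genetic effects integrated out analytically (O(n) per evaluation in the
  eigenbasis), then ve is drawn from its closed-form inverse-gamma
  conditional. The priors are the (V, nu) scaled inverse-gammas (shape
  nu/2, scale nu·V/2): V = 1, nu = 0.002 on both components for the
  Gaussian models; V = 0.002/2.002, nu = 2.002 on the genetic variance of
  the threshold model. Collapsing removes the strong coupling between the
  genetic effects and their variance that makes naive single-site Gibbs
  mix slowly (lag-1 autocorrelation drops from ~0.75 to ~0.02 at thinning
  50 on a 300-accession fixture);
* rotated genetic effects — independent Gaussian conditionals redrawn
  after the variance update (zero-eigenvalue directions carry no genetic
  effect).

The binary life-cycle model is a probit threshold model via latent
truncated-normal augmentation with residual variance fixed at 1 for
identifiability. Complete separation by a covariate warns (posterior is
prior-driven) instead of failing.

Summaries: posterior mean, 95% HPD interval (equal-tailed by flag),
`pMCMC = 2 min(P(>0), P(<0))` floored at 2/n_retained so it is never zero,
lag-1 autocorrelation and effective sample size per parameter; a flag
records whether every monitored lag-1 autocorrelation is below 0.1, the
chain-quality criterion used throughout. Chains are bit-reproducible given
(data, prior, settings, seed). Full defaults are 150 000 iterations,
thinning 50, burn-in 50 000 for the Gaussian models, and ten-fold longer
for the threshold model. The sampler's residual-variance conditional was
verified against the closed-form inverse-gamma posterior
(Kolmogorov–Smirnov).

Trade-off models regress each single stress on the other four single
stresses plus life cycle over complete cases, one Gaussian animal model
per stress.

## Two-trait MTMM GWAS

Composites: PC1 of the standardized responses in which summer annuals are
the more resistant (*P. rapae*, *P. xylostella*, drought + *Pieris*,
*Botrytis* + *Pieris*) and PC1 of those in which winter annuals are
(thrips, aphids, drought). Each composite is standardized to unit
variance and its sign fixed so that it correlates positively with the
group's mean standardized response — PC sign is otherwise arbitrary and
would flip effect directions.

The null model `vec(Y) ~ N(X beta, Vg ⊗ K + Ve ⊗ I)` (trait-block outer
ordering) is fitted by REML over the six free parameters of (Vg, Ve) via
log-Cholesky parameterization (PSD by construction), initialized from
single-trait variance splits and the phenotypic correlation, optimized by
Nelder–Mead with one restart. With identity-like kinship only Vg + Ve is
identified; the fit flags that degeneracy. (Vg, Ve) are then plugged in
and held fixed for every SNP — the standard plug-in approximation; the
per-SNP model is

    y = s1 mu1 + s2 mu2 + x beta + (x ∘ s1) alpha + upsilon

whitened per kinship eigen-index by the inverse Cholesky factor of the
2×2 covariance, reducing every test to nested OLS on the whitened stack:
full (beta = alpha = 0, 2 numerator df), common (beta = 0 against
alpha = 0, 1 df), specific (alpha = 0 against full, 1 df), exact F
p-values with the residual df of the larger model (2n − 4 or 2n − 3).
Markers enter at MAF > 0.05 (strict). The GLS machinery collapses exactly
to textbook stacked OLS when the plug-in covariance is spherical, which is
asserted against a brute-force oracle in the tests.

QTL windows: SNPs at −log10 p ≥ 4 (default) seed windows of 20 kb total
span centred on the SNP (floored at position 1); touching windows on a
chromosome merge; regions are numbered in genome order and exported as
0-based half-open BED. The 20 kb default is the total span (±10 kb); a
half-window reading (±20 kb) is available via `window_bp` since the
convention is genuinely ambiguous in common usage. LD r² is the squared
Pearson correlation of 0/1 columns within a window (NaN against
monomorphic companions).

## Synthetic data generator

The generator defines the study conditions for all tests:

* **Genotypes** — 8 demes (10 in the study-like preset) placed uniformly
  in a European-scale box (lon −10..30, lat 36..62); per-marker ancestral
  frequencies Uniform(0.08, 0.92); deme frequencies drift on the logit
  scale with spatially correlated perturbations (exponential covariance,
  range 8°, SD 1.2), producing isolation by distance; accession calls are
  Bernoulli draws; coordinates are deme locations jittered by 0.8°.
  Markers monomorphic in the sample are dropped. Default panel 240 × 3000
  (study-like preset 308 accessions).
* **Traits** — additive genetic values `N(0, Vg ⊗ K)` for the seven
  responses, with per-trait totals and narrow-sense heritabilities set to
  the observed trait summary (h2 0.41/0.60/0.39/0.67/0.25/0.90/0.34;
  total variances 203/192/250/286/381/86/31 on the response scale) and
  default genetic correlations of −0.2 (drought vs *P. rapae*) and −0.3
  (*P. rapae* vs aphids), the observed trade-off pattern.
* **Life cycle** — probit on standardized latitude (+1.0) and elevation
  (−0.6) plus a kinship-structured liability (SD 0.7), calibrated to a
  29% winter-annual fraction; winter annuals flower at ≥ 75 days or are
  censored. Per-trait winter effects use the observed sign pattern and
  magnitudes (−9.21, +4.61, +7.37, +10.68, +10.40, −3.50, −1.75).
* **Bioassays** — per-plant weights invert the percentage-reduction
  definition around a log-normal 10 g baseline (sdlog 0.1 — percentage
  responses are scale-free, so this choice is inert), with additive
  block/rack/shelf/tray/row/column effects (SDs 1.0/0.3/0.3/0.3/0.3/
  0.15/0.15 g) and 0.8 g residual noise; experiments 3–4 add block
  (SD 1.5), sub-block (SD 1.0) and residual (SD 3.0) noise on the damage/
  count scale. Three calibration accessions recur in every experiment-1
  block — without them block effects would be confounded with genotypes.
  Experiment 2 drops a random 14% of accessions (germination failure).

What it does not emulate: linkage disequilibrium beyond deme structure (no
recombination map), selection, genotype-by-environment interaction,
non-Gaussian count noise for aphids (counts are continuous proxies,
truncated at zero on the accession level), or spatially correlated
residuals within trays. Passing tests therefore demonstrate correctness of
the estimators under the generating model, not robustness to those
real-data features.

## Problem sizes in tests and the acceptance script

The shipped suite runs the statistical checks at reduced sizes chosen so
each property is still sharply testable: heritability recovery at
300 × 2000 over 20 seeds per level; MTMM calibration with 1000 null SNPs
at n = 240; the planted trade-off at 240 × 1500 over 20 seeds with
4000-iteration chains; mixed-model recovery at 50 accessions × 6
replicates. `scripts/acceptance.py` runs the full pipeline on the
study-like preset (308 accessions, ~3000 polymorphic markers) with
experiment-1 replication reduced to 2 and chains of 30 000 (Gaussian) /
60 000 (threshold) iterations, then reports the computed quantities as
JSON. These sizes are the package's stated desk-scale conditions; the full
defaults (six replicates, 150 000 / 1.5 M iteration chains) remain the
configuration defaults for real analyses.

One consequence of reduced replication worth knowing when reading the
acceptance output: percentage responses from the same experiment share the
estimated control baseline, so its sampling noise induces a positive
correlation between derived responses (e.g. drought and *P. rapae*). At
two replicates this artifact is of the same order as the generator's weak
default genetic trade-off (−0.2) and can mask its sign in the single
pipeline run; the trade-off detection guarantee is therefore tested on
accession-level responses with the planted correlation of −0.5, where it
holds in ≥ 16/20 seeds.

## Known limitations

* Missing genotype calls are rejected, not imputed.
* The bioassay solver assumes the fixed design is full rank; aliased
  GEN/TRT combinations raise an error rather than being dropped.
* Only two traits in the MTMM; only one genetic variance component
  (no epistatic kinships).
* Asymptotic/posterior intervals only — no parametric bootstrap.
* The plug-in (null-model) covariance in the per-SNP GLS tests slightly
  deflates significance for SNPs with very large effects, the usual cost
  of not re-estimating variance components per SNP.
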