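# Methods

`gsel` implements a complete desk-scale genomic-selection (GS) study for
multi-family populations of fully inbred small-grain breeding lines:
simulation of the populations and traits, adjustment of field-trial
phenotypes, five genomic estimated breeding value (GEBV) prediction methods,
marker-based relatedness and linkage disequilibrium (LD), and the
cross-validation (CV) machinery used to measure prediction accuracy within,
across and between populations.

## Population and genome model

**Genome.** The default genome is 21 chromosomes of 150 cM with evenly
spaced dominant presence/absence markers (120 per chromosome, 2,520 total),
mimicking a hexaploid-wheat-sized DArT panel. Positions are chromosome-local
centimorgans.

**Recombination.** Meiosis follows the Haldane map function with no
crossover interference: between adjacent markers separated by `d` Morgans a
crossover occurs with probability `r = 0.5 (1 - exp(-2d))`; chromosomes
assort independently and each chromosome's starting haplotype is uniform.
Interference would change junction spacing but none of the quantities
studied here, so the simplest model consistent with a cM map is used.

**Founders.** Parents are fully inbred, so each contributes one binary
haplotype. Per-marker allele frequencies in the founder pool are drawn from
a U-shaped Beta(0.15, 0.15) spectrum. This was calibrated once so that two
populations built from overlapping 110-parent subsets of a 160-parent pool
segregate for roughly 1,250 markers each with roughly 1,100–1,200
polymorphic in both — the degree of partial panel sharing characteristic of
independent elite breeding pools genotyped on one array.

**Line types.** A doubled haploid (DH) is a single F1 gamete with its
genome doubled (one meiosis). A recombinant inbred line (RIL) is produced
by single-seed descent from the F1 for `selfing_generations` selfing
meioses (default 8); residual heterozygous positions at the end are
resolved by a fair coin. Internally every line is simulated as a
parental-origin mosaic, so recombination junctions can be counted exactly;
RILs accumulate close to twice the junctions of DH lines (the measured
RIL(F8)/DH ratio is ~1.9, inside the 1.7–2.1 band expected from
map-expansion theory at finite selfing generations).

**Default populations.** `study_populations()` builds two ~350-line
populations (70 crosses x 5 lines each from 110 parents), one DH and one
RIL by default. Cross plans with 8–10 lines per F1 (the classical DH
scheme) are available through `CrossPlan`/`random_cross_plan`.

## Trait model

A trait architecture is `n_qtl` distinct QTL markers (default 100) drawn
uniformly from a marker pool, with i.i.d. Normal(0, sigma_a^2) additive
effects attached to the allele coded 1 (`sigma_a = 1` by default; the
phenotype scale is arbitrary). The genetic value of line *i* is
`g_i = sum_k beta_k x_ik`; Gaussian noise is added with variance
`Var(g) (1 - h2) / h2`, computed from the *realized* variance of `g` in the
simulated population, so the line-mean heritability of the simulated trait
equals the target in expectation. Calibration: the mean realized
`Var(g)/Var(y)` over 200 replicates is within ±0.01 of the 0.3 and 0.6
targets at n = 350. QTL markers stay in the predictor matrix — markers are
their own QTL proxies, as with a real array.

**Partially shared architectures.** To study cross-population prediction
when the two populations express different QTL subsets, a common 100-QTL
set is drawn on the markers polymorphic in both populations, and each
population's trait uses a subset of it. Two schemes exist:

* *independent* (default): each trait draws `round(f * n_qtl)` QTLs
  independently without replacement; the expected shared proportion of each
  subset is `f`.
* *overlap*: both subsets have fixed size and exactly `round(p * k)` common
  QTLs, for an explicitly set overlap `p`.

Inside the grid experiment the independent scheme is realized as prefixes
of one per-replicate QTL permutation. A permutation prefix is a uniform
without-replacement draw, so the per-cell distribution is unchanged, but
replaying the same replicate stream at every fraction nests the subsets and
couples the whole accuracy curve: differences between adjacent fractions
then reflect the sharing level rather than replicate noise (a common-
random-numbers design).

## Phenotype adjustment and heritability

Stage 1 (within trial): `Y_ij = mu + G_i + B_j + e_ij` with fixed genotype
and sub-block effects and a sum-to-zero constraint on blocks, fitted by
least squares. Breeding lines are unreplicated; the repeated control
cultivars present in every sub-block are what identifies the block effects.
A line's adjusted value is its observation minus the estimated block
effect. On noise-free data with known offsets the genotype values are
recovered exactly, and the operation is idempotent.

Stage 2 (across locations): `Y_il = mu + G_i + Location_l + e_il` with
random genotype and fixed location. Balanced data use the exact
expected-mean-squares decomposition: `sigma2_e = MS_E` and
`sigma2_g = (MS_G - MS_E) / l`, truncated at zero (and flagged) when
`MS_G < MS_E`, with the genotype F test `MS_G / MS_E`. Unbalanced data fall
back to REML (random line intercept) with a boundary-corrected
likelihood-ratio test. Line-mean heritability is
`h2 = sigma2_g / (sigma2_g + sigma2_e / l)` — the standard entry-mean
definition for a line evaluated once at each of `l` locations.

## GEBV prediction methods

All estimators are scikit-learn compatible (`fit(X, y)` / `predict(X)`).
Marker columns are centered with the *training* means; target genotypes are
centered with the stored training means, never their own.

**RidgeBLUP (RR-BLUP).** `beta = (Xc'Xc + lambda I)^-1 Xc' (y - ybar)` with
`lambda = (1 - h2)/h2 * sum_j Var(x_j)`, the value implied by partitioning
the additive variance equally per unit of marker variance. When no trait
heritability is supplied the default is `h2 = 0.37`. The dual (n x n) form
is used when markers outnumber lines.

**BayesianRidgeGEBV (BRR).** Gibbs sampler for `y = 1 mu + X beta + e` with
`beta_j ~ N(0, s2_beta)` common to all markers and scaled-inverse-chi-square
priors on both variances. Defaults: residual scale 4.5 (df 3), effect scale
0.009 (df 3), 20,000 burn-in of 60,000 iterations, thinning 10 for the
stored variance samples. Reported effects are posterior means.

**BayesianLassoGEBV.** The normal–exponential (double-exponential marginal)
hierarchy: `beta_j ~ N(0, s2_e tau2_j)`, `tau2_j ~ Exp(lambda2/2)`, latent
scales updated by inverse-Gaussian draws, and `lambda2` given a Gamma(1,
rate) hyperprior whose mean equals the shrinkage implied by a heritability
of 0.37: `lambda2_0 = 2 sum_j Var(x_j) (1 - h2)/h2` (from the prior effect
variance `2 s2_e / lambda2`). Both samplers run single-site updates with a
maintained residual (one sweep is O(n p), compiled with numba), and are
exactly reproducible given the chain seed.

**GBLUP.** Mixed-model BLUP on a marker relationship `K = Xc Xc' / c`
(`c` = mean diagonal). The variance ratio `delta = s2_e/s2_g` is estimated
by spectral REML: the restricted likelihood is profiled in the eigenbasis
of the centered kinship, leaving a one-dimensional optimization. GEBVs are
`ybar + K[:, t](K_tt + delta I)^-1 (y - ybar)`. With `K = Xc Xc'/c` this is
algebraically identical to RidgeBLUP at `lambda = c * delta`; the identity
holds to ~1e-15 in the tests. Centering always leaves one null eigenvalue,
so `strict=True` flags rank deficiency *beyond* that direction (duplicated
or excessively related lines) as a "kinship singular" error — the classical
animal-model failure mode; by default a 1e-6 diagonal jitter is applied
only if the mixed-model system itself is near singular.

**KernelRidgeGEBV (RKHS).** Gaussian-kernel ridge:
`K_ij = exp(-d2_ij / theta)` on squared Euclidean marker distances,
`alpha = (K + r I)^-1 (y - ybar)`. The default bandwidth is the median
pairwise squared distance (median heuristic); the default ridge is 1.0. At
zero regularization a tiny numerical floor (1e-10) keeps the solve defined
while preserving interpolation to ~1e-6.

**RandomForestGEBV.** Bagged regression trees with random feature
selection, 500 trees and `mtry = n_markers // 3` (the standard regression
default), via scikit-learn's forest; deterministic given its seed.

## Accuracy and cross-validation

Accuracy is the Pearson correlation between GEBVs and observed (or
simulated) phenotypes; a constant vector makes it undefined (flagged NaN
and excluded from summaries with a logged count). Three schemes:

* **single** — within one population, `round(0.8 n)` training lines (341
  lines split 273/68), the rest validating; 200 iterations by default;
* **composite** — populations pooled (after marker harmonization), then
  resampled as one;
* **cross** — per iteration, 80% of the training population(s) fit the
  model and a 20% sample of the held-out population is predicted.

Every iteration refits the model; a master seed spawns per-iteration
substreams so any iteration is reproducible in isolation. Stochastic
estimators are reseeded per iteration from the stream.

## The QTL-sharing experiment

For each sharing fraction (0.1–1.0 by 0.1) and heritability (0.3, 0.6), and
50 replicates per cell: draw the common architecture, derive the two
(partially shared) trait architectures, simulate both traits, train ridge
on the full first population, predict the full second, record the
correlation. Measured behavior with the default populations: accuracy rises
almost linearly with the shared fraction, from statistically null at 10%
sharing (mean r ≈ 0.01–0.04, well within twice the per-replicate SD of
~0.08–0.12) to ≈ 0.22 (h2 = 0.3) and ≈ 0.39 (h2 = 0.6) at full sharing,
with the higher-heritability curve uniformly on top. This reproduces, as a
simulation property, the failure of cross-population prediction when
architectures are only partially shared. Note that at 10% sharing the
*expected* accuracy is small but positive (≈ f times the full-sharing
accuracy under the linear decay), so "null" is a statement relative to the
replicate spread, not a point zero; a test against the standard error of
the mean would reject at any realistic replicate count. The disjoint-
architecture null (no shared QTLs at all), whose expectation *is* exactly
zero by sign symmetry of the independent effects, is tested against 2
standard errors of the mean.

## Problem sizes and numerical choices

* The statistical test suite and the reproduction script run scaled-down
  versions of the expensive pieces, chosen as sizes at which every effect
  of interest is comfortably resolved: Gibbs equivalence checks at
  100 x 300 with 20k/120k chains; CV determinism and the disjoint null on
  an 840-marker genome; the five-method concordance on a 1,260-marker
  genome with 15 CV iterations and 2k/7k chains; the sharing grid at full
  2,520-marker scale with 50 replicates.
* The ridge/Gibbs equivalence check uses moderately informative variance
  priors (df 30 at the simulation's scale). With diffuse df 3 priors the
  posterior of the variance ratio is wide, and the posterior-mean effects
  differ from the plug-in matched-lambda ridge by a *systematic*
  ~0.1–0.2 sd (the expectation of a nonlinear shrinkage is not the
  shrinkage at the expected ratio); concentrating the variance posterior
  isolates the conditional ridge–BRR correspondence the check is about.
* Variance-component estimates are truncated at zero and flagged;
  eigenvalues are clipped at zero before REML; the REML search runs on
  log(delta) in [1e-4, 1e4].
* Mean imputation fills missing genotype calls per marker; all-missing
  markers are dropped with a log message. Markers are never filtered on
  minor allele frequency.
* On the five-method concordance trait (100 QTLs, h2 = 0.82), the Bayesian
  LASSO is usually the most accurate method (sparse architectures favor
  marker-specific shrinkage) and the forest/kernel methods trail slightly;
  the full spread of CV mean accuracies hovers around 0.1.

## What the simulations do and do not show

The generator reproduces the structural features that drive GS accuracy in
multi-family inbred material — family kinship, marker panel sharing, DH/RIL
map expansion, controlled trait architecture and heritability — and the
field-trial emulator reproduces the unreplicated-lines-plus-repeated-
controls design with additive block and location effects. It does not
model selection, drift across cycles, genotype-by-environment interaction,
epistasis, marker ascertainment bias, or genotyping error. Passing tests
therefore certify the estimators and the resampling machinery, and the
*direction* of the population-sharing effects, but say nothing about
absolute accuracies attainable on real field data, which depend on trait
architecture and environment structure outside this model.

## Known limitations

* The RKHS implementation is one member of the kernel-method family
  (Gaussian kernel, fixed median-heuristic bandwidth); no kernel averaging
  or bandwidth tuning.
* The Bayesian samplers report posterior means only; credible intervals
  would need the full thinned chains (the scalar variance chains are kept,
  the effect chains are not, to bound memory).
* The unbalanced-ANOVA REML fallback reports a likelihood-ratio p-value
  rather than an exact F test.
* Dominant 0/1 coding on inbreds conflates allele dosage with presence;
  heterozygous or outbred material is out of scope.
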