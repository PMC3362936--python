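# Methods

`tolgen` implements a quantitative-genetic analysis of disease resistance
and tolerance in a broiler population challenged with ascites, together
with a matched synthetic-population generator so that every stage of the
analysis can be exercised and validated end to end. This note documents
the models, the estimation machinery, the simulator, the numerical
choices, and what the validation results do and do not show.

## Traits and models

Four traits drive the analysis. Body weight at 2 and 7 weeks (BW2, BW7,
grams) and heart ratio (RATIO, the right-ventricle share of total heart
weight in percent, an indicator of ascites severity and hence of
resistance) are observed; the reaction-norm decomposition of BW7 defines
two latent traits per animal, the 7-week weight of a healthy bird
(INTERCEPT, g) and the tolerance slope of weight on severity (SLOPE,
g/%). Severity enters as the plateau-linear covariate

    RATIOPlat = max(0, RATIO - threshold),    threshold = 29%,

so healthy birds sit at zero and only affected birds carry severity
information.

Three mixed animal models are fitted by REML:

* **model 1** (BW2, BW7):
  `y = mu + animal + dam + GENDER + BATCHxSTABLE + AGE + e`,
  with `animal ~ N(0, sigma2_G A)` over the full pedigree (A the
  numerator relationship matrix) and `dam ~ N(0, sigma2_M I)` an
  environmental litter effect without pedigree;
* **model 2** (RATIO): model 1 plus the fixed effect of the heart cutter
  (PERSON, 11 levels);
* **model 3** (tolerance): a random-regression model for BW7 with a
  correlated random intercept and slope on RATIOPlat at both the animal
  (pedigree, unstructured 2x2) and dam (IID, unstructured 2x2) levels,
  fixed gender, batch-by-stable, age and cutter effects, a fixed
  population slope with slope-by-batch-stable and slope-by-cutter
  interactions, and a separate residual variance in each of five severity
  classes (RATIOPlat = 0, (0,5], (5,10], (10,15], >15). Interval
  membership at the inner edges is left-open/right-closed so the healthy
  class contains exactly the plateau. An optional fixed BW2 covariate
  guards against severity being confounded with early growth.

Age effects are fitted as class factors (recording ages take a handful of
discrete day values), and all factors use reference-level (first-level)
coding; the slope-by-factor interactions use the same reference
constraints as their intercept counterparts.

Bivariate and extended fits stack two single-trait designs: random terms
shared by name become blocks of correlated effect columns (2x2 for
trait-mean pairs; 3x3 over trait, intercept and slope for the extended
fits), and the residual gains one cross-trait covariance parameter for
same-animal record pairs. Phenotypic correlations are assembled from the
summed (co)variance components, not from raw data.

## Covariance functions

A fitted 2x2 block G over (intercept, slope) gives the genetic (or
maternal) variance of BW7 at any severity t as the quadratic form
x'Gx with x = (1, t)', and the genetic correlation between healthy birds
(t = 0) and birds at severity t as

    r(t) = (s00 + t s01) / sqrt(s00 (s00 + 2 t s01 + t^2 s11)).

Combining both trajectories with the class-specific residual variances
yields V_P = V_G + V_M + V_E, h^2 = V_G/V_P and m^2 = V_M/V_P pointwise
(the decomposition holds exactly by construction). The default grid runs
from RATIOPlat 0 to 20 in steps of 0.5, reported against back-transformed
heart ratios 29-49%; V_E at a grid point is the variance of the class
containing the point. The maternal trajectory uses the dam-level block
with the same formulas.

## REML engine

All fits run through one sparse average-information (AI) REML engine:

* The mixed-model equations `C s = W'R^-1 y`,
  `C = W'R^-1 W + diag(0, G^-1)`, are factored with a hand-written
  simplicial sparse LDL' (elimination-tree symbolic analysis, up-looking
  numeric factorization, numba kernels). `G^-1` uses Henderson's sparse
  A-inverse built directly from pedigree triplets with the inbreeding
  adjustment; inbreeding coefficients come from a gametic-contribution
  recursion so the full A is never formed (the dense tabular method is
  retained as a small-pedigree test oracle).
* Equations are eliminated youngest-animals-first, with dam effects and
  the dense fixed-effect rows last. On pedigree MMEs this
  structure-aware ordering produced an order-of-magnitude less fill than
  generic minimum-degree orderings in our benchmarks.
* Exact first derivatives of the restricted likelihood need selected
  elements of `C^-1`; these come from the Takahashi recurrences on the
  factor pattern, with the nearly dense trailing block (parents, dams,
  fixed effects) inverted by BLAS through its Schur complement.
* Updates are Newton steps using the AI matrix, taken in a log-Cholesky
  parameterization (log-diagonal/free off-diagonal Cholesky factors of
  each covariance block, log residual variances) so every proposal is
  automatically positive definite, with per-coordinate step clipping at
  4 log-units and step halving on likelihood decrease. When an AI step
  fails, a monotone EM-REML step (also exact, via the same selected
  inverse) substitutes. If progress stalls on a likelihood ridge, an
  L-BFGS-B polish with exact analytic gradients in the transformed space
  finishes the job.
* Convergence: relative log-likelihood change below 1e-8 with stable
  parameters, or a relative parameter change below 1e-6, within 200
  iterations. If the polish cannot improve the likelihood further the
  optimum is declared reached even when a component sits on a boundary.
  Variance components collapsing to zero with non-positive scores are
  pinned at a small floor and flagged; block correlations beyond |0.985|
  are reported with a boundary flag (a perfectly correlated block is a
  boundary estimate, not an interior one).
* Standard errors are square roots of the inverse AI matrix at the
  optimum; SEs of heritabilities, maternal ratios and correlations use
  the first-order delta method through that matrix. Degenerate curvature
  yields NaN SEs rather than fabricated ones.

The engine's likelihood, scores and ML correction were validated against
an independent dense marginal-covariance implementation and numerical
gradients; on balanced half-sib designs REML reproduces the closed-form
ANOVA estimators to 1e-6 relative, and on pedigree-free random-intercept
models it matches statsmodels' MixedLM (estimates and log-likelihood).

## Information criteria and the threshold scan

AIC = -2 logL + 2k and BIC = -2 logL + k ln(n), with k the number of
variance parameters and n the record count, follow the usual
mixed-model-software convention when reported for a single fit. The
plateau-threshold scan (candidates 27, 28, 29, 30%) is a comparison
between models whose severity covariate differs, and restricted
likelihoods are not comparable across changing fixed designs (the
log|X'V^-1X| term scales with the covariate). We observed exactly this
failure mode — a systematic drift of the scan toward the largest
candidate — before switching the scan's criteria to the full (ML)
log-likelihood evaluated at the REML estimates, with k counting fixed
plus variance parameters. The published AIC/BIC values for this
comparison are on an unstated likelihood scale; only their ordering
(plateau better than linear) is treated as reproducible. The linear
comparison model uses severity = RATIO - 29 without plateau capping and
keeps the same five residual classes so both models estimate the same
parameter count.

The kink-location signal that separates neighbouring thresholds is weak:
it rests on the few hundred birds whose heart ratio falls between the
candidates, each contributing a mean shift of at most ~2 x 14.6 g against
a residual standard deviation near 210 g. Scan power is therefore low at
reduced scale and moderate even at the full design size; the validation
checks the scan at the full 7,722-bird scale and treats majority-correct
selection as the achievable property.

## Significance conventions

Variances and variance ratios are called significant when the estimate
minus 0.98 standard errors stays above zero (one-tailed); correlations
when |estimate| exceeds 1.96 standard errors (two-tailed). These are the
analysis's reporting conventions, kept verbatim — not likelihood-ratio
tests. Note that the one-tailed rule marginally calls an estimate equal
in size to its own standard error significant (x - 0.98 x > 0).

## The synthetic population

The generator reproduces the study design forward from its reported
structure: 83 sires each mated to ~15.7 dams (788 dams, dams shared
between sires), 7,722 offspring in 5 batches x 2 stables, hearts cut by
11 people, ~9% mortality removing week-7 records, and a handful of
additional missing BW2/RATIO records matching the reported trait counts.
A balanced `reduced(n_sires, dams_per_sire, offspring_per_dam)` preset
gives the scaled-down populations used in tests.

Genetics: every animal carries a 4-vector of additive values for (BW2,
RATIO, INTERCEPT, SLOPE), founders drawn from N(0, G4) with variances
(309, 15.1, 10640, 57.8) and the reported genetic correlation structure;
non-founders are parent averages plus Mendelian-sampling deviations with
variance 0.5 (1 - (F_s + F_d)/2) G4. Dams additionally carry an
independent maternal 4-vector with variances (59.3, 1.17, 2771, 23.0)
and the reported maternal correlations. Slightly indefinite (rounded)
correlation matrices are projected to the PSD cone by eigenvalue
clipping with the unit diagonal restored.

Phenotypes: RATIO is an ordinary normal trait (mean 28.2, total variance
46.72, residual variance by difference), giving ~45% of birds above the
29% threshold — the plateau-linear world the tolerance model assumes,
not a two-component mixture. BW2 is normal around 248 g (V_P = 946).
BW7 is built from the reaction norm: intercept part (mean 2080 g) plus
(population slope -14.6 g/% plus slope deviations) times RATIOPlat, plus
a residual whose variance depends on the severity class. Fixed-effect
level values are modest relative to trait SDs (e.g. +-30 g gender
contrast on BW7, ~25 g batch-stable SD, ~1 g/% slope-interaction SDs),
drawn once per population and centered to sum to zero so the configured
means and population slope remain the identifiable population values.

The five BW7 residual-class variances are not reported anywhere; they
are calibrated at run time so that the class-wise phenotypic coefficients
of variation reproduce the published sequence 11.5, 11.7, 13.8, 15.2,
19.1% given the default genetic and maternal components, evaluating each
class at its expected severity under the RATIO distribution. This is the
only reported constraint on the residual heterogeneity.

What the generator does not emulate: deep ancestral pedigrees (founders
are unrelated, whereas the study had 2,677 ancestors over 25
generations; the machinery handles arbitrary pedigrees, the default
population just does not exercise deep ones), selection across
generations, batch-specific hatching logistics, any physiological
mechanism of ascites, and a mixture structure for heart ratio.
Consequently, passing recovery tests show that the estimation machinery
is unbiased for data satisfying the model's own assumptions at the
study's design scale — not that the biological conclusions would
replicate on other populations.

## Known estimand subtlety: the fixed population slope

Severity is computed from the simulated RATIO phenotype, which under the
default correlation structure is genetically (r = -0.36) and maternally
(r = -0.80) correlated with the tolerance slope. Affected birds
therefore carry systematically more negative slope deviations, and the
fixed population slope recovered by the reaction-norm model estimates
the mean slope among affected birds — roughly
(cov_G + cov_M)/V_P(RATIO) x E[RATIO excess | affected] ~ -1.9 g/% below
the structural -14.6 (about -16.3; zeroing the two correlations in the
generator restores recovery to within Monte-Carlo error). The same
conditioning is inherent to fitting the model on real data, where the
published slope is likewise the conditional estimand. The validation
reports the faithful model-3 estimate and documents the shift rather
than redefining either the generator or the estimator around it.

## Problem sizes used in the validation

Worked-example arithmetic is exact and instant. Recovery studies use:
100 replicates of 40 sires x 8 dams x 10 offspring for the BW2
mean-model heritability; 20 replicates of 30 sires x 10 dams x 10
offspring (~3,000 birds) for the tolerance components; 10 replicates of
42 sires x 10 dams x 12 offspring (~5,000 birds) for the population
slope; and 10 full-design populations for the threshold scan. Replicate
seeds derive deterministically from a single base seed. Monte-Carlo
standard errors accompany every recovered mean, and recovery is judged
within two of them.
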