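# Methods

## The estimand

For person *i*, usual intake of component *k* is the long-run average daily
amount, evaluated at a *reference recall context*: weekday, first recall,
reported "same as usual" amount. Recall-context covariates (weekend incl.
Friday, sequence, more/same/less) are nuisance reporting effects; fixing them
at reference levels makes subgroup comparisons reflect diet, not interview
circumstances. Population targets are survey-weighted functionals of the
usual-intake distribution: per-component mean HEI-2010 score, the mean total
score, and the percent at the component maximum (share meeting the
recommendation).

## HEI-2010 scoring

Standards live in a versioned config (`dietqual/data/hei2010_standards.yaml`)
keyed by component, with units and the two anchors (density earning 0 points,
density earning full points). The maximum-score anchors are the published
density standards; the zero-score anchors for the moderation components and
the fatty-acid ratio (refined grains ≥ 4.3 oz/1000 kcal, sodium ≥ 2.0 g/1000
kcal, empty calories ≥ 50% of energy, ratio ≤ 1.2) are the published HEI-2010
constants, kept in config so they are auditable. Scores are linear between
anchors and clamped — one formula serves adequacy (uphill from 0), moderation
(downhill), and the ratio component.

Empty calories = solid-fat kcal + added-sugar kcal + 7 kcal/g × alcohol grams
*in excess of* 13 g per 1000 kcal. A profile with unsaturated fat but exactly
zero SFA has an unbounded ratio: we return `inf` with a warning (scores at
the cap) rather than invent a finite value; no fat at all is an error.

## Transforms

Amounts and energy use Box–Cox with exponent fixed at 0.25; the fatty-acid
ratio uses log. Transformed values are centered and scaled to variance 2 from
the analysis sample, and the (shift, center, scale) triple is stored per
component so the map is exactly invertible. The zero-handling shift δ (half
the smallest positive observed amount) is applied **only when zeros actually
occur** among the modeled amounts. Episodic amounts are modeled conditional
on consumption and are therefore positive, and strictly positive components
(energy, sodium) need no shift; a blanket shift would be a large, pointless
distortion for energy (~hundreds of kcal).

Back-transformation must not simply invert the mean — the inverse transforms
are convex — so usual intake is computed as the expectation of the inverse
over the within-person residual, by 9-point Gauss–Hermite quadrature (exact
for the quartic Box–Cox inverse; a second-order Taylor correction exists as a
cheap fallback). The quadrature is verified against adaptive numerical
integration in the tests.

## The measurement-error model and its estimator

On the transformed scale, with 12 components + energy (K = 13):

    z_ijk = x_ij' β_k + b_ik + e_ijk,  b_i ~ N(0, Σ_b), e_ij ~ N(0, Σ_e)

and, for components with more than 10% zero recalls (config threshold), a
probit consumption model with its own person effect u_ik ~ N(0, σ_uk²).
Assumptions: normality on the transformed scale, within-person residuals
independent across days, consumption indicators independent of the amount
residuals, and consumption-probability effects independent of the amount
effects. That last independence is a deliberate model restriction: with at
most two recalls per person, the probability–amount random-effect correlation
is barely identified and coupling them makes the person-level posterior
non-Gaussian; the synthetic generator's default matches the restriction.

Estimation is deterministic and moment-based, with an exact-EM refinement:

* **Fixed effects** β_k: per-component OLS on observed (consumption-day)
  rows; reported SEs are cluster-robust by participant with a G/(G−1)
  small-sample factor, computed from the *marginal* residuals (person effect
  plus day noise).
* **Covariances**: for persons with both recalls, the cross-recall residual
  covariance estimates Σ_b (symmetrized), and the average within-recall
  covariance minus Σ_b estimates Σ_e; both use pairwise-complete moments
  (episodic amounts are missing on non-consumption days) and are projected
  to the nearest positive-semidefinite matrix by eigenvalue clipping.
* **EM refinement** (default 2 passes): the Gaussian posterior of b_i given
  each person's observed residual pattern is available in closed form, so
  the E-step is exact; the M-step updates Σ_b from posterior second moments,
  Σ_e from posterior-centered residuals, and β from posterior-mean-adjusted
  outcomes (a working-independence conditional M-step).
* **Episodic submodel**: marginal probit plus a concordance-matched random
  effect (matching the observed rate of consuming on both days through the
  bivariate normal CDF, computed via Owen's T) initializes a full
  maximum-likelihood fit of the random-effects probit with 15-node
  Gauss–Hermite integration.

A fit refuses to proceed without at least one two-recall participant (the
within-person variance is otherwise unidentified) and flags non-convergence
of the probit optimizer. Covariate columns without variation (e.g. sex inside
a single-sex subgroup refit) are dropped automatically.

## Usual-intake draws and the pseudo-population

Given the fitted model, each person's effects b_i have a Gaussian posterior
determined by their observed residual pattern; persons sharing a pattern
share a posterior covariance (computed once per pattern). The episodic
person effect u has a non-Gaussian posterior given the 0/1 consumption
history; it is drawn from a 41-point grid approximation of its density.
A pseudo-population row is then: draw (b, u), set covariates to the reference
context, Gauss–Hermite back-transform, multiply episodic components by
Φ(x_ref'γ + u). With M draws per person, each row carries weight w_i / M.

Age/sex standardization is model-based: draws are regenerated with age set to
the standard mean (41.30 years) and sex redrawn per pseudo-row at the
standard proportion male (47.76%), so subgroup contrasts do not reflect
age/sex composition. Subgroup summaries refit the model per subpopulation
(all parameters free to differ); a `share_model` flag trades that for speed.
Percent-at-maximum uses an absolute tolerance of 1e-9 points, purely to
absorb float rounding in "score equals the maximum".

## Survey estimation

Weighted means, weighted variances, Taylor-linearized SEs of means and of
regression coefficients (stratified-cluster sandwich over PSU totals with the
n_h/(n_h−1) factor), and the Rao–Wu rescaling bootstrap: within stratum h,
resample n_h − 1 PSUs with replacement and rescale weights by
m × n_h/(n_h − 1). Rao–Wu is the documented choice among bootstrap variants;
it is design-consistent and keeps all replicate weights nonnegative. Designs
must have ≥ 2 PSUs per stratum (a lone PSU raises an error suggesting
certainty-PSU handling). Any stage that should sit inside the bootstrap —
including refitting the measurement-error model per replicate
(`refit_per_replicate`, default on in the pipeline) — is re-run per
replicate on the participants of the resampled PSUs (the model fit itself is
unweighted; replicate weights enter at the summary stage); the cheap
alternative reweights the fixed pseudo-population.

## Correlates regression

The outcome is the person-level HEI total from recall-*averaged* intake:
amounts and energy are averaged across available recalls first, then scored
once (average-then-score; densities come from averaged amounts, not averaged
densities). Estimation is weighted least squares with the Taylor sandwich;
inference uses t/F references with design degrees of freedom (#PSUs −
#strata). Backward selection drops the least significant non-forced term
while its p-value exceeds 0.1, with categorical predictors tested and
dropped as whole blocks via joint Wald tests (selection operates on
"variables", not dummy columns); ties break toward the larger p, then
alphabetically, and every drop is logged with its p-value. Field center and
heritage are always retained. R² is the weighted R² of the final fit.
Reference levels follow the study convention (Mexican heritage, Bronx
center, no-high-school education, lowest income, obese, current smoker,
inactive).

## The synthetic generator

The generator emulates the study's data structure, not its food supply:

* covariates with configurable marginals (six heritage groups with the
  cohort's published mix as default, four field centers, SASH acculturation
  scores, weight status, smoking, activity, conditions);
* a stratified design (default 8 strata × 6 PSUs) with lognormal weight
  dispersion;
* person effects drawn on the transformed scale from a multivariate normal
  (default exchangeable correlation 0.3 across the 13 dimensions), with
  day-to-day residual SDs chosen 1.5–1.7× the between-person SDs — the
  high intraindividual variability regime that motivates the correction;
* three episodic components by default (whole fruit 0.70, greens and beans
  0.55, seafood and plant proteins 0.50 consumption probability) with
  probit-scale person effects (SD 0.8);
* context effects (weekend Friday–Sunday, sequence, reported usual amount)
  as small additive shifts on the transformed scale, shared across
  components through per-component responsiveness multipliers;
* default daily amounts sized for a ~2000 kcal diet so that component
  densities straddle their standards (some recommendations commonly met,
  sodium and fatty acids rarely — mirroring the field's typical findings).

Truth is defined exactly as the estimand: the within-person expectation of
the back-transformed amount at the reference context, times the consumption
probability. Because truth is generated on the transformed scale, the
fitting model is correctly specified by default; a `misspecified_noise`
toggle substitutes skewed (scaled χ²₄) day-to-day residuals for robustness
experiments. What the generator does **not** emulate: food-level reporting,
nutrient-coding error, correlated nonresponse, informative weights, or
probability–amount random-effect correlation — so passing recovery tests
demonstrate estimator correctness under the stated model, not robustness to
real-world coding artifacts.

## Problem sizes and numerical choices

Recovery experiments run at n = 2000 participants × 2 recalls with M = 100
draws (the full-scale validation) and n = 600 × 20 replicates for the
variance-correction property; regression calibration uses 50 replicates at
n = 1200. These sizes put every experiment within a few minutes on a single
core while leaving parameter noise small relative to the effects tested.
Matrix inversions add a relative ridge of 1e-8; posterior covariances are
symmetrized and sampled through eigendecomposition with clipped eigenvalues;
essentially constant transformed samples fall back to unit scale rather than
amplifying float noise.

## Known limitations

* With two recalls per person, finite-cohort noise bounds how precisely the
  realized cohort's usual-intake distribution can be recovered: the cohort's
  mean day-to-day noise (order σ_w/√(2n) on the transformed scale) is
  absorbed into the fitted intercepts and no estimator can separate it from
  the true mean, and tail shares compare posterior probabilities against
  realized person effects. At n = 2000 this leaves percent-at-max
  discrepancies of a few percentage points on the worst of the 12
  components even though variance parameters are recovered essentially
  unbiased; mean scores are much tighter. Larger cohorts or more recalls
  per person shrink both terms.
* The probability–amount independence restriction (above) means correlated
  preference effects — people who rarely eat fish also eating less of it
  when they do — are not captured.
* Fixed-effect estimation is working-independence OLS/EM rather than full
  GLS; the efficiency loss is small at survey sizes.
* The bootstrap treats the first-stage PSU resampling as capturing all
  design variance (standard Rao–Wu practice); second-stage finite-population
  corrections are not implemented.
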