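# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices made where the design was genuinely open. Every
number quoted as a check here is computed by the test suite or the
acceptance script; nothing is asserted that the code does not compute.

## The feasible utility space

The UK EQ-5D-3L time-trade-off value set is embedded as eleven
constants (a full-health constant of 0.081, per-dimension level-2 and
level-3 decrements, and the any-level-3 term 0.269). Scoring all
3⁵ = 243 states yields utilities in [−0.594, 0.883] ∪ {1}: state 11111
scores exactly 1, the pits state 33333 scores −0.594, and the largest
value strictly below full health is 0.883 (state 11211), leaving the
open gap (0.883, 1) unattainable. The value set is a replaceable
object, but only the UK 3L tariff ships. Utilities are plain floats;
feasibility is enforced by validators rather than a numeric type.

## ALDVMM likelihood and estimation

Each mixture component is a normal distribution censored to the
feasible space: latent values at or above Ψ = 0.883 are observed as 1,
values at or below L = −0.594 as the floor, interior values as
themselves. An observed y exactly equal to Ψ is treated as interior
(density), y = 1 as the upper mass; values inside the gap are rejected
as infeasible input. Component membership is a multinomial logit with
the last component as reference; scales are log-parameterised.

Numerical choices:

- **Optimisation.** L-BFGS-B on the negative log-likelihood with
  analytic gradients, over a design standardised internally
  (coefficients and covariances are mapped back exactly afterwards).
  Default 20 randomised starts from quantile-block initial values;
  tolerance 1e−6 on the gradient, at most 500 iterations per start;
  best final likelihood wins, ties broken by start index. After the
  best start, up to two polish restarts from the incumbent squeeze
  flat mixture ridges further.
- **Degeneracy.** Censored normal mixtures have unbounded likelihood
  when a component scale collapses onto interior observations. Scales
  are bounded below at 0.04 on the utility scale; a start whose
  bound-hitting component is mostly interior *and* carries under 2 % of
  the posterior mass is a spurious spike and is rejected (an error is
  raised only if every start degenerates). A component at the bound
  that models the full-health mass is legitimate and only warned about.
- **Convergence flag.** Reported from the *projected* gradient: at an
  active scale bound the raw gradient may push outward while the KKT
  conditions hold. Large mixtures (the 4-component model has 81
  parameters) can end on very flat ridges with the flag False while
  predictions are stable; the flag is informative, not fatal.
- **Label switching.** Components are relabelled in decreasing order of
  average membership probability; the robust covariance is permuted
  (and the membership block re-based) to match.
- **Inference.** The covariance is the sandwich A⁻¹BA⁻¹ with A the
  numerical Hessian of the negative log-likelihood (central differences
  of the analytic gradient) and B the outer product of per-patient
  score sums — cluster-robust for repeated visits.
- **Information criteria.** AIC = 2k − 2ℓ and BIC = k ln n − 2ℓ with n
  the number of observations. QIC is computed as
  −2ℓ + 2·trace(A·V_robust), the working-independence analogue of AIC
  for clustered data; its exact form is not standardised, so AIC/BIC
  are primary for selection.

Predictions are the analytic expectation: per component, the
full-health mass plus the floor mass plus the doubly-truncated normal
mean, mixed by the membership probabilities. A prediction always lies
in [−0.594, 1]; note that as an average of a mass at 1 with interior
values it *can* legitimately lie inside the gap (a patient with perfect
QLQ-C30 scores maps to ≈ 0.95), whereas simulated draws never can.

## Response mapping

Stage one fits an ordered probit per EQ-5D dimension on the comparator
design (the 15 rescaled scores, age, age²) via maximum likelihood
(statsmodels), with cutpoints absorbing the intercept. An empty
level-3 cell (expected for mobility and self-care, which sit near 1 %
level 3) degrades that dimension to a binary probit with the second
cutpoint pinned at +6 on the latent scale, with a warning. Stage two
multiplies the marginal level probabilities over the 243 states
(independent latent errors by default) and takes the tariff-weighted
expectation.

Exactly replicating the multilevel seemingly-unrelated estimation of
the source analysis is out of scope; as an optional extension, a
Gaussian-copula correlation layer estimates the 10 pairwise latent
error correlations by bivariate-probit likelihood (a polychoric-style
estimate conditional on covariates, subsampled for speed, projected to
the nearest positive-definite correlation matrix) and evaluates state
probabilities with a seeded GHK simulator (500 draws by default,
normalised to sum to 1). At identity correlation the GHK path
reproduces the product rule within simulation error.

## Linear comparator

A random-intercept linear model (statsmodels MixedLM, maximum
likelihood; pooled OLS when no patient has repeated visits) on the
comparator design. Predictions use fixed effects only — mapping
targets out-of-sample patients — and are deliberately not clamped:
leaving [−0.594, 1] is the comparator's documented flaw and must stay
observable. Its cluster-robust covariance is the GEE-style sandwich
under the fitted marginal covariance σ_u²J + σ_e²I.

## Synthetic-data generator

The generator emulates the published structure of the estimation data
(an advanced-breast-cancer trial panel, ~602 patients, ~3 800 visits):

- **Covariates.** One standard-normal severity factor per record
  (variance split 50/50 between a patient level and a visit level)
  drives all 15 scales with loading 0.65 — positive for global health
  and the functional scales, negative for symptoms. Each scale is a
  location-scale transform of a latent normal clipped to [0, 100]; the
  latent parameters are solved from censored-normal moment equations so
  the *clipped* scores match the published per-scale means and SDs
  (naive clipping would shift the global health mean by ≈ 0.4 points).
  Age ~ N(54, 10.5²), truncated to [25, 90], constant within patient.
  Visit counts are 1 + negative binomial with mean 6.34.
- **Utility truth.** A 4-component ALDVMM whose calibration anchors are
  the published component summaries (probabilities 0.2213/0.3213/
  0.1686/0.2888; means 0.6720/0.8238/0.4740/0.7781; SDs 0.070/0.242/
  0.371/0.126). Per component, the latent location and total SD are
  solved so censored draws reproduce the anchor moments; the total
  variance is then split between covariate slopes, a patient-level
  random intercept (SD 0.05 on the latent scale, standing in for the
  unreported within-patient autocorrelation) and the residual scale.
  Slope magnitudes scale per component (factors 1/7.5/4/1.5 on a small
  base) within each component's variance budget: the narrow component
  (SD 0.070) can carry almost no covariate signal, while the wide
  full-health and poor-health components carry most of it. Membership
  depends on global health with a strong quadratic term for the
  full-health component and a negative linear term for the poor-health
  component, giving the inverse-S mean-utility curve (flat middle,
  acceleration into the spike at 1, plunge toward the floor) that
  characterises EQ-5D data and defeats linear mapping at both ends.
  A final two-knob adjustment (a common location shift and the
  full-health membership intercept) sets the analytic pooled mean and
  full-health share exactly to the published data values (0.715, 23 %)
  on a fixed internal reference sample; this step trades the per-
  component shares slightly for exact pooled anchors.
- **Response truth.** Per-dimension latent indices (global health plus
  one dimension-specific scale) with cutpoints placed at empirical
  quantiles of a fixed reference sample so the marginal level shares
  hit their targets — level 3 at 1 % for mobility and self-care as
  observed, plausible values for the rest — and latent errors
  correlated at 0.45 across dimensions.
- **Missingness.** MCAR at the row level (default rate 4.2 %, the
  published drop rate): a hit row has one random outcome or covariate
  cell blanked, so the complete-case filter removes it.

What the generator does *not* emulate: treatment arms, disease
progression, visit timing, informative dropout, or the exact
correlation structure among the 15 scales (one factor rather than a
multi-factor structure). Passing tests therefore show that the
estimators recover known truth and reproduce the published
distributional geometry — not that the shipped coefficients equal the
unpublished ones fitted to the trial.

## Test problem sizes

Parameter-recovery checks run 20 Monte-Carlo replicates at n = 5 000
(two-component mixture on a one-covariate design; ordered probits;
random-intercept model at 500 patients × 6 visits) and compare the
mean estimate against truth within three replicate standard errors.
The severity-bias and diagnostic checks fit the full 17-covariate
4-component mixture once on a ~2 400-observation panel. Oracle checks
use an independent scipy censored-normal likelihood (100 random draws,
agreement to 1e−6) and a 10⁶-draw Monte-Carlo mean. These sizes keep
the whole suite under a few minutes while leaving the Monte-Carlo
error small relative to the tolerances tested.

## Known limitations

- QIC follows a documented but non-unique definition.
- The response mapping omits patient-level random effects inside the
  probits; its correlation layer is pairwise, not joint, estimation.
- The convergence flag is conservative on large mixtures (see above).
- The generator's pooled calibration is exact on its internal reference
  sample; a finite generated panel deviates by sampling (and patient-
  cluster) noise, which the calibration tests account for.
- Only the UK 3L tariff ships; other value sets would slot into the
  ValueSet object but are untested.
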