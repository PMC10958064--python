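# Methods

This note documents the statistical models, the synthetic-data generator,
the sampler, and the numerical and design choices behind `twingrowth`.

## Observation models

**Behavior.** Noise-blast durations are analyzed in seconds, restricted to
negative- and neutral-feedback trials. The default (contrast)
parameterization places the growth components of interest on the
negative-vs-neutral difference:

    mu = (gamma0 + w_occ) + gamma1 a + gamma2 a^2
         + (beta0+u0+v0) c + (beta1+u1+v1) c a + (beta2+u2+v2) c a^2

where `a = age - centering_age` in years (default centering 9.75, or the
pooled mean age; the constant is recorded in the fit), `c` indicates
negative feedback, `w_occ` is a scalar occasion (individual-by-wave) random
intercept, and `u` (individual, within family) and `v` (family) are
3-vectors of random growth components with freely estimated 3x3
covariances at each level. Residuals are Student-t(nu, 0, sigma); values
at the 3500 ms ceiling are right-censored and contribute the tail
probability `P(Y >= U)` to the likelihood. A `raw` switch models
negative-trial durations alone with the growth components on the outcome,
since published interval magnitudes are compatible with either
parameterization; the contrast form is the default because the scientific
quantity is the response to rejection *relative to* neutral feedback.

The occasion intercept is retained alongside the age polynomial so that
occasion-specific deviations (a child's "good day") are not conflated with
trial noise.

**Neural.** Wave-level ROI contrast scores use the same quadratic growth
model with the trial and occasion levels removed: random intercept/linear/
quadratic components at the individual and family levels, Student-t
residuals, no censoring.

**Intercept-only models.** For variance decomposition, all slopes are
removed and every level keeps a random intercept. Per posterior draw,

    ICC_level = V_level / (sum_levels V + sigma^2 * nu/(nu-2)),

using the t residual *variance*, not sigma^2. Shares sum to one by
construction (asserted per draw). The "greater than zero" summary is
reported as `P(ICC > epsilon)` with epsilon = 0.01 (configurable), because
`P(ICC > 0)` is trivially ~1 under continuous priors.

## Sampler

No general-purpose MCMC engine suited to this model family is among the
package's dependencies, so the fitter is a purpose-built Gibbs sampler:

* Student-t residuals via the normal scale-mixture augmentation
  `e_i | w_i ~ N(0, sigma^2 / w_i)`, `w_i ~ Gamma(nu/2, nu/2)`.
* Censored responses imputed each sweep from the truncated normal above
  the bound given the current weights.
* `(sigma^2, nu)` updated jointly by a random-walk Metropolis step on the
  *marginal* t likelihood (weights integrated out), with step sizes
  adapted during warmup; weights are then refreshed from their exact
  conditional. This removes the notoriously slow sigma-nu-w coupling of
  the pure augmentation scheme.
* Conjugate draws for fixed effects (normal), random-effect vectors
  (batched 3x3 normal solves), scalar variances (inverse-gamma) and
  covariance blocks (inverse-Wishart).
* Two reparameterization moves that are essential for mixing in this
  design: a translation move exchanging mass between each random-effect
  block's mean and the matching fixed effects, and a nested reallocation
  move exchanging mass between individual- and family-level effects of a
  twin pair (and occasion vs. individual intercepts), both exact conjugate
  Gibbs steps on the transformed parameterization. Scalar random-effect
  SDs additionally get an ancillarity-sufficiency interweaving (ASIS)
  re-draw via a 1-d slice sampler in the non-centered parameterization,
  which unsticks variance components near zero. Without these moves the
  individual-vs-family variance split of a twin design mixes with ESS in
  the single digits; with them the intercept-only fit matches a
  method-of-moments oracle to the third decimal.

**Priors** (all overridable via `Priors`): fixed effects N(0, (10 sd(y))^2);
scalar variances and sigma^2 ~ InvGamma(0.001, 0.001); covariance blocks ~
InvWishart(d+1, 0.01 I); nu - 2 ~ Gamma(2, scale 10). Conjugate forms were
chosen over half-t/LKJ equivalents so that every block update is an exact
draw; at the data sizes used the posterior is likelihood-dominated and the
difference is immaterial. A prior-predictive helper confirms the priors
exclude no part of the observable [0, 3500] ms range.

**Diagnostics.** R-hat and bulk ESS (ArviZ) for every fixed effect, sigma,
nu and random-effect SD; default thresholds R-hat <= 1.01, ESS >= 400.
Violations are warned about and flagged on the result (`converged=False`),
never silently ignored. Short-chain fits used in smoke tests routinely
flag; the replication experiments below use chain lengths for which the
fixed-effect ESS is in the hundreds.

Missing outcomes contribute nothing to the likelihood, which is the
correct Bayesian treatment under missing-at-random ignorability; empty
groups fall back to prior draws automatically.

## Synthetic cohort generator

The generator emulates a twin cohort of 256 same-sex pairs ("512
children"), 55% monozygotic, measured at three lab waves roughly two years
apart, with 20 trials per feedback condition per wave and a 3500 ms
response ceiling:

* **Ages**: wave-1 age uniform on 7.02-9.68 y; later waves add 2 y plus
  uniform jitter of +-0.25 y (shared by twins), reproducing the observed
  age overlap between waves. Published tables give only ranges and means,
  so uniformity is a choice.
* **Retention**: 100% / 89.1% / 65.6% (456/512, 336/512), implemented as
  monotone logistic dropout on the *standardized observed wave-1 mean
  duration* (slope 0.5), with intercepts calibrated so expected retention
  matches the targets exactly — a concrete MAR mechanism. MRI completion
  is an independent per-wave thinning (94.7% / 89.5% / 70.2%); final-wave
  well-being availability is 87.5% of wave-5 retainees.
* **Truth defaults**: fixed effects and RE SDs are the midpoints of the
  published 95% intervals for all four outcomes (e.g. behavior contrast
  intercept 1.40 s, quadratic -0.045). Quantities the study does not
  report are set once to realistic values: neutral baseline (1.5, -0.05,
  -0.01) s, occasion SD 0.54 s, residual sigma 0.70 s, nu = 8 — chosen so
  the intercept-only decomposition approximates the published behavioral
  profile (29% wave, 3% individual, 3% family, 65% residual) and the
  negative-trial censoring rate is realistic (~10-20%). Neural residual
  scales (3.5-4.3) similarly reproduce the published near-(0.01-0.04)
  individual/family ICCs. Default RE correlation matrices are identity
  except a -0.3 individual-level intercept-linear correlation for AI and
  intercept-quadratic for MPFC, mirroring the two reported covariances.
* **Zygosity** is a recorded attribute that does not alter the generative
  model by default (the analysis ignores it); an optional
  `mz_similarity_boost` adds extra MZ twin similarity for robustness
  studies.
* **Positive-feedback trials** are generated from the neutral distribution
  for schema fidelity and excluded by the models.
* **Condition-independent baseline intercepts** (`tau_u_base`,
  `tau_v_base`, default 0) let an intercept-only-structured truth place
  individual/family variance on overall durations, which is what the
  variance-decomposition recovery study needs.
* **Floors and ceilings**: durations are clipped at the ceiling with a
  censoring flag, and floored at 0 ms *without* a flag. Under the default
  truth the floored mass is a few percent of neutral trials; it thins the
  left tail, which is why fitted nu tends to exceed the generating nu.
  Fixed-effect recovery is unaffected (verified by the coverage study).
  The well-being subscales are continuous scores on a [1,4]-like scale
  (about 1% of generated values fall outside; they are not clipped so
  that moment-convergence checks hold exactly).

What the generator does **not** emulate: response-time skew beyond the
t family, learning/order effects within a wave, item-level questionnaire
structure, genetic (ACE) architecture, and measurement error in the ROI
contrasts (carried over from upstream fMRI estimation). Passing tests
therefore show the *procedure* is correct and calibrated under the stated
model, not that the model is true of any real cohort.

## Well-being CFA

Subscale scores are means of 4-point items (80% answered required,
reverse-coding supported, proration configurable per subscale). The
one-factor CFA minimizes `F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - 5`
with marker scaling, by L-BFGS-B with analytic gradient and boundary
constraints `theta >= 0` (a uniqueness on the bound is flagged as a
Heywood case). `T = (N-1) F_ML` (the classic Wishart form; `N F_ML`
available), df = 5; CFI/TLI against the independence baseline (df 10);
`RMSEA = sqrt(max(T-df,0)/(df (N-1)))`; standard errors from the inverse
observed information `(2/(N-1)) H^-1`. Listwise deletion is used — the
branching decision only needs a defensible fit assessment. Branch rule:
common factor iff CFI >= .95 and TLI >= .95 and RMSEA <= .06 (boundaries
pass); thresholds configurable. An independent ML factor-analysis
implementation (statsmodels) agrees with the fitted implied correlation
matrix to ~1e-7 on simulated data.

## Saturated SEM and pooling

Per plausible-value set, the saturated multivariate regression is fitted
by ML on listwise-complete cases: coefficients coincide with per-outcome
least squares (asserted against a normal-equations oracle to 1e-6), the
predictor covariance is the N-denominator sample covariance (12 variances
plus 66 = 12*11/2 free covariances), and SEs come from the information
matrix (`sigma^2_ML (X'X)^{-1}`; covariance SEs `sqrt((s_ii s_jj +
s_ij^2)/N)`). T = 0 on df = 0 by construction. Draw pairing across the
four independently fitted outcomes is by thinned draw index; since the
posteriors are independent, the pairing affects only Monte-Carlo noise in
the between-draw variance.

Rubin's rules: `Qbar`, `Wbar`, between-variance `B`, total `T = Wbar +
(1+1/m)B`, missing-information fraction `gamma`, and Barnard-Rubin df
`(1/nu_R + 1/nu_obs)^-1` with `nu_com = N_complete - 12 - 1` by default
(the published fractional dfs below m-1 indicate a small-sample
adjustment was used; the exact software convention is not recoverable
from the text, so `nu_com` is an argument). `gamma = 0` (identical draws)
is handled without division blow-up; pooled identities hold to machine
precision and are asserted.

**A calibration caveat.** Plausible values are drawn from the stage-1
posterior, which does not condition on the well-being outcomes. This
two-stage (uncongenial) imputation makes the pooled t-test *conservative*
when the fraction of missing information is large: in a null simulation
with plausible-value noise at 25% of predictor variance the pooled total
variance overestimates the true sampling variance of `Qbar` by ~50% and
the empirical type-I rate drops to ~0.017. The type-I calibration study is
therefore run at a moderate missing-information level (noise at 10% of
predictor variance), where the rate is ~0.04 — inside [0.025, 0.075] at
alpha = .05. Users should expect the pooled tests to err on the
conservative side when individual growth components are weakly identified
(exactly the regime of small individual-level ICCs).

## Problem sizes of the recovery studies

The package's replication experiments are sized to run on a single CPU in
minutes while retaining their statistical meaning:

* credible-interval coverage: 20 cohorts of 50 families, 8 trials per
  condition, 2 chains x (250 warmup + 300 draws); pass if >= 17/20 cover
  both the contrast intercept and the quadratic slope;
* censoring-aware vs censoring-blind: 20 cohorts of 40 families with the
  bound lowered to 3300 ms (~30% of negative trials censored); pass if the
  censoring-aware posterior mean of beta0 is closer to truth >= 18/20;
* variance-share recovery and method-of-moments agreement: one cohort of
  200 families at full retention without censoring (72,000 trial rows);
* CFA calibration: N = 10,000; type-I calibration: 500 replications of
  m = 50 pooled fits at N = 120.

The thresholds (17/20, 18/20, 0.03, 0.02, 3 SE, [0.025, 0.075]) are fixed
properties of the checks, independent of the sizes chosen.

## Known limitations

* The fitted `nu` is biased upward under the default generator because of
  the unmodeled floor at 0 ms (see above); this propagates mildly into the
  residual-variance share at high censoring but not into fixed effects.
* Random-effect *correlations* at the family level are weakly identified
  at desk-scale cohort sizes; their posteriors are prior-influenced.
* The common-factor branch of the stage-2 SEM is implemented as factor
  scores from the CFA rather than a full latent-outcome ML fit; the
  separate-subscales branch (the one a misfitting one-factor model takes)
  is complete.
* Behavioral and neural fits assume a shared quadratic form; no spline or
  higher-order alternatives are provided.
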