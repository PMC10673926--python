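# Methods

`clonalfish` implements the statistical machinery of a clonal-fish
individuality study: repeated daily behavior measurements on individually
reared, genetically identical fish, weekly growth measurements, and a
sequence of broods per female, analysed with variance-components
repeatability, individual growth curves, and chained regression models.
This note documents the models, the generator that stands in for raw
experimental data, the numerical choices, and the limits of what the tests
demonstrate.

## Repeatability from random-intercept mixed models

All repeatabilities are intraclass correlations from a random-intercept
linear mixed model fit by REML,

    y_ij = x_ij' beta + u_i + e_ij,  u_i ~ N(0, V_ID),  e_ij ~ N(0, V_res),
    R = V_ID / (V_ID + V_res).

*Raw* repeatability uses an intercept-only model; *adjusted* repeatability
conditions on fixed covariates (size and age class for behavior; onset,
female size at parturition, mother ID, and the reciprocal trade-off trait
for reproduction).

The fitter profiles the variance ratio `lambda = V_ID/V_res` out of the
restricted likelihood: for fixed `lambda`, the GLS coefficients and the
error variance are closed-form (each individual contributes one rank-one
update, so a likelihood evaluation is O(n) after caching sufficient
statistics), leaving a one-dimensional bounded optimisation over
`log(lambda)` (Brent, absolute tolerance 1e-10).  When the profile
maximises at the lower boundary the estimate is reported as `V_ID = 0`,
never negative.  Balanced designs reproduce the one-way ANOVA
method-of-moments estimators; unbalanced fits agree with an independent
dense-matrix implementation and with `statsmodels` `MixedLM` to at least
four decimals (both checked in the test suite).

Confidence intervals for `R` are percentile intervals (linear-interpolation
/ type-7 percentiles) over `n_sim = 1000` parametric simulations: responses
are redrawn from the fitted model's own estimates and refitted, and a trait
is called significantly repeatable when the 95% interval excludes zero.  If
more than 20% of refits fail the interval is refused rather than reported.
Every stochastic operation takes an explicit seed, which is recorded in the
output alongside `n_sim`.

Fixed-effect p-values use maximum-likelihood likelihood-ratio tests for
mixed models (chi-square, df = columns removed) and partial F-tests for
plain linear models.  LRT p-values are mildly anti-conservative for
individual-level predictors when only ~34 individuals carry the information
(measured null rejection ~0.07 at nominal 0.05); Satterthwaite or
Kenward-Roger corrections would shrink this but need the full per-parameter
covariance machinery, which this package deliberately avoids.  Stepwise-
backward selection repeatedly removes the least significant removable term
with p >= alpha (default 0.05); mother ID is always protected, female size
at parturition is protected where the analysis plan mandates it, and
marginal terms are never removed while their interaction is in the model.
Ties break by larger p, then term order.

R² measures: marginal/conditional R² are computed from the variance of the
fixed-effect predictions and the variance components
(`var(Xb) / (var(Xb)+V_ID+V_res)` and `(var(Xb)+V_ID) / (...)`).  Partial R²
for a term is `1 - RSS_full/RSS_reduced` in plain regressions (equal to
`t²/(t²+df)` for one-column terms) and the drop in marginal R² on removing
the term (floored at 0) in mixed models.

## Behavior metrics

Daily *activity* is the average distance moved per second: total Euclidean
path length over consecutive valid sample pairs divided by total valid
elapsed time, at a nominal 0.2-s sampling step.  Pairs separated by more
than 3x the nominal step are treated as recording gaps and excluded from
both numerator and denominator; nothing is interpolated, because
interpolation would fabricate movement.  Daily *feeding time* is the number
of samples inside a fixed 5 x 13 cm rectangle around the food patch times
the step length (boundary inclusive, left-closed dwell attribution),
reported in minutes.  Activity is log-transformed for repeatability
modelling; raw activity is used as the response in the daily
activity~feeding model.  Both metrics agree with naive loop implementations
to 1e-9 relative on random tracks.

## Growth

Each individual's weekly standard lengths are fit with the von Bertalanffy
growth model `L(t) = L_inf (1 - exp(-K (t - t0)))` (sometimes loosely
called logistic in the fish literature; the implemented form is the
standard von Bertalanffy curve, which is not logistic).  Fitting is
Levenberg-Marquardt nonlinear least squares with an analytic Jacobian,
`K > 0` enforced by optimising `log K`.  Starting values: `L_inf` at 1.05x
the observed maximum, `K` and `t0` from a regression of
`log(1 - L/L_inf0)` on age; three perturbed restarts guard against local
minima and the best-RSS converged solution is kept.  Flat (no-growth)
series are flagged unconverged instead of returning arbitrary parameters.
Noiseless series are recovered to 1e-6 in all three parameters; on noisy
series the fitted RSS is never worse than a 40^3-point grid search.  All
downstream size covariates (e.g. female size at each parturition) are
predictions from these curves rather than raw measurements; predictions
before `t0` are clamped at zero with a warning.

## Reproduction

A female's profile is the ordered sequence of broods (age at parturition,
brood size, measured offspring lengths).  Onset is the age at first
parturition.  The offspring-size response in all models is the per-brood
mean length; per-offspring rows are kept for descriptive output only.
Broods whose offspring were counted but not measured remain in brood-size
analyses and drop out of offspring-size analyses (complete-case), which is
why offspring-size models can have fewer broods than brood-size models.
Cumulative reproductive output is the right-continuous step function of
summed brood sizes.

The trade-off-adjusted models are two brood-level mixed models with an
individual random intercept: mean offspring length on brood size, onset,
female size at parturition and mother ID; and brood size on mean offspring
length plus the same covariates.  Their variance components give the
adjusted repeatabilities ("productivity" differences remaining after the
trade-offs are controlled).  No multiple-testing correction is applied —
models are reported individually, matching standard practice for this kind
of per-model analysis.

## Linkage models

Per-individual behavioral predictors are means over the 28 observation
days (untransformed; a log-activity toggle exists).  Three model groups
run through stepwise selection:

1. direct: brood size and mean offspring length (brood-level LMMs) and
   onset (individual-level LM) on mean activity + mean feeding, with mother
   ID and (in the brood-level models) female size at parturition protected;
2. growth: `L_inf` and `K` (LMs) on mean activity + mean feeding, the `K`
   model keeping `L_inf` as a protected covariate;
3. growth -> reproduction: brood size, offspring size (LMMs) and onset (LM)
   on `K` and `L_inf`, with female age at parturition as a removable
   covariate in the brood-level models.

Individuals missing any stage are dropped listwise with a logged manifest;
fewer than five shared individuals is an error.

## Synthetic cohort generator

The generator is the package's stand-in for the experiment and defines the
conditions under which everything is tested: 34 individuals, 28 daily
behavior records each, weekly sizes to day 280, broods every ~30 days after
an onset near day 160 (about 4.5 broods per female by day 280), and ~17
offspring per brood.  Latent individual effects for log-activity and
feeding are bivariate normal (default correlation -0.5: more active fish
spend less time at the stationary food patch); independent latent effects
drive brood size (log-scale, Poisson counts) and offspring size.  Daily
behavior adds an age trend (activity rises, feeding falls over the four
weeks) plus within-individual noise, so raw repeatability sits below
adjusted repeatability as in real cohorts; defaults put raw R near 0.37
(log-activity) and 0.18 (feeding).

Growth and reproduction encode the causal chain the linkage stage is meant
to detect: `L_inf` increases with an individual's mean feeding time (0.02
cm per minute against a 0.15 cm residual SD), onset increases with `L_inf`
(55 days/cm), brood size and offspring size increase with female size at
parturition, and offspring length trades off against brood size (-0.013 cm
per offspring).  There is *no* direct behavior -> reproduction effect;
behavior reaches reproduction only through growth.  Note one consequence:
in the unadjusted onset model the mediated feeding -> size -> onset path is
sometimes detected as a "direct" feeding effect — a property of strong
mediation under model selection, not a generator defect.

Trajectories are generated separately as a persistent-heading random walk
(heading SD 0.6 rad/step) at constant per-day speed `exp(latent
log-activity)` inside a reflecting 20 x 20 cm arena (dimensions are a
package default; only the 5 x 13 cm zone size is fixed by the study
design).  During the feeding phase the heading is blended toward the zone
centre with weight increasing in the latent feeding effect.  The walk is
structurally, not quantitatively, faithful: it reproduces the calibrated
log-activity scale exactly (constant step length) and a monotone
feeding-effect -> zone-occupancy mapping, but no real movement statistics.
Full resolution (0.2 s, 10 h/day) is available; tests and examples use
scaled-down phases so a cohort simulates in seconds.

What passing tests therefore show: the estimators recover the generative
parameters under the model's own assumptions (Gaussian effects, correct
mean structures, VB growth).  They do not show robustness to model
misspecification — non-Gaussian individual effects, overdispersed counts
analysed as Gaussian, tracking artefacts — beyond the mild Poisson/Gaussian
mismatch already built into the brood-size analyses.

## Problem sizes used in checks

Acceptance-style checks run at the study scale (34 individuals) with: 50
replicates for repeatability recovery (R in {0.2, 0.4, 0.6}, bias < 0.01 in
practice, tolerance +/-0.1), 100 replicate datasets x 200 simulations for CI
coverage (observed ~0.97 for a nominal 0.95), 50 replicates for
chain-structure recovery, and 20 random small datasets for the REML grid
oracle.  The acceptance script reports the same quantities at slightly
smaller replicate counts; all sizes are recorded in its JSON output.

## Known limitations

- Single random intercept only; no crossed/nested random effects, no GLMMs
  (brood sizes are Poisson in the generator but analysed with a Gaussian
  LMM, as is common for moderately large counts).
- ML LRT p-values are mildly anti-conservative at 34 individuals (see
  above).
- The breeding-tank/male robustness columns are reserved in the schema but
  no dedicated analysis is implemented.
- Whether onset should be age at first parturition or first conception is
  ambiguous in the field; this package uses first parturition.
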