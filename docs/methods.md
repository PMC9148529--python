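# Methods

This note records the statistical model behind `ecarm`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Estimand and analysis model

The target of every analysis is the marginal (covariate-standardized) odds
ratio of DAS28 remission between the stringent (trial) and pragmatic
(observational) treat-to-target strategies at each of the 6/12/24-month
visits, over the pooled covariate distribution of both cohorts (an ATE-type
estimand).  Baseline confounding is addressed by inverse probability of
treatment weighting: a maximum-likelihood logistic propensity model of cohort
membership on the full baseline covariate list (age, gender, symptom
duration, education, RF and anti-CCP status, ESR, CRP, SJC28, TJC28, patient
and physician global assessments, comorbidity, smoking, fatigue, EQ-5D-like
index), stabilized ATE weights, propensities clipped at the 1st/99th
percentiles by default.  ATT weighting is available but not the default,
since the scientific question is phrased as emulated randomization of the
combined population.

Each per-visit analysis is a weighted logistic regression of the remission
indicator on the strategy indicator.  Because the weights (IPTW, and IPCW
where used) are estimated, the default variance is the probability-weight
sandwich A⁻¹BA⁻¹ with B built from weighted score contributions; with
constant weights this reproduces the classical 2×2 (Woolf) variance exactly
on the saturated model, which the tests assert.  Wald intervals and p-values
are formed on the log-OR scale (normal reference; t with Barnard–Rubin
degrees of freedom after multiple imputation — both references are standard,
and which one the original analyses used is not documented, so the package
reports the t-based value whenever pooling supplies a finite df).

## Missingness taxonomy and the five approaches

Subject-visits are classified as observed, missing-at-visit (visit recorded,
≥ 1 DAS28 component absent), intermittent (fully blank visit with a later
non-blank visit) or drop-out (blank tail).  Two structural rules follow from
the definitions: intermittent cannot occur at the final visit, and drop-out
propagates forward.

* **Complete follow-up case** drops every subject not fully observed at all
  three visits.
* **Strict censoring + IPCW** sets subjects as drop-outs at their first
  missing-at-visit or intermittent visit (whichever comes first), producing a
  monotone pattern; sequential per-visit logistic hazard models (fit on the
  at-risk set, separately per cohort) yield cumulative weights
  ∏ⱼ 1/(1−ĥᵢ(j)), stabilized by the marginal survival.
* **MI + censoring + IPCW** first imputes missing-at-visit components, then
  censors at the first remaining intermittent gap and applies IPCW to the
  combined (created + natural) drop-out.
* **MI + IPCW** imputes missing-at-visit components and whole intermittent
  visits; IPCW handles natural drop-out only.
* **MI for all** imputes everything and runs the IPTW-weighted outcome model
  on completed panels.

Design choices where the original workflow is not fully documented, adopted
here as the package's own conventions:

* Censoring-hazard models use baseline covariates plus the last fully
  observed DAS28 (so no post-censoring information enters), fit separately
  per cohort because the two follow-up regimes differ by design; a pooled
  fit is a config switch.
* In MI-containing approaches the censoring models and weights are re-fitted
  inside each imputed dataset, and Rubin's rules pool the final log ORs —
  weights are nuisance quantities specific to each completed dataset, so
  pooling happens at the estimate level.
* IPTW is estimated once on the (complete) baseline table and reused across
  approaches and imputations; re-estimation within imputations is moot in
  the synthetic path because baselines are complete by construction.
* All MI approaches share one imputation random stream, so a cell imputed
  under two scopes receives the same draw.  A corollary used by the tests:
  when a panel has no intermittent gaps, MI+censoring+IPCW and MI+IPCW are
  literally the same computation.  With intermittent gaps present the two
  approaches differ — censoring at a gap discards that subject's later
  observed data while MI+IPCW retains it — so their 24-month estimates agree
  only statistically (both target the same estimand), not identically.

## Multiple imputation

Components (TJC28, SJC28, ESR, PGA) are imputed, never the composite score
or the binary endpoint, and the score is recomputed afterwards; draws are
clipped/rounded to legal ranges (joint counts integer 0–28, ESR ≥ 1, PGA
0–100).  Conditional models are Bayesian normal linear regressions (full
posterior draw of coefficients and residual variance) followed by predictive
mean matching with a donor pool of 5 — appropriate for bounded, skewed
components.  Predictors are all baseline covariates, the baseline DAS28
composite, and the other visit-component columns; chains run per cohort,
M = 10 imputations and 10 sweeps by default, variables visited in increasing
missingness order.

Visits missing *in their entirety* (intermittent gaps and drop-out blocks)
are imputed as blocks: a donor subject with a fully observed visit is
matched by predictive mean matching on the predicted composite DAS28, and
the donor's whole component quadruple is copied.  Independent per-component
draws wash out the strongly bimodal joint structure of the four components
around the remission threshold, which attenuates the dependence of imputed
remission status on covariates; block matching preserves it (verified by the
MAR recovery experiments).  Cells outside an approach's imputation scope are
integrated over internally during the chained sweeps and re-blanked on
output, so observed cells are preserved bitwise and the scope contract
holds exactly.

MNAR sensitivity uses a delta adjustment in DAS28 units: each wholly or
partially imputed visit is shifted by delta through one component (PGA if it
was imputed, else ESR on the log scale, else TJC28 on the square-root
scale), clipped to legal ranges.  Delta = 0 reproduces MAR imputation;
increasing delta monotonically lowers the imputed-arm remission proportion
until clipping saturates.

Rubin pooling: Q̄ the mean estimate, Ū the mean squared SE, B the
between-imputation variance, T = Ū + (1+1/M)B, with Barnard–Rubin
small-sample degrees of freedom (collapsing to the classical (M−1)/λ² when
the complete-data df is taken as infinite, the default for the moderate
sample sizes here).

## The synthetic study

The generator emulates the study conditions rather than any real dataset.

**Baseline covariates** come from simple parametric families (normal,
lognormal, Bernoulli, binomial) with means in the ranges typical of early-RA
inception cohorts.  A latent severity factor s ~ N(0,1) loads on the disease
activity measures (joint-count propensities on the logit scale, acute-phase
reactants on the log scale, VAS scales additively), correlating the
components so the baseline DAS28 composite has realistic dispersion (mean
≈ 5.2, SD ≈ 1.0).  The trial cohort is shifted relative to the observational
reference — slightly younger, slightly higher joint counts and patient
global, small education/smoking offsets.  Shifts are placed only on
normal/Bernoulli/binomial-logit covariates, which makes the true propensity
of cohort membership exactly logistic in the raw covariates, so the IPTW
model is correctly specified and balance experiments are clean.

**Outcomes.**  Remission at each visit follows a logistic model in the trial
indicator (coefficient = the configured strategy log OR; defaults 0.42, 0.77,
0.40 at 6/12/24 months) and z-scored baseline covariates (DAS28 −0.40, age
−0.10, EQ-5D +0.10), with per-visit intercepts giving control-arm remission
around 30–50 %.  These covariate effects are deliberately moderate so the
marginal log OR stays within ~0.02 of the conditional coefficient; the
generator records the exact marginal truth by standardizing the
counterfactual probabilities over the pooled sample, and that recorded value
is the reference in all recovery experiments.  Given the drawn remission
status, a target DAS28 is sampled on the correct side of 2.6 (with a subject
random effect giving trajectory continuity in severity) and the four
components are constructed to reproduce it *exactly* through the DAS28
formula — joint counts and ESR at a commensurate severity, PGA solved in
closed form, ESR re-solved and joint counts adjusted in rare infeasible
cases — so the latent remission labels are exact, not approximate.

**Missingness.**  Per-visit drop-out hazards, intermittent probabilities
(6/12 months only) and component-missing probabilities (a uniformly drawn
nonempty proper subset of the four components) act sequentially: drop-out
first, then intermittent on surviving visits, then component blanking on
retained visits.  Default presets reproduce the reported rates: trial
hazards (0.016, 0.049, 0.040) give cumulative drop-out 1.6/6.4/10.1 %;
observational hazards (0.024, 0.0697, 0.2852) give 2.4/9.2/35.1 %, with
conditional intermittent (0.0748, 0.1244) and component-missing
(0.0443, 0.0579, 0.1310) rates giving the marginal 7.3/11.3 % and
4.0/4.6/8.5 % figures.  Under MAR, mechanisms are logistic in baseline
covariates and the last fully observed DAS28, with intercepts root-found so
the *marginal* rates still match the preset values; under MNAR the latent
DAS28 of the visit being blanked enters with a user slope.  Preset MAR
directions: sicker patients drop out of the trial (+0.30 per DAS28 unit),
well-doing patients attend the observational study less (−0.30 drop-out,
−0.20 intermittent).  An interior gap whose later visits are all removed by
subsequent drop-out is reported as drop-out, keeping labels consistent with
the final data.

**What the generator does not emulate:** real joint covariate distributions,
visit-date jitter (visits are on-schedule; window mapping is exercised
separately), within-subject outcome autocorrelation beyond baseline
covariates and the severity trajectory, baseline missingness, and
treatment-switching dynamics.  Passing recovery tests therefore show the
estimators behave correctly under the stated mechanisms, not that any
particular real-data analysis is unbiased.

## Numerical choices and degenerate inputs

* ESR is floored at 1 before the logarithm; remission uses strict `< 2.6`.
* Visit-window mapping assigns each scheduled visit the nearest raw visit in
  its window, ties resolved to the *later* visit (observational visits run
  late rather than early); windows must not overlap; each raw visit is used
  once.
* Perfect separation in propensity or censoring models raises an error
  naming the covariate (and visit); censoring fits with very few events that
  fail to converge fall back to the marginal hazard with the model recorded
  as skipped; visits with zero events get hazard 0 without a model fit.
* Hazard fits require a configurable minimum at-risk count (default 15);
  fitted hazards of 1 for an uncensored subject are an error.
* Weighted outcome fits refuse constant outcomes within an arm (infinite
  OR), non-positive weights, and missing outcomes.
* All randomness flows from integer seeds through split substreams
  (generator covariates/outcomes, missingness per cohort, imputation), so a
  persisted config reproduces a run byte-for-byte and changing M does not
  perturb the generated data.

## Problem sizes used by the test suite

The simulation suites run at deliberately scaled sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances: MCAR consistency uses
40 replicates of 600 subjects per cohort with M = 5 (replicate-mean SE
≈ 0.03 against a ±0.1 band); MAR selection uses 40 replicates of 1,000 per
cohort; balance and coefficient-recovery checks use single draws of
20,000–100,000 subjects where closed-form rates are asserted to ±0.005 or
±0.1 on coefficients.  The acceptance script runs the full pipeline once at
the study sizes (188/328) with M = 10.

## Known limitations

* The chained-equations imputer assumes linear conditional means on the
  predictor scale; block matching mitigates, but does not remove, bias under
  very strong nonlinear missingness mechanisms.
* IPCW with large cumulative hazards (observational 24-month analyses) can
  produce heavy-tailed weights; stabilization is on by default and
  percentile truncation is available but off, trading variance for
  transparency.
* Only cross-sectional per-visit outcome models are provided (no GEE/mixed
  longitudinal models), matching the per-visit reporting structure.
* The delta adjustment shifts one component per imputed visit; extreme
  deltas saturate at the component range boundaries.
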