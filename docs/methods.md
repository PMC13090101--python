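# Methods

## The survival model

Each monitored nest contributes an interval-censored known-fate likelihood
term built from its encounter history (*i*, *j*, *k*): found with eggs on
day *i*, last known active on day *j*, fate confirmed on day *k*.  A day
index *t* denotes the interval from the midnight beginning day *t* to the
next midnight; "surviving day *t*" means being active at the following
midnight, and the covariates attached to day *t* are that calendar day's
values.  The daily survival rate is logit-linear,

    S_t = 1 / (1 + exp(−x_t'β)),

and the per-nest log-likelihood is

    Σ_{t=i}^{j−1} log S_t + [failed] · log(1 − Π_{t=j}^{k−1} S_t).

A hatched nest has j = k and contributes only confirmed-alive days.  A
failed nest died during exactly one of the days j … k−1; the window term is
the probability of that union.  Failures are never located sub-day, even
for camera-monitored nests: camera timestamps are treated as accurate only
to the daily-visit level.  The model has a single hazard — fate causes
(depredation, agricultural destruction, abandonment, flooding) are labels
attached after the fact, not competing risks.  Nests with undetermined
fates are retained in data files but excluded from every analysis.

Design coding: categorical factors are reference-coded indicators —
Hauts-de-France vs. Alsace, camera vs. visits, crop vs. other habitat,
four-egg vs. smaller clutches, and the later study year vs. the earlier.
Covariates enter raw (unstandardised) so coefficients are directly
comparable across fits; the optimiser must therefore cope with very
different gradient scales, which L-BFGS-B handles via its quasi-Newton
metric.

### Fitting and inference

- Start values: intercept at the logit of the Mayfield estimate
  (confirmed-alive days / (confirmed-alive days + failures)), all other
  coefficients 0 — deterministic and close to the optimum for realistic
  data.
- Optimiser: L-BFGS-B on the analytic score, `ftol` 1e−12, coefficients
  box-bounded at ±25 on the logit scale.  The bound keeps degenerate fits
  finite (a dataset with no failures pushes the intercept to +∞); any
  estimate on the bound, and any all-hatched dataset, is reported with
  `converged = False` and a diagnostic, never silently.
- Covariance: inverse of the numerically differentiated observed
  information at the optimum (statsmodels `approx_hess`), symmetrised.
- Effective sample size for AICc: total exposure days Σ(k − i) — all days
  each nest was under observation and at risk, including the failure
  window.  The same per-nest k − i accounting is used in the exposure
  summaries, with the j/k split used only inside the likelihood.

## Model selection

The candidate space is every submodel of a global model that respects
interaction hierarchy (an interaction requires both main effects); the
intercept-only null is always included.  Candidates pass through, in
order:

1. **Collinearity screen** (before enumeration): pairwise Pearson r over
   all analysis rows; pairs with |r| strictly greater than 0.65 lose the
   member lower in a configurable priority list.  Zero-variance covariates
   are dropped with a warning.
2. **Balance filter**: nests are cross-tabulated over the candidate's
   categorical factors; the candidate is inadmissible when any cell holds
   ≤ 5 nests, or (with ≥ 2 factors) a Pearson chi-square test of mutual
   independence rejects at α = 0.05.  The test is applied without
   continuity correction; specs with a single categorical factor face only
   the small-cell rule.  (α and the correction are this package's choices;
   the screening idea itself only fixes "chi-square" and "≤ 5".)
3. **Fit** of every admissible candidate, cached by term set.
4. **Uninformative-parameter screen**: a fitted candidate (other than the
   null) is excluded when *every* non-intercept coefficient's 95% CI
   overlaps 0; one informative predictor suffices to keep it.  The screen
   is applied to all fitted candidates rather than only to pairs of models
   differing by one parameter — the stricter of the two readings of this
   rule, chosen because it subsumes the single-parameter special case.
   Non-converged fits are excluded with their own reason.
5. **Ranking** of survivors by AICc = −2 log L + 2K + 2K(K+1)/(n−K−1) with
   Akaike weights; excluded candidates stay in the output table with their
   exclusion reason.

The full 17-term global model spans 15,488 hierarchical submodels.
Enumeration is cheap; fitting all of them is supported but slow, so the
bundled demo scenario uses the six-term global
`region + method + wind + lagged wind + region:method + wind:lagged wind`
(25 candidates), which is the term superset the default synthetic truth
draws from.

## Cumulative incubation survival

The probability of surviving a full incubation (27 days — the species'
average clutch incubation) from a fitted model and a season of daily
weather:

- For every admissible start day (season length − 26), the product of the
  27 predicted daily survival rates, averaged over start days.
- 1000 bootstrap replicates, each resampling whole observed days
  (covariate vectors) i.i.d. with replacement within the group's
  region-seasons.  Resampling whole days preserves within-day covariate
  pairings; the one-day-lag columns are rebuilt from the resampled order
  (the first resampled day keeps its originally observed lag) so lagged
  terms see the resampled sequence.  Alternative resampling units (nests,
  or parametric draws of β) would propagate different uncertainty sources;
  day resampling targets weather variability, which is what the window
  product integrates over.
- Re-centring: the replicate distribution's mean is shifted to the
  expected mean implied by the group's mean predicted DSR,
  (mean DSR)²⁷, by subtracting the constant discrepancy from every
  replicate.  Point estimate = corrected replicate mean (identical to the
  expected mean by construction), SE = replicate SD, 95% CI = 2.5/97.5
  percentiles of the corrected replicates.  Values pushed outside [0, 1]
  by the shift are clamped and counted.
- Categorical covariates are fixed at the group's levels (region and
  method; any other factor at the group's modal level).

## Fate contingency analysis

Fates are cross-tabulated by region or monitoring method over the six
terminal categories.  The r×c Fisher exact test computes the two-sided
p-value as the total probability (all margins fixed, multivariate
hypergeometric) of tables no more probable than the observed one, with a
1e−7 relative slack on the probability comparison to avoid float-ordering
artifacts.  Two-row tables are enumerated by a vectorised column-by-column
expansion; the count of candidate tables is computed exactly by polynomial
convolution, and enumeration is used while it stays below 5×10⁶, beyond
which the p-value is Monte-Carlo estimated from 10⁶ seeded Patefield draws
and flagged as such.

The odds ratio reported for each 2×2 collapse (one fate vs. all others) is
the conditional MLE: the value of the noncentral-hypergeometric odds
parameter ψ solving E_ψ[X] = observed cell, found by bracketed
root-finding on log ψ; boundary cells yield the likelihood limits 0 or +∞.
Fate-by-fate p-value families are Holm–Bonferroni adjusted.

## The synthetic study

The generator emulates the data-generating process the analysis assumes,
so every estimator can be validated against known truth.

- **Weather**: per region, stationary Gaussian AR(1) series (φ = 0.5) for
  daily mean soil temperature, wind speed and irradiance around a linear
  seasonal trend, wind and irradiance floored at 0; rainfall is
  Bernoulli wet days (p = 0.69) with exponential wet-day amounts.  The
  season means reproduce the two study regions' contrasts: soil
  temperature 17.2 vs. 15.5 °C, wind 0.3 vs. 0.6 m/s (Alsace vs.
  Hauts-de-France), irradiance 217 vs. 223 W/m², rainfall 2.6 vs.
  2.2 mm/day.  Daily SDs (soil 4.0 °C, wind 0.15/0.20 m/s, irradiance
  60 W/m²) and trend slopes (+0.08 °C/day, +1 W/m²/day) are generator
  choices at values typical of temperate spring seasons; the sources only
  constrain the means.
- **Truth**: logit-linear DSR with default coefficients equal to the
  published top-model point estimates (intercept −1.013; region 1.700;
  camera 1.931; wind 1.905; lagged wind 7.732; region×camera −1.708;
  wind×lagged wind −5.741); incubation fixed at 27 days; failure causes
  drawn from region-specific mixtures matching the observed fate
  compositions, as labels only.
- **Observation process**: initiation days uniform over the feasible
  window (no published initiation distribution exists; this is a
  stand-in); discovery lag uniform on 0–6 days; visit intervals on
  {5, 6, 7, 8} days with probabilities (0.05, 0.30, 0.50, 0.15), giving
  median 7 and IQR 6–7; camera assignment 20/37 (Alsace) and 72/108
  (Hauts-de-France) when not fixed per group.  Nests that die or hatch
  before discovery are redrawn — field crews never see them — which
  induces the same left-truncation the likelihood conditions away by
  starting at *i*.  For failed nests, *j* is the last visit before the
  true failure and *k* the first visit at or after it; hatched nests get
  j = k at the hatch-completion day, treating hatch dates as dateable to
  the day (eggshell evidence), so the confirmed-alive span matches the
  true at-risk days.
- **Seeding**: one master seed; per-nest substreams derived via
  `SeedSequence(master, group, nest)`, so increasing the number of nests
  never changes earlier nests.

What the generator does *not* emulate: spatial weather heterogeneity
between nests of one region (all share the regional series), renesting
after failure, cause-specific hazards, observer-dependent fate
misclassification, and seasonal variation in visit effort.  Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to these violations.

## Problem sizes and numerical choices

The validation suite runs the parameter-recovery study at 100 replicates
of 1,000 nests (140/120/420/320 across the four region×method groups) over
a 130-day season — large enough for near-nominal Wald coverage, small
enough to run in about two minutes.  The uninformative-screen calibration
uses 400 seeded replicates of 100 nests.  The demo pipeline simulates 200
nests and completes in seconds.

Tolerances: likelihood-vs-enumeration agreement is asserted at 1e−10,
Mayfield closed-form equivalence at 1e−6 on the survival scale, bootstrap
re-centring identity at 1e−12, exact-test agreement with independent
hypergeometric sums at 1e−10.  Ties in Akaike weights are exact by
construction (shared exponent shift).  Degenerate inputs — empty tables,
all-hatched data, zero-variance covariates, zero-length failure windows,
rank-deficient designs — raise typed errors or set explicit non-convergence
diagnostics rather than producing numbers.

## Known limitations

- No random effects or shared frailty: nests are conditionally independent
  given covariates.
- Single-hazard model; cause-specific inference is limited to the
  contingency analysis.
- The Wald intervals and the AICc effective-sample-size convention (total
  exposure days) are asymptotic conventions; profile likelihood and
  alternative n definitions would shift borderline screening decisions.
- The weather bootstrap propagates weather variability only, not
  coefficient uncertainty or model-selection uncertainty.
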