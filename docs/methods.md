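# Methods

This note documents the models, estimation machinery, synthetic-data
generator and design decisions behind `beliefupdate`, in the spirit of a
statistical software methods appendix. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external analyses.

## Task and measures

A trial presents an adverse life event; the participant estimates their own
lifetime risk (E1) and the risk of a comparable other (eBR), sees the event's
population base rate (BR), rates their confidence in it, and re-estimates
their own risk (E2). All quantities live on the percent scale; ratings are
bounded to the response range [3, 77], which leaves room to update toward
even the most extreme base rates (10 and 70).

Derived measures per trial:

* estimation error `EE = E1 − BR`; an alternative mode uses `eBR − BR`.
* valence: good news if `EE > 0` (the risk was over-estimated, the news is
  favourable), bad news if `EE < 0`; trials with `EE = 0` or no response are
  excluded.
* update `UPD = E1 − E2` (good news) or `E2 − E1` (bad news), so a positive
  update always means movement toward the base rate.
* update bias `UDB = mean(UPD_good) − mean(UPD_bad)` per subject; positive
  values are optimistic.
* personal relevance `PR`: the self–other discrepancy normalized by its
  maximum attainable magnitude on the 1–99 scale,
  `PR = (eBR − E1)/(eBR − 1)` when `eBR > E1`,
  `PR = (E1 − eBR)/(99 − eBR)` when `eBR < E1`, and 0 at equality, clamped
  to [0, 1]. Note the branch–denominator pairing: each formula body is
  attached to the condition under which it is a normalized magnitude in
  [0, 1]. The reverse pairing, which sometimes appears in print, produces
  values outside [0, 1] and would break its use as the weight `(1 − PR)`.
* distance `eBR − E1`.

Subjects who lose all trials of one valence are dropped from bias summaries
with a warning; no imputation is performed.

## The 12 candidate models

Eight RL-like models predict `UPD = LR · |EE|` with a valence-dependent
learning rate `LR_good = S + A`, `LR_bad = S − A`; four of them further
multiply the error by `(1 − PR)`. Four Bayesian models predict
`UPD = LR · |E1 − E2b|`-style updates, where `E2b` is the posterior estimate
from Bayes' rule: prior odds `BR/(1 − BR)` times the likelihood ratio
`[E1/(1 − E1)] / [eBR/(1 − eBR)]` (all on the probability scale), mapped back
through `odds/(1 + odds)`. Within each family, variants free or fix the
scaling (fixed value 1) and asymmetry (fixed value 0), yielding 12
enumerable specifications; PR weighting exists only in the RL family.

Sign convention: predictions are stated as positive-toward-the-base-rate
updates and reconstructed as `E2 = E1 − valence · UPD`, which makes the
prediction equation consistent with the observed-update definition for both
valences. Two consequences used as test oracles: RL with `(S, A) = (1, 0)`
predicts `E2 = BR` exactly, and the Bayesian models with `(1, 0)` predict
`E2 = E2b` exactly (which collapses to `BR` when `E1 = eBR`). Bayesian
predictions are left unclipped; the response bounds are applied only when
*generating* ratings.

The two posterior expressions (odds product and odds-to-probability map) are
implemented as sequential steps — the only reading that yields a probability.

## Estimation

The observation model is additive Gaussian noise on the observed update. The
likelihood is profiled over the noise variance (MLE `RSS/n`, floored at 1e−6
to keep perfect fits finite); free parameters carry independent Gaussian
priors with means 1 (scaling) and 0 (asymmetry) and unit variance by default.
The prior variances are a design choice, exposed in `PriorSpec`; unit
variance is broad relative to the population spread of either parameter (both
well below 1) while still regularizing subjects with few trials of one
valence.

MAP estimates come from BFGS with eight deterministic multi-starts jittered
around the prior mean (the objective is smooth and, for every model, linear
in the parameters given the trial drivers, so multi-start is belt and
braces). The log model evidence is approximated by the Laplace method,

```
F = log p(y|θ̂) + log p(θ̂) + (d/2) log 2π − ½ log |−H|
```

with `H` the central-finite-difference Hessian of the log posterior at the
MAP (relative step 1e−4). For models with no free parameters, `F` is the
profiled log likelihood. If the Hessian is not negative definite the fit is
flagged and the evidence falls back to a prior-predictive Monte-Carlo
average. The Laplace value matches the analytic Gaussian-conjugate evidence
to 1e−6 on toy problems (tested), and the MAP interpolates correctly between
the prior mean (tight priors) and least squares (broad priors).

Fitting is deliberately non-hierarchical — each subject × model pair is
inverted independently — so group comparisons are not biased by shared
shrinkage across groups of different sizes.

## Random-effects model selection

Subjects' model identities are treated as draws from a population with
unknown frequencies `r ~ Dirichlet(α₀ = 1)`. The variational
Dirichlet–multinomial scheme iterates responsibilities
`g_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))` and pseudo-counts `α = α₀ + Σ_n g_n`
to convergence (1e−6 on α). Estimated frequencies are `Ef = α/Σα`;
exceedance probabilities come from Monte-Carlo argmax frequencies of
posterior Dirichlet samples (default 1e5 samples, standard error < 0.01;
argmax ties break to the lowest model index, a measure-zero event). The
Bayes omnibus risk compares the variational free energy of this model
against the null of uniform frequencies,
`BOR = 1/(1 + exp(F1 − F0))`, and protected exceedance probabilities are
`pxp = (1 − BOR)·xp + BOR/K`. Evidence is identified only up to per-subject
constants; the implementation is invariant to row shifts and row
permutations (tested).

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

* **Events.** 40 base rates drawn Normal(40, 15), rounded and clipped to
  [10, 70]. The spread is chosen so the truncated distribution covers the
  stated range with mean ≈ 40.
* **Groups.** Four testing contexts (oct2019, mar2020, may2021, jun2022)
  with default sizes 30/34/31/28; the first and last are outside, the middle
  two during the pandemic. Covariate distributions (age, gender, education)
  are reconstructed per group from the published means ± SEM via
  `sd = SEM·√N`. Task design is two-run for the oct2019 group and for 15 of
  the jun2022 group, one-run otherwise.
* **First estimates.** `E1 = BR − offset + ε`, `eBR = BR + ε'`, rounded and
  clipped to [3, 77]. The optimism offset (default +5 ± 2 across subjects)
  makes people *under*-estimate their own risk on average — the classic
  unrealistic-optimism pattern for adverse events — so bad-news trials
  slightly outnumber good-news trials. The estimate noise sd defaults to 20,
  which puts the mean estimation-error magnitude near 17, typical of this
  task family; this is the key driver of how identifiable the learning-rate
  components are.
* **Updates.** `E2 = E1 − valence·UPD_model + η`, clipped to the response
  range, with update noise sd defaulting to 8. The noise level is not an
  observable of the published task; 8 was chosen from a least-squares
  variance calculation so that the simulate-and-refit identifiability regime
  matches the reported recovery correlations (about 0.92 for scaling, 0.82
  for asymmetry at 123 × 40 with SEM-derived parameter spreads).
* **Confidence** is uniform on [0, 100]; a configurable during-pandemic
  shift emulates higher confidence in base rates under uncertainty.
* **Non-response** occurs at rate 0.011 per trial (≈ 0.44 trials per
  subject), and integer rounding of E1 produces occasional `EE = 0` trials,
  so the exclusion rules are exercised by default.
* **Pandemic effects** (`pandemic_config`): during-pandemic subjects get
  scaling −0.05, asymmetry −0.04, offset +2, estimate noise +2 and
  confidence +14. These fixed shifts reproduce the *direction* of the four
  headline context contrasts (weaker good-news updating, larger positive
  estimation errors, lower good-news learning rates, lower asymmetry) at
  small-to-moderate effect sizes; exact effect magnitudes of any real cohort
  are not targeted.

All randomness flows through one `SeedSequence` tree: one child per subject
plus a reserved child for study-level draws, so a configuration reproduces a
study byte for byte and is invariant to the key order of the group-size
mapping. What the generator does **not** emulate: real event semantics,
response times, within-subject retest correlation structure, or any
heavy-tailed/ordinal features of real rating data — passing tests show the
*pipeline* behaves correctly under its assumed statistical structure, not
that real data satisfy those assumptions.

## Group statistics

The update LME has fixed effects |EE|, valence (−1/+1), context (0/1),
design (1/2), age, gender (0/1), education and valence × context, with a
random intercept and independent random slopes for |EE| and valence by
subject (independence between random terms is assumed; the correlation
structure is not identifiable from the data sizes in play). Models are
fitted by ML; inference is Wald t with residual-style degrees of freedom
(`n_obs − n_fixed`), and CIs use β ± 1.96·SE. Optimization tries L-BFGS then
Powell; on failure the random-effects structure is simplified stepwise
(drop valence slope, drop |EE| slope, intercept-only) with the downgrade
recorded on the result. Variants support four-level context dummies
(baseline oct2019) and a distance covariate. The learning-rate LME (two rows
per subject: S+A and S−A) keeps a random intercept; per-subject parameter
regressions have one row per subject, so the random intercept is absorbed by
the residual and the model is estimated as OLS. No multiple-testing
correction is applied to post-hoc t-tests (they characterize directionality,
mirroring common practice in this literature); the t-tests are
pooled-variance Student tests with Cohen's d on the pooled sd.

The fixed effects agree with an independent lme4 (R) maximum-likelihood fit
to 2e−3 on a simulated dataset (tested when Rscript is available).

## Power analysis

`power_simulation` holds each subject's first estimates, covariates and
trial composition fixed, re-simulates updates from per-subject model
assignments (typically each context's selection winner with MAP
parameters), refits the update LME, and counts rejections of the
valence-by-context interaction at α = 0.05. Iterations with non-convergent
LMEs are excluded from the denominator and reported. Under a null generator
(no context effect, no parameter spread) the rejection rate over 1000
simulated studies is 0.051 with the intercept-only structure — inside the
99% binomial band of the nominal level (tested). The null-calibration test
uses a 62-subject cohort and the intercept-only structure, matching how the
null data are generated and keeping the 1000-iteration loop to about two
minutes.

## Problem sizes used in the checks

Parameter recovery runs at full study scale (123 × 40). Model recovery uses
40 subjects per generating model at update noise 2 (low noise isolates
structural confusability from estimation noise); its 12 × 12 frequency
matrix shows family-level dominance for every generating model and
diagonal peaks for the two headline models, with the expected bleed from
nested pairs (an asymmetric generator with a small mean asymmetry is
parsimoniously explained by its symmetric nested variant for some
subjects). The context-contrast check pools three simulated cohorts
(369 subjects) to stabilize Cohen's d estimates.

## Known limitations

* The Laplace evidence uses the profile Hessian over the free parameters
  (noise variance profiled out), not the full joint curvature; for these
  sample sizes the difference is well below the between-model evidence gaps.
* Clipping simulated E2 to the response range slightly attenuates extreme
  subjects' effective learning rates; recovery correlations are therefore
  mildly conservative relative to an unbounded simulation.
* Exceedance probabilities are Monte-Carlo estimates; at the default budget
  their standard error is below 0.01, which matters only for values
  extremely close to ties.
* The mixed models assume Gaussian residuals on a bounded outcome; with
  strong clipping (very large update noise) the Wald inference would be
  approximate.
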