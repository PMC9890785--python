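# Methods

## The problem

A risk model for a rare short-horizon clinical event (order 10–1,000
events per 100,000 visits) is fitted on a development sample of visits and
must be validated *internally* — using only the development data — before
anyone sees prospective data. This package implements the three standard
internal validation schemes and a temporal (prospective) benchmark, on
synthetic cohorts whose structure mirrors visit-level health-records data,
so the schemes' behavior can be studied as an executable experiment.

Three structural features drive everything:

* **Visits cluster within persons**, and a single person-level event is
  attributed to several of that person's visits. Any resampling at the
  visit level would split correlated rows across arms; all partitioning
  and bootstrapping here is therefore at the **person** level, with the
  bootstrap additionally **stratified by event-person status** so the tiny
  event stratum keeps its exact size in every replicate.
* **Events are rare**, so performance estimates are noisy and percentile
  thresholds sit far in the tail of the score distribution.
* **Flexible learners interpolate**: a random forest with small terminal
  nodes nearly memorizes its training persons. A bootstrap sample contains
  on average 1 − 1/e ≈ 63.2% of the original persons, so evaluating a
  bootstrap-refitted model "on the original sample" is ~63% an in-sample
  evaluation. The optimism correction subtracts an optimism estimate that
  is therefore biased toward zero, and the corrected estimate inherits
  most of the apparent (in-sample) optimism.

## Synthetic cohort generator

`generate_cohort(CohortConfig)` draws, per person: a Gaussian random
intercept (frailty, log-odds SD `frailty_sd`), a negative-binomial visit
count (mean `visit_mean`, dispersion `visit_dispersion`, minimum 1), and a
chronological split of visits into a development and a prospective period
(`dev_period_fraction`). Per visit: binary predictors with prevalences
drawn log-uniformly on [0.01, 0.75] (shifted by per-predictor deltas in
the prospective period — covariate drift) and standard-normal continuous
predictors. The visit log-odds is a configurable signal: linear terms,
pairwise interactions, and step ("threshold") terms — the nonlinear parts
are what a flexible forest can exploit and a main-effects logistic model
cannot.

**Event attribution.** The default mechanism (`attribution="person"`)
draws one Bernoulli event per person-period from the person's *average*
visit-level risk and marks the k most recent visits of that period
(`event_visits_per_event`, default k = 2). This preserves the key
person/visit distinction: one event, several positive visit rows. A
second mechanism (`attribution="visit"`) draws independent per-visit
Bernoulli outcomes; it is the correctly specified data process for a
visit-level logistic model and is used as the parametric control in the
test suite.

**Rate calibration.** A period-specific intercept is solved by Brent root
finding so the *expected* visit-level event rate equals the configured
rate exactly, given the realized covariates; an unreachable target rate
(possible under person attribution, where at most min(k, n) visits per
person can be positive) raises an error naming the achievable range.

**Two seeds.** `structure_seed` fixes the data-generating *process*
(prevalences, default signal and drift); `seed` fixes the *draw*. Two
cohorts differing only in `seed` are independent samples from one process
— which is what independent-holdout oracle checks and the parametric
control require. Identical config + seed reproduces the table
byte-for-byte.

**Known departures from real data.** Predictors are independent across
visits and persons (no person-level covariate signature, no
autocorrelation), missingness and informative visit timing are absent,
and under person attribution the positive visits are chosen by recency,
not by their own covariates. The last point matters: if the two periods
have unequal visits-per-person, the average-risk attribution dilutes
visit-level signal more in the longer period, which can make prospective
discrimination *exceed* the honest development estimate as a pure
artifact. The default `dev_period_fraction = 0.5` keeps periods
symmetric so that drift, not the attribution mechanism, drives
development-vs-prospective differences.

## Desk-scale study conditions

The package's defaults define the study conditions used throughout the
tests: 5,000 persons, mean 5 visits (≈25k visits, half per period), 1,200
events per 100,000 development visits falling to 900 per 100,000
prospectively (≈150 development event-visits), frailty SD 0.5, drift
touching eight binary predictors (three of them outcome-associated) and
one continuous predictor. These values keep the defining features of the
regime — strong class imbalance, clustered events, drift, a flexible
learner with far more parameters than events — at a size where a full
multi-seed study runs on one CPU in minutes. Rarer rates (e.g. the
24/19-per-100k of large health-system cohorts, via `--paper-scale`) are
supported but need proportionally larger cohorts for stable metrics.

## Learners and tuning

`LearnerSpec` describes either a random forest (`min_node_size` — a
fraction of training visits by default, so flexibility is
sample-size-relative; `mtry`; `n_trees`) or an L2-penalized logistic model
(`penalty`, 0 = unpenalized). Defaults: `n_trees = 500` on `LearnerSpec`
(the field-standard forest size), 50 in the desk-scale experiment grids;
the default `mtry` grid brackets ⌊√p⌋ by half and double; node-size grids
are {0.002, 0.005, 0.01, 0.02, 0.03} of training visits for the
split-sample model and {0.005, 0.01, 0.026, 0.052} for the entire-sample
model (the same design expressed in fractions rather than absolute visit
counts, which would not transfer across cohort sizes).

`tune` runs person-level k-fold CV (folds stratified by event-person
status so every fold sees events even at desk scale), assembles **one
pooled out-of-fold score vector per grid point**, computes AUC once on
that vector, and selects the argmax. Ties prefer the simpler model
(larger terminal nodes, then fewer predictors per split, then grid
order). Pooled-vector AUC is used rather than per-fold averaging because
per-fold AUCs are extremely unstable with a handful of events per fold.

## The three schemes

* **split_sample_validate** — persons split 50/50 exactly; tuning and the
  final fit use only the training half; thresholds come from the final
  model's in-sample *training* scores; points are computed on the testing
  half; CIs bootstrap the testing half only (model and thresholds fixed).
* **cv_validate** — one entire-sample tuning pass (shared with the
  optimism correction); the final entire-sample model m₀ supplies the
  thresholds from its in-sample scores; points are computed on the saved
  out-of-fold scores (every visit scored by a model that excluded that
  person's fold); CIs resample the saved (score, label) pairs
  person-stratified, **without refitting**.
* **bootstrap_optimism_validate** — B replicates; each refits with the
  cross-validation-selected hyperparameters (no re-tuning); per replicate
  the threshold set is rebuilt from m⁽ᵇ⁾'s in-sample scores on s⁽ᵇ⁾ and
  used for *both* evaluations inside the optimism difference, mirroring
  the rule that thresholds follow the model being evaluated. The
  corrected point is the mean of the corrected replicates
  {Perf(m₀,s₀) − Optimism⁽ᵇ⁾} (identical to apparent − mean optimism);
  CIs are quantiles of that distribution with the apparent term held
  fixed. Corrected values are *not* clipped to [0, 1]; out-of-range
  values are reported with a warning because they are diagnostic of
  method failure. Replicates whose refit fails are recorded as failed and
  excluded; more than 10% failures aborts.

Prospective validation evaluates a frozen model with its frozen
development-side thresholds on the later period; thresholds are never
recomputed prospectively, matching deployment.

## Numerical conventions

* AUC is the midrank Mann–Whitney statistic (ties count ½), O(n log n).
* Every empirical quantile — threshold cutoffs and CI endpoints — uses
  the type-1 inverse-CDF definition (⌈qn⌉-th order statistic, no
  interpolation), for bit-reproducibility; a 10⁻⁹ guard absorbs binary
  floating-point artifacts such as 0.025 × 1000 = 25.000000000000004.
  Under this convention the reference-set flagged fraction at percentile
  p is (n − ⌈pn/100⌉ + 1)/n, i.e. 1 − p/100 plus at most one visit (plus
  tie-induced excess).
* Flagging rule: score ≥ cutoff. PPV = TP/(TP+FP), displayed per 100,000
  flagged visits; undefined (no flagged visits) PPV is reported missing,
  never fabricated.
* All randomness derives named integer streams from one root seed
  (SHA-256 of root + token path), so changing B never perturbs the
  cohort and any single bootstrap replicate is reproducible in isolation.
* Reports are byte-identical across reruns of the same config + seed;
  wall-times go to a separate run log to keep them so.

## Stability traces

Every bootstrapped quantity records a moving estimate over replicates:
running mean (optimism scheme) or fixed point (CI-only schemes) plus
running type-1 2.5/97.5 percentiles, with the final row equal to the
reported estimate and CI bit-for-bit. These are the standard diagnostics
for judging whether B replicates were enough.

## What the tests do and do not show

The suite demonstrates, at desk scale: (a) the bootstrap-corrected AUC of
a flexible forest exceeds the same model's prospective AUC (mean
overestimate well above 0.02 across seeds) while the cross-validated
estimate stays closer — the qualitative failure mode of optimism
correction for data-adaptive learners; (b) for a correctly specified
logistic model on a linear visit-level process, all three schemes agree
with prospective performance within ±0.02 — the regime where optimism
correction is known to be valid; (c) exact optimism arithmetic and
no-leakage audits. Because the generator omits person-level covariate
signatures and temporal autocorrelation, these results show the *mechanism*
of the schemes' behavior, not effect sizes for any particular real
dataset.

## Known limitations

* The cv scheme's CI conditions on the fitted out-of-fold scores (the
  no-refit design). It therefore omits fold-model estimation noise and
  the pooled-fold score-scale artifact, and runs mildly anti-conservative
  (~85–90% observed coverage under the null at small n). Refitting inside
  CI resamples would remove this at substantial cost but would blur the
  line between the cv scheme and optimism correction; the package keeps
  the cheap reading and documents it.
* Under person attribution, positive visits are recency-chosen, so
  visit-level discrimination is bounded below the signal's visit-level
  Bayes limit; comparisons across periods are only fair when periods are
  symmetric in visits per person (see above).
* 0.632/0.632+ estimators, repeated CV, calibration metrics, NPV and
  decision-curve analysis are out of scope.
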