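# optimism-lab

Internal validation of clinical prediction models for **rare events** —
and, in particular, an executable comparison of the three standard ways to
estimate how well a model fitted on a development sample will perform on
future data:

1. **Split-sample testing-set validation** — half the *persons* are held
   out; the model is tuned and fitted on the training half and evaluated
   on the testing half.
2. **Cross-validated out-of-fold (OOF) estimation** — the model is tuned
   on the entire development sample with person-level k-fold CV; the saved
   out-of-fold predictions for the selected hyperparameters provide the
   performance estimate.
3. **Bootstrap optimism correction** — for each of B event-stratified
   person-level bootstrap samples s⁽ᵇ⁾, refit mᵇ and compute

       Optimism⁽ᵇ⁾ = Perf(m⁽ᵇ⁾, s⁽ᵇ⁾) − Perf(m⁽ᵇ⁾, s₀)
       Perf_corrected = Perf(m₀, s₀) − (1/B) Σᵇ Optimism⁽ᵇ⁾

   where m₀ is the entire-sample model and s₀ the development sample.

Each internal estimate is then compared with **prospective (temporal)
validation**: the same model evaluated on a later period of the same
population, with covariate drift and a lower event rate.

The interesting regime is a *flexible* learner (a random forest with small
terminal nodes) on a *rare* outcome: a bootstrap sample contains on
average only 63.2% of the original persons, so Perf(m⁽ᵇ⁾, s₀) is partly an
in-sample evaluation, the optimism is under-estimated, and the "corrected"
estimate can vastly overstate prospective performance — while OOF
cross-validation, which never scores a visit with a model that saw that
person, stays honest. For a correctly specified parametric (logistic)
model all three schemes agree. This package reproduces both behaviors at
desk scale.

Because real visit-level health-records data of this kind are restricted,
the package ships a **synthetic cohort generator** (`optimism_lab.cohort`)
producing visit tables with the relevant structure: visits clustered
within persons, a person-level frailty, a rare binary outcome where one
person-level event marks the k most recent visits (so person-level — not
visit-level — resampling is the correct unit), ~100 mostly-binary
predictors with interaction/threshold signal, and covariate/event-rate
drift between the development and prospective periods. The marginal event
rate per period is calibrated exactly by root-finding on the intercept.

Metrics are AUC (midrank Mann–Whitney) and sensitivity / specificity / PPV
at the 75th/90th/95th/99th percentiles of a *reference* risk-score
distribution (thresholds always travel with the model; they are never
recomputed on the evaluation sample). All CIs are quantile bootstrap
intervals from event-stratified person-level resampling, with moving
stability traces over replicates.

## Worked example

```python
from optimism_lab import (CohortConfig, LearnerSpec, generate_cohort,
                          temporal_split, tune, fit, cv_validate,
                          bootstrap_optimism_validate, prospective_validate,
                          seed_for)

cfg = CohortConfig(seed=1)                       # desk-scale rare-event cohort
dev, prosp = temporal_split(generate_cohort(cfg))

flexible = LearnerSpec(kind="random_forest", min_node_size=0.002, mtry=10, n_trees=50)
tuning = tune(dev, [flexible], k=5, seed=seed_for(1, "tune"))
m0 = fit(dev, tuning.selected, seed=seed_for(1, "m0"))

cv  = cv_validate(dev, tuning=tuning, model0=m0, n_boot=200, seed=1)
opt = bootstrap_optimism_validate(dev, tuning.selected, m0, B=40, seed=1)
pr  = prospective_validate(m0, prosp, cv.thresholds, n_boot=200, seed=1)

print("cv oof AUC        ", round(cv.estimate("auc").point, 3))
print("optimism-corrected", round(opt.estimate("auc").point, 3))
print("prospective       ", round(next(e for e in pr if e.metric == "auc").point, 3))
```

Output (seed 1):

```
cv oof AUC         0.595
optimism-corrected 0.853
prospective        0.65
```

The optimism-corrected estimate overshoots the model's prospective AUC by
~0.2, while the cross-validated estimate is far closer — the bootstrap
correction fails for the flexible learner exactly because its "out-of-
sample" term is contaminated by in-sample persons.

The same study runs end to end from the shell:

```bash
optimism-lab run --seed 1 --out results/run1          # full desk-scale study
optimism-lab run --paper-scale --out results/full     # full-scale replication counts
optimism-lab simulate --seed 2 --out results/cohort   # just the synthetic cohort
optimism-lab report --report results/run1/report.json --out results/tables
```

`run` writes `report.json` (deterministic for a given config+seed), one
CSV per metric with internal vs prospective cells and optimism deltas, a
CI-width comparison (including the split-test vs cross-validated AUC
interval width ratio, in percent), and per-replicate stability traces.

## Layout

| module | contents |
| --- | --- |
| `optimism_lab.cohort` | synthetic visit-level cohort generator, CSV/YAML IO, summaries |
| `optimism_lab.resampling` | person-level splits, stratified person folds, event-stratified person bootstrap |
| `optimism_lab.metrics` | midrank AUC, percentile thresholds, classification metrics, quantile CIs |
| `optimism_lab.models` | random-forest and logistic learners, person-level CV tuning |
| `optimism_lab.validation` | the three internal validation schemes, optimism records, stability traces |
| `optimism_lab.experiment` | full-study orchestration, prospective validation, report tables, CLI config |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
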