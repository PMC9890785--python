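"""The three internal validation schemes for a development cohort.

* ``split_sample_validate`` — persons are split 50/50; the model is tuned
  and fitted on the training half, thresholds come from its in-sample
  training scores, and performance is measured on the held-out testing
  half with event-stratified person-bootstrap CIs.
* ``cv_validate`` — the model is tuned on the whole development sample;
  the saved out-of-fold scores of the selected hyperparameters provide the
  point estimates (every visit scored by a model that never saw that
  person), thresholds come from the entire-sample model's in-sample
  scores, and CIs resample the saved (score, label) pairs without
  refitting.
* ``bootstrap_optimism_validate`` — Harrell-style correction: per
  replicate b, refit on an event-stratified person bootstrap sample s_b,
  measure optimism_b = Perf(m_b, s_b) - Perf(m_b, s_0), and subtract the
  mean optimism from the apparent performance Perf(m_0, s_0). Thresholds
  follow the model being evaluated (m_b's in-sample scores on s_b; m_0's
  on s_0). CIs are quantiles of the corrected-replicate distribution
  {Perf(m_0, s_0) - optimism_b}; corrected values are reported unclipped —
  values outside [0, 1] are diagnostic of method failure, not errors.

Each scheme returns a :class:`ValidationReport` carrying the fitted model
(for later prospective evaluation), its threshold set, estimates for AUC
and sensitivity/specificity/PPV at each percentile cutpoint, and moving
stability traces over bootstrap replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_for, seed_for
from .metrics import (PerformanceEstimate, ThresholdSet, evaluate_all,
                      percentile_thresholds, quantile_ci, quantile_type1)
from .models import LearnerSpec, RiskModel, TuningResult, fit, predict_scores, tune
from .resampling import PersonResampler, split_persons, stratified_person_bootstrap

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (75.0, 90.0, 95.0, 99.0)


def _key_label(key) -> str:
    metric, pct = key
    return metric if pct is None else f"{metric}@{pct:g}"


@dataclass
class OptimismRecord:
    """Per-replicate bookkeeping for the optimism correction.

    For every metric/threshold key: performance of the replicate model in
    its own bootstrap sample, in the original sample, their difference
    (the optimism), and the corrected replicate value
    apparent - optimism. The identity
    perf_in_bootstrap - perf_in_original == optimism holds exactly.
    """

    b: int
    failed: bool = False
    perf_in_bootstrap: dict = field(default_factory=dict)
    perf_in_original: dict = field(default_factory=dict)
    optimism: dict = field(default_factory=dict)
    corrected_replicate: dict = field(default_factory=dict)


@dataclass
class ValidationReport:
    """Output of one validation scheme."""

    scheme: str
    model: RiskModel | None
    thresholds: ThresholdSet
    estimates: list[PerformanceEstimate]
    traces: dict  # label -> DataFrame(b, point, ci_lower, ci_upper)
    seed: int
    n_boot: int
    tuning: TuningResult | None = None
    records: list[OptimismRecord] | None = None
    extras: dict = field(default_factory=dict)

    def estimate(self, metric: str, percentile: float | None = None) -> PerformanceEstimate:
        for est in self.estimates:
            if est.metric == metric and (
                (percentile is None and est.percentile is None)
                or (est.percentile is not None and percentile is not None
                    and float(est.percentile) == float(percentile))
            ):
                return est
        raise KeyError((metric, percentile))

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "scheme": e.scheme, "metric": e.metric, "percentile": e.percentile,
            "point": e.point, "ci_lower": e.ci_lower, "ci_upper": e.ci_upper,
            "n_boot": e.n_boot,
        } for e in self.estimates]
        return pd.DataFrame(rows)


def stability_trace(replicate_values, point: float | None = None) -> pd.DataFrame:
    """Moving estimate over bootstrap replicates.

    For each prefix length b: the running point (mean of the first b
    replicate values, or the fixed ``point`` when the scheme's point
    estimate does not depend on the replicates) and the running type-1
    2.5/97.5 percentiles. The final row reproduces the reported estimate
    and CI exactly.
    """
    values = np.asarray(replicate_values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one replicate value")
    rows = []
    for b in range(1, values.size + 1):
        prefix = values[:b]
        finite = prefix[np.isfinite(prefix)]
        if finite.size == 0:
            pt, lo, hi = np.nan, np.nan, np.nan
        else:
            pt = float(finite.mean()) if point is None else float(point)
            lo = quantile_type1(finite, 0.025)
            hi = quantile_type1(finite, 0.975)
        rows.append({"b": b, "point": pt, "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


def _metric_replicates(scores, labels, person_ids, thresholds: ThresholdSet,
                       n_boot: int, seed: int) -> dict:
    """Event-stratified person-bootstrap replicates of every metric, with
    the model and thresholds held fixed (no refitting)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rs = PersonResampler(np.asarray(person_ids), labels == 1)
    keys = None
    out: dict = {}
    for b in range(n_boot):
        rows, _, _ = rs.draw_rows(rng_for(seed, "ci", b))
        vals = evaluate_all(scores[rows], labels[rows], thresholds)
        if keys is None:
            keys = list(vals)
            out = {k: np.empty(n_boot) for k in keys}
        for k in keys:
            out[k][b] = vals[k]
    return out


def _build_estimates(points: dict, replicates: dict | None, scheme: str,
                     n_boot: int) -> tuple[list[PerformanceEstimate], dict]:
    estimates, traces = [], {}
    for key, point in points.items():
        metric, pct = key
        lo = hi = None
        if replicates is not None:
            values = replicates[key]
            if np.isfinite(values).any():
                lo, hi = quantile_ci(values)
            traces[_key_label(key)] = stability_trace(values, point=point)
        if not np.isfinite(point):
            logger.warning("%s: %s is missing (undefined on this sample)", scheme, _key_label(key))
        estimates.append(PerformanceEstimate(metric, pct, float(point), lo, hi, scheme, n_boot))
    return estimates, traces


def split_sample_validate(dev: pd.DataFrame, grid: list[LearnerSpec],
                          percentiles=DEFAULT_PERCENTILES, n_boot: int = 1000,
                          k: int = 5, seed: int = 0) -> ValidationReport:
    """Split-sample scheme: train on half the persons, validate on the rest."""
    partition = split_persons(dev, 0.5, rng_for(seed, "split"))
    train = partition.select(dev, "train")
    test = partition.select(dev, "test")
    assert not set(train["person_id"]) & set(test["person_id"]), "train/test persons must be disjoint"

    tuning = tune(train, grid, k=k, seed=seed_for(seed, "tune"))
    model = fit(train, tuning.selected, seed=seed_for(seed, "final"))
    thresholds = percentile_thresholds(model.in_sample_scores, percentiles,
                                       reference_label="split_train_in_sample")
    test_scores = predict_scores(model, test)
    y_test = test["y"].to_numpy(dtype=int)
    points = evaluate_all(test_scores, y_test, thresholds)
    replicates = _metric_replicates(test_scores, y_test, test["person_id"].to_numpy(),
                                    thresholds, n_boot, seed_for(seed, "boot"))
    estimates, traces = _build_estimates(points, replicates, "split_sample_test", n_boot)
    return ValidationReport(
        scheme="split_sample_test", model=model, thresholds=thresholds,
        estimates=estimates, traces=traces, seed=seed, n_boot=n_boot,
        tuning=tuning, extras={"partition": partition, "n_test_visits": len(test)},
    )


def cv_validate(dev: pd.DataFrame, grid: list[LearnerSpec] | None = None, k: int = 5,
                percentiles=DEFAULT_PERCENTILES, n_boot: int = 500, seed: int = 0,
                tuning: TuningResult | None = None,
                model0: RiskModel | None = None) -> ValidationReport:
    """Cross-validation scheme on the entire development sample.

    ``tuning``/``model0`` may be supplied so one entire-sample tuning pass
    can be shared with the optimism correction.
    """
    if tuning is None:
        if grid is None:
            raise ValueError("provide either a grid or a TuningResult")
        tuning = tune(dev, grid, k=k, seed=seed_for(seed, "tune"))
    if model0 is None:
        model0 = fit(dev, tuning.selected, seed=seed_for(seed, "m0"))
    if not np.array_equal(tuning.visit_ids, dev["visit_id"].to_numpy()):
        raise ValueError("tuning out-of-fold scores are not aligned to the development table")
    oof = tuning.oof_scores
    assert oof.shape[0] == len(dev) and not np.isnan(oof).any(), \
        "out-of-fold scores must cover every development visit exactly once"
    y = dev["y"].to_numpy(dtype=int)
    thresholds = percentile_thresholds(model0.in_sample_scores, percentiles,
                                       reference_label="entire_sample_in_sample")
    points = evaluate_all(oof, y, thresholds)
    replicates = _metric_replicates(oof, y, dev["person_id"].to_numpy(),
                                    thresholds, n_boot, seed_for(seed, "boot"))
    estimates, traces = _build_estimates(points, replicates, "cv_oof", n_boot)
    return ValidationReport(
        scheme="cv_oof", model=model0, thresholds=thresholds,
        estimates=estimates, traces=traces, seed=seed, n_boot=n_boot, tuning=tuning,
    )


def corrected_point(apparent: float, optimism_values) -> float:
    """Optimism-corrected estimate: apparent minus mean optimism."""
    values = np.asarray(optimism_values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return float("nan")
    return float(apparent - finite.mean())


def bootstrap_optimism_validate(dev: pd.DataFrame, spec: LearnerSpec, model0: RiskModel,
                                B: int = 500, percentiles=DEFAULT_PERCENTILES,
                                seed: int = 0, max_failure_fraction: float = 0.1) -> ValidationReport:
    """Bootstrap optimism correction of the entire-sample model.

    No re-tuning inside replicates: every m_b reuses the hyperparameters
    selected once by cross-validation, as in the study design.
    """
    if model0.n_train_visits != len(dev):
        raise ValueError("model0 must be fitted on the development table passed here")
    y0 = dev["y"].to_numpy(dtype=int)
    thresholds0 = percentile_thresholds(model0.in_sample_scores, percentiles,
                                        reference_label="entire_sample_in_sample")
    apparent = evaluate_all(model0.in_sample_scores, y0, thresholds0)

    records: list[OptimismRecord] = []
    n_failed = 0
    for b in range(B):
        rec = OptimismRecord(b=b)
        try:
            sample = stratified_person_bootstrap(dev, rng_for(seed, "resample", b))
            m_b = fit(sample.table, spec, seed=seed_for(seed, "refit", b))
            thr_b = percentile_thresholds(m_b.in_sample_scores, percentiles,
                                          reference_label=f"bootstrap_in_sample_b{b}")
            rec.perf_in_bootstrap = evaluate_all(
                m_b.in_sample_scores, sample.table["y"].to_numpy(dtype=int), thr_b)
            rec.perf_in_original = evaluate_all(predict_scores(m_b, dev), y0, thr_b)
            rec.optimism = {k: rec.perf_in_bootstrap[k] - rec.perf_in_original[k]
                            for k in rec.perf_in_bootstrap}
            rec.corrected_replicate = {k: apparent[k] - rec.optimism[k] for k in rec.optimism}
        except Exception as exc:  # noqa: BLE001 — replicate failure is data, not a crash
            rec.failed = True
            n_failed += 1
            logger.warning("optimism replicate %d failed: %s", b, exc)
        records.append(rec)
    if n_failed > max_failure_fraction * B:
        raise RuntimeError(f"{n_failed}/{B} optimism replicates failed (> {max_failure_fraction:.0%})")
    if n_failed:
        logger.warning("excluded %d failed optimism replicate(s) from means", n_failed)

    keys = list(apparent)
    points, replicates = {}, {}
    for key in keys:
        corr = np.array([r.corrected_replicate.get(key, np.nan) for r in records if not r.failed])
        # mean of corrected replicates == apparent - mean optimism; computed
        # this way so the stability trace's final entry matches bit-for-bit
        finite = corr[np.isfinite(corr)]
        points[key] = float(finite.mean()) if finite.size else float("nan")
        replicates[key] = corr
        if np.isfinite(points[key]) and not (0.0 <= points[key] <= 1.0):
            logger.warning("optimism-corrected %s = %.4f lies outside [0, 1] — "
                           "diagnostic of correction failure, reported unclipped",
                           _key_label(key), points[key])

    estimates, traces = [], {}
    n_used = B - n_failed
    for key in keys:
        values = replicates[key]
        finite_ok = np.isfinite(values).any()
        lo, hi = quantile_ci(values) if finite_ok else (None, None)
        traces[_key_label(key)] = stability_trace(values)  # running corrected mean
        estimates.append(PerformanceEstimate(key[0], key[1], points[key], lo, hi,
                                             "bootstrap_optimism", n_used))
    return ValidationReport(
        scheme="bootstrap_optimism", model=model0, thresholds=thresholds0,
        estimates=estimates, traces=traces, seed=seed, n_boot=n_used,
        records=records, extras={"apparent": apparent, "n_failed": n_failed},
    )
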