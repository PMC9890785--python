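"""Full study orchestration: cohort, schemes, prospective check, reports.

``run_study`` executes the complete design on one synthetic cohort:

1. generate the visit-level cohort and split it by period;
2. split-sample scheme: tune/fit on half the development persons,
   validate on the held-out half, then evaluate that model prospectively
   with its own (training-side) thresholds;
3. entire-sample pass: one tuning run shared by the cross-validation
   scheme and the bootstrap optimism correction, one entire-sample model
   m0, prospective evaluation of m0 with the development-side thresholds;
4. assemble per-cell comparisons (internal vs prospective, optimism
   deltas, CI widths) shaped like the study's result tables.

Reports are deterministic given (config, seed); wall-times are logged to a
separate run log so report files are byte-stable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from ._rng import rng_for, seed_for
from .cohort import CohortConfig, generate_cohort, summarize_cohort, temporal_split
from .metrics import PerformanceEstimate, ThresholdSet, evaluate_all, quantile_ci
from .models import LearnerSpec, RiskModel, default_mtry_grid, fit, predict_scores, rf_grid, tune
from .resampling import PersonResampler
from .validation import (DEFAULT_PERCENTILES, ValidationReport, _build_estimates,
                         _metric_replicates, bootstrap_optimism_validate, cv_validate,
                         split_sample_validate)

logger = logging.getLogger(__name__)

# node-size grids as fractions of the training sample (split-sample grid is
# finer at the small end because the training set is half the size)
SPLIT_NODE_FRACTIONS = (0.002, 0.005, 0.01, 0.02, 0.03)
ENTIRE_NODE_FRACTIONS = (0.005, 0.01, 0.026, 0.052)


class StageError(RuntimeError):
    """A study stage failed; carries the stage name and seeds to reproduce."""


@dataclass
class ExperimentConfig:
    """Study configuration with desk-scale defaults.

    ``paper_scale`` switches the bootstrap/replication counts (and event
    rates) to the values used at full health-system scale; everything else
    stays configurable.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    split_grid: list[LearnerSpec] | None = None   # None -> default rf grid
    entire_grid: list[LearnerSpec] | None = None
    percentiles: tuple = DEFAULT_PERCENTILES
    k: int = 5
    b_optimism: int = 40
    n_boot_test: int = 200
    n_boot_cv: int = 200
    n_boot_prospective: int = 200
    seed: int = 0
    n_trees: int = 50

    def validate(self) -> None:
        self.cohort.validate()
        for name in ("k", "b_optimism", "n_boot_test", "n_boot_cv", "n_boot_prospective", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for p in self.percentiles:
            if not (0 < p < 100):
                raise ValueError("percentiles must lie in (0, 100)")

    def resolved_grids(self) -> tuple[list[LearnerSpec], list[LearnerSpec]]:
        mtry = default_mtry_grid(self.cohort.n_predictors)
        split = self.split_grid or rf_grid(SPLIT_NODE_FRACTIONS, mtry, self.n_trees)
        entire = self.entire_grid or rf_grid(ENTIRE_NODE_FRACTIONS, mtry, self.n_trees)
        return split, entire

    def at_paper_scale(self) -> "ExperimentConfig":
        cohort = replace(self.cohort, event_rate_dev=24e-5, event_rate_prosp=19e-5)
        return replace(self, cohort=cohort, b_optimism=500,
                       n_boot_test=1000, n_boot_cv=500, n_boot_prospective=1000)

    def to_dict(self) -> dict:
        split, entire = self.resolved_grids()
        return {
            "cohort": self.cohort.to_dict(),
            "split_grid": [vars(s).copy() for s in split],
            "entire_grid": [vars(s).copy() for s in entire],
            "percentiles": list(self.percentiles),
            "k": self.k, "b_optimism": self.b_optimism,
            "n_boot_test": self.n_boot_test, "n_boot_cv": self.n_boot_cv,
            "n_boot_prospective": self.n_boot_prospective,
            "seed": self.seed, "n_trees": self.n_trees,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "cohort" in d and d["cohort"] is not None:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        for key in ("split_grid", "entire_grid"):
            if d.get(key):
                d[key] = [LearnerSpec(**spec) for spec in d[key]]
        if "percentiles" in d and d["percentiles"] is not None:
            d["percentiles"] = tuple(d["percentiles"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def prospective_validate(model: RiskModel, prosp: pd.DataFrame, thresholds: ThresholdSet,
                         n_boot: int = 1000, seed: int = 0) -> list[PerformanceEstimate]:
    """Evaluate a fixed model in the prospective period.

    Thresholds are NOT recomputed: they carry their development-side
    reference label, mirroring deployment, where cutoffs are frozen before
    prospective data exist.
    """
    if len(prosp) == 0:
        raise ValueError("prospective table is empty")
    scores = predict_scores(model, prosp)
    y = prosp["y"].to_numpy(dtype=int)
    points = evaluate_all(scores, y, thresholds)
    replicates = _metric_replicates(scores, y, prosp["person_id"].to_numpy(),
                                    thresholds, n_boot, seed_for(seed, "prosp"))
    estimates, _ = _build_estimates(points, replicates, "prospective", n_boot)
    return estimates


@dataclass
class ExperimentReport:
    """Per scheme x metric x threshold: internal and prospective estimates
    and their difference (the realized optimism of the internal scheme)."""

    rows: pd.DataFrame
    ci_widths: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "rows": self.rows.replace({np.nan: None}).to_dict(orient="records"),
            "ci_widths": self.ci_widths.replace({np.nan: None}).to_dict(orient="records"),
            "metadata": self.metadata,
        }
        text = json.dumps(payload, sort_keys=True, indent=1,
                          default=lambda o: o.item() if hasattr(o, "item") else str(o))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ExperimentReport":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(rows=pd.DataFrame(payload["rows"]),
                   ci_widths=pd.DataFrame(payload["ci_widths"]),
                   metadata=payload.get("metadata", {}))


def ci_width_ratio_percent(wide: tuple[float, float], narrow: tuple[float, float]) -> int:
    """How much wider (in %) the first CI is than the second, to the
    nearest integer percent."""
    w1 = wide[1] - wide[0]
    w2 = narrow[1] - narrow[0]
    if w2 <= 0:
        raise ValueError("reference interval has non-positive width")
    return int(round(100.0 * (w1 / w2 - 1.0)))


def _comparison_rows(internal: ValidationReport, prospective: list[PerformanceEstimate],
                     model_label: str) -> list[dict]:
    prosp_by_key = {(e.metric, e.percentile): e for e in prospective}
    rows = []
    for est in internal.estimates:
        pe = prosp_by_key[(est.metric, est.percentile)]
        delta = est.point - pe.point if np.isfinite(est.point) and np.isfinite(pe.point) else np.nan
        rows.append({
            "model": model_label, "scheme": internal.scheme,
            "metric": est.metric, "percentile": est.percentile,
            "internal_point": est.point, "internal_lower": est.ci_lower, "internal_upper": est.ci_upper,
            "prospective_point": pe.point, "prospective_lower": pe.ci_lower, "prospective_upper": pe.ci_upper,
            "optimism_delta": delta, "n_boot_internal": est.n_boot, "n_boot_prospective": pe.n_boot,
        })
    return rows


def run_study(config: ExperimentConfig, outdir=None) -> ExperimentReport:
    """Execute the full comparison; fully reproducible from (config, seed)."""
    config.validate()
    root = config.seed
    split_grid, entire_grid = config.resolved_grids()
    timings: dict[str, float] = {}

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed (root seed {root}): {exc}") from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.1fs", name, timings[name])
        return result

    cohort_cfg = replace(config.cohort, seed=seed_for(root, "cohort"))
    cohort = stage("generate_cohort", generate_cohort, cohort_cfg)
    dev, prosp = stage("temporal_split", temporal_split, cohort)

    split_report = stage("split_sample_validate", split_sample_validate, dev, split_grid,
                         percentiles=config.percentiles, n_boot=config.n_boot_test,
                         k=config.k, seed=seed_for(root, "scheme", "split"))
    split_prosp = stage("prospective_split_model", prospective_validate,
                        split_report.model, prosp, split_report.thresholds,
                        n_boot=config.n_boot_prospective, seed=seed_for(root, "prosp", "split"))

    tuning = stage("entire_sample_tune", tune, dev, entire_grid, config.k,
                   seed_for(root, "scheme", "entire-tune"))
    model0 = stage("entire_sample_fit", fit, dev, tuning.selected,
                   seed_for(root, "scheme", "entire-fit"))
    cv_report = stage("cv_validate", cv_validate, dev,
                      percentiles=config.percentiles, n_boot=config.n_boot_cv,
                      seed=seed_for(root, "scheme", "cv"), tuning=tuning, model0=model0)
    opt_report = stage("bootstrap_optimism_validate", bootstrap_optimism_validate,
                       dev, tuning.selected, model0, B=config.b_optimism,
                       percentiles=config.percentiles, seed=seed_for(root, "scheme", "optimism"))
    entire_prosp = stage("prospective_entire_model", prospective_validate,
                         model0, prosp, cv_report.thresholds,
                         n_boot=config.n_boot_prospective, seed=seed_for(root, "prosp", "entire"))

    rows = (_comparison_rows(split_report, split_prosp, "split_sample")
            + _comparison_rows(cv_report, entire_prosp, "entire_sample")
            + _comparison_rows(opt_report, entire_prosp, "entire_sample"))
    rows_df = pd.DataFrame(rows)

    widths = []
    for r in rows:
        if r["internal_lower"] is not None and np.isfinite(r["internal_lower"]):
            widths.append({
                "scheme": r["scheme"], "metric": r["metric"], "percentile": r["percentile"],
                "internal_width": r["internal_upper"] - r["internal_lower"],
                "prospective_width": (r["prospective_upper"] - r["prospective_lower"])
                if r["prospective_lower"] is not None else np.nan,
            })
    widths_df = pd.DataFrame(widths)
    try:
        split_auc = split_report.estimate("auc")
        cv_auc = cv_report.estimate("auc")
        ratio = ci_width_ratio_percent((split_auc.ci_lower, split_auc.ci_upper),
                                       (cv_auc.ci_lower, cv_auc.ci_upper))
    except (ValueError, TypeError):
        ratio = None

    summary = summarize_cohort(cohort)
    metadata = {
        "seed": root,
        "config": config.to_dict(),
        "selected_spec_split": vars(split_report.tuning.selected).copy(),
        "selected_spec_entire": vars(tuning.selected).copy(),
        "split_test_vs_cv_auc_width_ratio_pct": ratio,
        "cohort_summary": {
            "n_visits": summary.n_visits, "n_persons": summary.n_persons,
            "n_event_visits": summary.n_event_visits, "n_event_persons": summary.n_event_persons,
            "event_rate_per_100k": summary.event_rate_per_100k,
        },
    }
    traces = {"split_sample_test": split_report.traces, "cv_oof": cv_report.traces,
              "bootstrap_optimism": opt_report.traces}
    report = ExperimentReport(rows=rows_df, ci_widths=widths_df, metadata=metadata, traces=traces)

    if outdir is not None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        config.to_yaml(out / "config.yaml")
        report_tables(report, out)
        trace_rows = []
        for scheme, tr in traces.items():
            for label, df in tr.items():
                d = df.copy()
                d.insert(0, "metric", label)
                d.insert(0, "scheme", scheme)
                trace_rows.append(d)
        pd.concat(trace_rows, ignore_index=True).to_csv(out / "stability_traces.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump({"timings_seconds": timings}, fh, indent=1, sort_keys=True)
    return report


def _fmt(x, scale=1.0, digits=3):
    if x is None or not np.isfinite(x):
        return "NA"
    return f"{x * scale:.{digits}f}"


def report_tables(report: ExperimentReport, outdir) -> dict:
    """Write one CSV per metric (internal vs prospective cells, optimism
    deltas) plus a CI-width comparison file; returns the file paths."""
    import pathlib
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for metric in ("auc", "sensitivity", "specificity", "ppv"):
        sub = report.rows[report.rows["metric"] == metric].copy()
        scale = 1e5 if metric == "ppv" else 1.0
        digits = 1 if metric == "ppv" else 3
        formatted = pd.DataFrame({
            "scheme": sub["scheme"],
            "percentile": sub["percentile"],
            "internal": [f"{_fmt(p, scale, digits)} ({_fmt(l, scale, digits)}, {_fmt(u, scale, digits)})"
                         for p, l, u in zip(sub["internal_point"], sub["internal_lower"], sub["internal_upper"])],
            "prospective": [f"{_fmt(p, scale, digits)} ({_fmt(l, scale, digits)}, {_fmt(u, scale, digits)})"
                            for p, l, u in zip(sub["prospective_point"], sub["prospective_lower"], sub["prospective_upper"])],
            "optimism_delta": [_fmt(d, scale, digits) for d in sub["optimism_delta"]],
        })
        path = out / f"{metric}.csv"
        formatted.to_csv(path, index=False)
        paths[metric] = path
    widths = report.ci_widths.copy()
    ratio = None
    auc_rows = report.rows[report.rows["metric"] == "auc"].set_index("scheme")
    if {"split_sample_test", "cv_oof"} <= set(auc_rows.index):
        s, c = auc_rows.loc["split_sample_test"], auc_rows.loc["cv_oof"]
        if all(v is not None and np.isfinite(v)
               for v in (s["internal_lower"], s["internal_upper"], c["internal_lower"], c["internal_upper"])):
            ratio = ci_width_ratio_percent((s["internal_lower"], s["internal_upper"]),
                                           (c["internal_lower"], c["internal_upper"]))
    if ratio is None:
        ratio = report.metadata.get("split_test_vs_cv_auc_width_ratio_pct")
    path = out / "ci_width.csv"
    with open(path, "w") as fh:
        fh.write(f"# split_test_vs_cv_auc_width_ratio_pct: {ratio if ratio is not None else 'NA'}\n")
        widths.to_csv(fh, index=False)
    paths["ci_width"] = path
    return paths
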