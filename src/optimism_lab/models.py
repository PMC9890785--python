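"""Learners under validation: random forest and a logistic baseline.

The random forest is the flexible, data-adaptive learner whose internal
validation the study design probes; the (optionally ridge-penalized)
logistic model is the non-adaptive parametric contrast for which classical
optimism correction is known to behave well. Both sit behind one
fit/predict/tune surface keyed by :class:`LearnerSpec`.

Hyperparameter tuning follows the study recipe: person-level k-fold
cross-validation, one pooled out-of-fold score vector per grid point, AUC
computed once on that vector, argmax selected. The selected grid point's
out-of-fold scores are retained because the cross-validation scheme reuses
them for internal validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from ._rng import seed_for
from .cohort import predictor_columns
from .metrics import SingleClassError, auc
from .resampling import make_person_folds

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Prediction-time predictor schema differs from training schema."""


@dataclass(frozen=True)
class LearnerSpec:
    """Hyperparameterized learner description.

    kind: 'random_forest' or 'logistic'.
    min_node_size: minimum terminal node size; a value in (0, 1) is a
        fraction of training visits (resolved at fit time), >= 1 an
        absolute visit count. Fractions are the default idiom because
        absolute leaf sizes only make sense relative to the sample size
        they were chosen for.
    mtry: predictors sampled per split (random forest only).
    n_trees: forest size.
    penalty: L2 strength for the logistic learner (0 = unpenalized).
    """

    kind: str
    min_node_size: float | None = None
    mtry: int | None = None
    n_trees: int = 500
    penalty: float = 0.0

    def __post_init__(self):
        if self.kind not in ("random_forest", "logistic"):
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if self.kind == "random_forest":
            if self.min_node_size is None or self.min_node_size <= 0:
                raise ValueError("random_forest requires min_node_size > 0")
            if self.mtry is None or self.mtry < 1:
                raise ValueError("random_forest requires mtry >= 1")
            if self.n_trees < 1:
                raise ValueError("n_trees must be >= 1")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")

    def resolved_min_node(self, n_visits: int) -> int | None:
        if self.min_node_size is None:
            return None
        if self.min_node_size < 1:
            return max(1, int(round(self.min_node_size * n_visits)))
        return int(self.min_node_size)

    def describe(self) -> str:
        if self.kind == "random_forest":
            return f"rf(node={self.min_node_size:g}, mtry={self.mtry}, trees={self.n_trees})"
        return f"logistic(penalty={self.penalty:g})"


@dataclass
class RiskModel:
    """A fitted, score-producing learner plus its training context."""

    estimator: object
    spec: LearnerSpec
    predictors: list[str]
    in_sample_scores: np.ndarray
    train_visit_ids: np.ndarray
    n_train_visits: int
    n_train_persons: int

    @property
    def score_summary(self) -> dict:
        s = self.in_sample_scores
        return {
            "min": float(s.min()), "q25": float(np.quantile(s, 0.25)),
            "median": float(np.quantile(s, 0.5)), "q75": float(np.quantile(s, 0.75)),
            "max": float(s.max()), "mean": float(s.mean()),
        }


def _design(table: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    return table[predictors].to_numpy(dtype=float)


def fit(table: pd.DataFrame, spec: LearnerSpec, seed: int = 0) -> RiskModel:
    """Fit a learner; deterministic given (table, spec, seed)."""
    predictors = predictor_columns(table)
    if spec.kind == "random_forest" and spec.mtry is not None and spec.mtry > len(predictors):
        raise ValueError(f"mtry={spec.mtry} exceeds n_predictors={len(predictors)}")
    X = _design(table, predictors)
    y = table["y"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("training data contain a single outcome class")
    if spec.kind == "random_forest":
        est = RandomForestClassifier(
            n_estimators=spec.n_trees,
            min_samples_leaf=spec.resolved_min_node(len(table)),
            max_features=spec.mtry,
            random_state=seed_for(seed, "forest"),
            n_jobs=1,
        )
    else:
        C = np.inf if spec.penalty == 0 else 1.0 / spec.penalty
        est = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
    est.fit(X, y)
    scores = est.predict_proba(X)[:, 1]
    return RiskModel(
        estimator=est,
        spec=spec,
        predictors=predictors,
        in_sample_scores=scores,
        train_visit_ids=table["visit_id"].to_numpy(),
        n_train_visits=len(table),
        n_train_persons=table["person_id"].nunique(),
    )


def predict_scores(model: RiskModel, table: pd.DataFrame) -> np.ndarray:
    """One risk score per visit, order-aligned to ``table``."""
    cols = set(predictor_columns(table))
    trained = set(model.predictors)
    if cols != trained:
        missing = sorted(trained - cols)
        extra = sorted(cols - trained)
        raise SchemaError(f"predictor schema mismatch; missing={missing}, extra={extra}")
    return model.estimator.predict_proba(_design(table, model.predictors))[:, 1]


@dataclass
class TuningResult:
    """Grid of out-of-fold AUCs, the selected spec, and its saved
    out-of-fold scores (aligned to ``visit_ids``)."""

    grid: list[LearnerSpec]
    oof_auc: list[float]
    selected_index: int
    oof_scores: np.ndarray  # for the selected spec
    visit_ids: np.ndarray
    fold_of_person: pd.Series
    seed: int

    @property
    def selected(self) -> LearnerSpec:
        return self.grid[self.selected_index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (spec, a) in enumerate(zip(self.grid, self.oof_auc)):
            rows.append({
                "kind": spec.kind,
                "min_node_size": spec.min_node_size,
                "mtry": spec.mtry,
                "n_trees": spec.n_trees,
                "penalty": spec.penalty,
                "oof_auc": a,
                "selected": i == self.selected_index,
            })
        return pd.DataFrame(rows)


def _tie_break_key(spec: LearnerSpec, index: int, n_visits: int):
    # among equal AUCs prefer the simpler model: larger terminal nodes,
    # then fewer predictors per split, then earlier grid position
    if spec.kind == "random_forest":
        size = spec.resolved_min_node(n_visits)
        return (size, -spec.mtry, -index)
    return (spec.penalty, 0, -index)


def tune(table: pd.DataFrame, grid: list[LearnerSpec], k: int = 5, seed: int = 0) -> TuningResult:
    """Person-level k-fold CV over a grid; selects the pooled-OOF-AUC argmax.

    If some fold leaves single-class training data, folds are redrawn with
    a derived seed (at most 5 attempts).
    """
    if not grid:
        raise ValueError("empty tuning grid")
    y = table["y"].to_numpy(dtype=int)
    folds = None
    for attempt in range(5):
        cand = make_person_folds(table, k, seed_for(seed, "folds", attempt))
        ok = True
        for f in cand.arms:
            train_y = cand.select_not(table, f)["y"]
            if train_y.nunique() < 2:
                ok = False
                break
        if ok:
            folds = cand
            break
        logger.warning("fold attempt %d left single-class training data; refolding", attempt)
    if folds is None:
        raise SingleClassError("could not build folds with two-class training data in 5 attempts")

    fold_label = table["person_id"].map(folds.assignments).to_numpy()
    n = len(table)
    oof_auc_list: list[float] = []
    oof_store: list[np.ndarray] = []
    for i, spec in enumerate(grid):
        oof = np.full(n, np.nan)
        for f in folds.arms:
            hold = fold_label == f
            model = fit(table[~hold].reset_index(drop=True), spec, seed=seed_for(seed, "fit", i, f))
            oof[hold] = predict_scores(model, table[hold].reset_index(drop=True))
        assert not np.isnan(oof).any(), "out-of-fold scores must cover every visit"
        oof_auc_list.append(auc(oof, y))
        oof_store.append(oof)
        logger.info("tune: %s -> oof auc %.4f", spec.describe(), oof_auc_list[-1])

    best = max(range(len(grid)),
               key=lambda i: (oof_auc_list[i], _tie_break_key(grid[i], i, n)))
    return TuningResult(
        grid=list(grid),
        oof_auc=oof_auc_list,
        selected_index=best,
        oof_scores=oof_store[best],
        visit_ids=table["visit_id"].to_numpy(),
        fold_of_person=folds.assignments,
        seed=seed,
    )


def default_mtry_grid(n_predictors: int) -> list[int]:
    """{floor(sqrt(p)/2), floor(sqrt(p)), 2*floor(sqrt(p))}, the classification
    default bracketed by half and double."""
    base = int(np.floor(np.sqrt(n_predictors)))
    vals = sorted({max(1, base // 2), base, min(n_predictors, 2 * base)})
    return vals


def rf_grid(node_fractions, mtry_values, n_trees: int = 500) -> list[LearnerSpec]:
    return [
        LearnerSpec(kind="random_forest", min_node_size=f, mtry=m, n_trees=n_trees)
        for f in node_fractions for m in mtry_values
    ]
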