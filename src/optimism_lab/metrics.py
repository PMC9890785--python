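"""Discrimination and threshold classification metrics with quantile CIs.

Conventions used throughout the package:

* AUC is the Mann-Whitney probability computed from midranks (ties count
  one half), O(n log n).
* Risk-score thresholds are placed at percentiles of a named *reference*
  score distribution (e.g. the training-set in-sample scores), and a visit
  is flagged high-risk iff its score is >= the cutoff.
* All empirical quantiles — threshold cutoffs and bootstrap CI endpoints —
  use the type-1 inverse-CDF definition (the ceil(q*n)-th order statistic,
  no interpolation), so results are bit-reproducible across platforms.
* PPV is TP/(TP+FP); because events are rare it is also displayed per
  100,000 flagged visits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

METRICS = ("auc", "sensitivity", "specificity", "ppv")


class SingleClassError(ValueError):
    pass


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0:
        raise SingleClassError("no events (positive class absent)")
    if n0 == 0:
        raise SingleClassError("no non-events (negative class absent)")
    return n1, n0


def auc(scores, labels) -> float:
    """Mann-Whitney AUC via midranks: P(score_event > score_nonevent) + ties/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n1, n0 = _check_binary(labels)
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def quantile_type1(values, q: float) -> float:
    """Empirical q-quantile by the inverse-CDF (type 1) definition."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty input")
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    # tiny epsilon guards float error, e.g. 0.025 * 1000 = 25.000000000000004
    k = max(1, math.ceil(q * values.size - 1e-9))
    return float(values[k - 1])


@dataclass(frozen=True)
class ThresholdSet:
    """Percentile cutpoints bound to absolute score cutoffs.

    ``reference_label`` records which score distribution the percentiles
    were taken from — the study convention is that thresholds travel with
    the model (defined on development-side scores), never recomputed on the
    evaluation sample.
    """

    percentiles: tuple
    cutoffs: tuple
    reference_label: str

    def __post_init__(self):
        pcts = np.asarray(self.percentiles, dtype=float)
        cuts = np.asarray(self.cutoffs, dtype=float)
        if pcts.size != cuts.size:
            raise ValueError("percentiles and cutoffs must have equal length")
        if pcts.size and (np.any(np.diff(pcts) <= 0) or np.any((pcts <= 0) | (pcts >= 100))):
            raise ValueError("percentiles must be strictly increasing within (0, 100)")
        if cuts.size and np.any(np.diff(cuts) < 0):
            raise ValueError("cutoffs must be non-decreasing with percentile")


def percentile_thresholds(reference_scores, percentiles: Sequence[float], reference_label: str) -> ThresholdSet:
    """Type-1 empirical percentiles of a reference score distribution."""
    scores = np.asarray(reference_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("reference scores are empty")
    pcts = tuple(sorted(float(p) for p in percentiles))
    cuts = tuple(quantile_type1(scores, p / 100.0) for p in pcts)
    return ThresholdSet(percentiles=pcts, cutoffs=cuts, reference_label=reference_label)


@dataclass
class PerformanceEstimate:
    """One metric with its threshold context and (optional) quantile CI.

    For optimism-corrected estimates the point need not lie inside the CI
    (nor even inside [0, 1]); such values are diagnostic and are reported,
    not clipped.
    """

    metric: str
    percentile: float | None
    point: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    scheme: str = ""
    n_boot: int | None = None

    @property
    def per_100k(self) -> float:
        """Display scale for PPV (events per 100,000 flagged visits)."""
        return self.point * 1e5

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.point)


def _counts_at_cutoff(scores: np.ndarray, labels: np.ndarray, cutoff: float):
    flagged = scores >= cutoff
    tp = int(np.count_nonzero(flagged & (labels == 1)))
    fp = int(np.count_nonzero(flagged & (labels == 0)))
    fn = int(np.count_nonzero(~flagged & (labels == 1)))
    tn = int(np.count_nonzero(~flagged & (labels == 0)))
    return tp, fp, fn, tn


def classify_at_thresholds(scores, labels, thresholds: ThresholdSet, scheme: str = "") -> list[PerformanceEstimate]:
    """Sensitivity, specificity and PPV at each cutpoint (point estimates).

    Flagging rule: score >= cutoff. PPV with zero flagged visits is
    undefined and returned as NaN with a logged warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    out = []
    for pct, cut in zip(thresholds.percentiles, thresholds.cutoffs):
        tp, fp, fn, tn = _counts_at_cutoff(scores, labels, cut)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if tp + fp == 0:
            logger.warning("no visits flagged at the %gth percentile cutoff; PPV undefined", pct)
            ppv = float("nan")
        else:
            ppv = tp / (tp + fp)
        out.extend([
            PerformanceEstimate("sensitivity", pct, sens, scheme=scheme),
            PerformanceEstimate("specificity", pct, spec, scheme=scheme),
            PerformanceEstimate("ppv", pct, ppv, scheme=scheme),
        ])
    return out


def evaluate_all(scores, labels, thresholds: ThresholdSet) -> dict:
    """All metrics as a flat dict keyed by (metric, percentile|None)."""
    values = {("auc", None): auc(scores, labels)}
    for est in classify_at_thresholds(scores, labels, thresholds):
        values[(est.metric, est.percentile)] = est.point
    return values


def quantile_ci(replicate_values, level: float = 0.95) -> tuple[float, float]:
    """Quantile-based CI from bootstrap replicate values (type-1 quantiles).

    Non-finite replicates are dropped (count logged); with a single finite
    replicate the interval degenerates to that value.
    """
    values = np.asarray(replicate_values, dtype=float)
    finite = values[np.isfinite(values)]
    n_dropped = values.size - finite.size
    if n_dropped:
        logger.warning("quantile_ci: dropped %d non-finite replicate(s) of %d", n_dropped, values.size)
    if finite.size == 0:
        raise ValueError("all replicate values are missing")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    return quantile_type1(finite, alpha), quantile_type1(finite, 1.0 - alpha)
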