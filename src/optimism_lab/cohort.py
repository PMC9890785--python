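"""Synthetic visit-level cohorts for rare-event risk prediction studies.

Emulates the structure of large health-system cohorts used to build
short-horizon (90-day) suicide/self-harm risk models: many visits clustered
within persons, a very rare binary outcome, a mostly-binary high-dimensional
predictor block with nonlinear and interaction signal, and covariate /
event-rate drift between a development period and a later prospective
period. One person-level event is attributed to that person's most recent
visits in the period, so a single event can mark several visit rows — the
feature that makes person-level (rather than visit-level) resampling the
correct unit for validation.

The universal data carrier is a pandas DataFrame ("visit table") with
columns ``person_id, visit_id, period, y, x_0001, ...``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from ._rng import rng_for

logger = logging.getLogger(__name__)

PERIOD_DEV = "development"
PERIOD_PROSP = "prospective"

ID_COLUMNS = ("person_id", "visit_id", "period", "y")


class CalibrationError(ValueError):
    """Marginal event-rate calibration failed: the target rate is outside
    the range achievable under the configured attribution mechanism."""


@dataclass(frozen=True)
class SignalSpec:
    """Log-odds signal acting on the predictor block.

    linear:       predictor index -> coefficient
    interactions: (i, j, coefficient) pairwise product terms
    thresholds:   (j, cutoff, coefficient) step terms coef * 1[x_j > cutoff]
    Indices are 0-based into the predictor columns (binary block first,
    then continuous).
    """

    linear: Mapping[int, float] = field(default_factory=dict)
    interactions: tuple = ()
    thresholds: tuple = ()

    def is_null(self) -> bool:
        return not (self.linear or self.interactions or self.thresholds)

    def to_dict(self) -> dict:
        return {
            "linear": {int(k): float(v) for k, v in self.linear.items()},
            "interactions": [[int(i), int(j), float(c)] for i, j, c in self.interactions],
            "thresholds": [[int(j), float(cut), float(c)] for j, cut, c in self.thresholds],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignalSpec":
        return cls(
            linear={int(k): float(v) for k, v in (d.get("linear") or {}).items()},
            interactions=tuple((int(i), int(j), float(c)) for i, j, c in (d.get("interactions") or ())),
            thresholds=tuple((int(j), float(cut), float(c)) for j, cut, c in (d.get("thresholds") or ())),
        )


def default_signal(n_binary: int, n_continuous: int, structure_seed: int) -> SignalSpec:
    """Default signal: ~12 binary flags, 3 continuous slopes, two pairwise
    interactions and one step term — enough nonlinearity that a flexible
    tree ensemble can out-discriminate a main-effects logistic model."""
    rng = rng_for(structure_seed, "signal")
    n_bin_sig = min(12, n_binary)
    bin_idx = np.sort(rng.choice(n_binary, size=n_bin_sig, replace=False))
    bin_coef = rng.uniform(0.7, 1.6, size=n_bin_sig) * np.where(rng.random(n_bin_sig) < 0.75, 1.0, -1.0)
    linear = {int(j): float(c) for j, c in zip(bin_idx, bin_coef)}
    cont_idx = []
    if n_continuous > 0:
        n_cont_sig = min(3, n_continuous)
        cont_idx = np.sort(rng.choice(n_continuous, size=n_cont_sig, replace=False)) + n_binary
        for j, c in zip(cont_idx, rng.uniform(0.3, 0.7, size=len(cont_idx))):
            linear[int(j)] = float(c)
    interactions = []
    if n_bin_sig >= 4:
        pairs = rng.choice(n_bin_sig, size=(2, 2), replace=False)
        for i, j in pairs:
            interactions.append((int(bin_idx[i]), int(bin_idx[j]), float(rng.uniform(0.8, 1.5))))
    thresholds = []
    if len(cont_idx) > 0:
        thresholds.append((int(cont_idx[0]), 1.0, float(rng.uniform(1.0, 1.8))))
    return SignalSpec(linear=linear, interactions=tuple(interactions), thresholds=tuple(thresholds))


def default_drift(n_binary: int, n_continuous: int, structure_seed: int) -> dict:
    """Default drift: prevalence deltas on 8 binary flags — three of them
    outcome-associated (drift in predictors tied to the outcome, like
    changing instrument usage, is what actually degrades prospective
    discrimination) — plus a mean shift on one continuous predictor."""
    rng = rng_for(structure_seed, "drift")
    signal = default_signal(n_binary, n_continuous, structure_seed)
    signal_bin = [j for j in signal.linear if j < n_binary]
    sig_idx = rng.choice(len(signal_bin), size=min(3, len(signal_bin)), replace=False)
    drift = {int(signal_bin[i]): float(rng.uniform(0.08, 0.18) * rng.choice([-1, 1]))
             for i in sig_idx}
    rest = np.setdiff1d(np.arange(n_binary), list(drift))
    idx = rng.choice(rest, size=min(5, rest.size), replace=False)
    drift.update({int(j): float(d) for j, d in zip(idx, rng.uniform(-0.12, 0.12, size=len(idx)))})
    if n_continuous > 0:
        drift[int(n_binary)] = 0.3
    return drift


@dataclass
class CohortConfig:
    """Generator configuration.

    Defaults are the package's desk-scale study conditions: ~25k visits in
    5,000 persons split evenly between periods, 1,200 events per 100,000
    development visits falling to 900 per 100,000 prospectively,
    person-level frailty, and covariate drift that touches several
    outcome-associated predictors.

    attribution: "person" draws one event per person-period from the
    person's average visit-level risk and marks the k most recent visits
    (k = event_visits_per_event); "visit" draws independent per-visit
    Bernoulli outcomes (a correctly specified visit-level logistic
    process, useful as a parametric control).
    """

    n_persons: int = 5000
    visit_mean: float = 5.0
    visit_dispersion: float = 1.2
    n_binary: int = 100
    n_continuous: int = 5
    event_rate_dev: float = 1200e-5
    event_rate_prosp: float = 900e-5
    signal: SignalSpec | None = None  # None -> default_signal
    frailty_sd: float = 0.5
    drift: Mapping[int, float] | None = None  # None -> default_drift; {} -> no drift
    dev_period_fraction: float = 0.5
    event_visits_per_event: int = 2
    attribution: str = "person"
    seed: int = 0
    structure_seed: int = 20230

    @property
    def n_predictors(self) -> int:
        return self.n_binary + self.n_continuous

    def validate(self) -> None:
        if self.n_persons < 2:
            raise ValueError("n_persons must be >= 2")
        if not (0 < self.event_rate_dev < 1 and 0 < self.event_rate_prosp < 1):
            raise ValueError("event rates must lie in (0, 1)")
        if not (0 < self.dev_period_fraction < 1):
            raise ValueError("dev_period_fraction must lie in (0, 1)")
        for name in ("visit_mean", "n_binary", "n_continuous", "event_visits_per_event"):
            if getattr(self, name) <= 0 and name != "n_continuous":
                raise ValueError(f"{name} must be positive")
        if self.n_continuous < 0 or self.n_binary < 1:
            raise ValueError("need n_binary >= 1 and n_continuous >= 0")
        if self.frailty_sd < 0:
            raise ValueError("frailty_sd must be >= 0")
        if self.attribution not in ("person", "visit"):
            raise ValueError("attribution must be 'person' or 'visit'")

    # -- config (de)serialization ------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["signal"] = None if self.signal is None else self.signal.to_dict()
        d["drift"] = None if self.drift is None else {int(k): float(v) for k, v in self.drift.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if d.get("signal") is not None:
            d["signal"] = SignalSpec.from_dict(d["signal"])
        if d.get("drift") is not None:
            d["drift"] = {int(k): float(v) for k, v in d["drift"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def predictor_columns(table: pd.DataFrame) -> list[str]:
    """Predictor column names (``x_*``), in schema order."""
    return sorted(c for c in table.columns if c.startswith("x_"))


def _signal_log_odds(X: np.ndarray, signal: SignalSpec) -> np.ndarray:
    lp = np.zeros(X.shape[0])
    for j, c in signal.linear.items():
        lp += c * X[:, j]
    for i, j, c in signal.interactions:
        lp += c * X[:, i] * X[:, j]
    for j, cut, c in signal.thresholds:
        lp += c * (X[:, j] > cut)
    return lp


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a visit table covering both periods.

    Per person: a Gaussian random intercept (frailty) and a negative-
    binomial visit count, the first ``dev_period_fraction`` of visits
    falling in the development period. Per visit: period-dependent
    predictors and a log-odds built from the signal spec. A period-specific
    calibration intercept is solved by root finding so the expected
    visit-level event rate matches the configured rate in each period, then
    outcomes are drawn under the configured attribution mechanism.
    """
    config.validate()
    n_b, n_c = config.n_binary, config.n_continuous
    k_attr = config.event_visits_per_event

    struct = rng_for(config.structure_seed, "prevalence")
    prevalence = np.exp(struct.uniform(np.log(0.01), np.log(0.75), size=n_b))
    signal = config.signal if config.signal is not None else default_signal(n_b, n_c, config.structure_seed)
    drift = config.drift if config.drift is not None else default_drift(n_b, n_c, config.structure_seed)

    rng = rng_for(config.seed, "cohort")

    # person-level structure
    extra_mean = config.visit_mean - 1.0
    if extra_mean <= 0:
        n_visits = np.ones(config.n_persons, dtype=int)
    else:
        r = config.visit_dispersion
        n_visits = 1 + rng.negative_binomial(r, r / (r + extra_mean), size=config.n_persons)
    n_dev = np.rint(config.dev_period_fraction * n_visits).astype(int)
    frailty = rng.normal(0.0, config.frailty_sd, size=config.n_persons) if config.frailty_sd > 0 else np.zeros(config.n_persons)

    total = int(n_visits.sum())
    person_row = np.repeat(np.arange(config.n_persons), n_visits)
    row_offsets = np.cumsum(n_visits) - n_visits
    visit_idx = np.arange(total) - np.repeat(row_offsets, n_visits)  # chronological within person
    is_prosp = visit_idx >= np.repeat(n_dev, n_visits)

    # predictors
    X = np.empty((total, n_b + n_c))
    for j in range(n_b):
        p = prevalence[j]
        delta = drift.get(j, 0.0)
        if delta:
            p_row = np.where(is_prosp, np.clip(p + delta, 1e-3, 1 - 1e-3), p)
            X[:, j] = (rng.random(total) < p_row).astype(float)
        else:
            X[:, j] = (rng.random(total) < p).astype(float)
    for j in range(n_c):
        col = n_b + j
        X[:, col] = rng.normal(size=total) + drift.get(col, 0.0) * is_prosp

    used = set(signal.linear) | {i for i, j, _ in signal.interactions} \
        | {j for i, j, _ in signal.interactions} | {j for j, _, _ in signal.thresholds}
    if used and max(used) >= n_b + n_c:
        raise ValueError(f"signal references predictor index {max(used)} "
                         f"but only {n_b + n_c} predictors are configured")
    lp = _signal_log_odds(X, signal) + frailty[person_row]

    # period-specific intercept calibration, then outcome draw
    y = np.zeros(total, dtype=int)
    for period_mask, rate, tag in (
        (~is_prosp, config.event_rate_dev, PERIOD_DEV),
        (is_prosp, config.event_rate_prosp, PERIOD_PROSP),
    ):
        if not period_mask.any():
            raise ValueError(f"no visits fall in the {tag} period; adjust dev_period_fraction")
        lp_m = lp[period_mask]
        n_period = lp_m.size
        if config.attribution == "visit":
            weights = None
            seg_bounds = None
            max_rate = 1.0

            def realized(c, lp_m=lp_m, n_period=n_period):
                return expit(lp_m + c).mean()

        else:
            # person-period segments (rows are person-major, time-ordered)
            pm = person_row[period_mask]
            seg_start = np.flatnonzero(np.r_[True, pm[1:] != pm[:-1]])
            seg_bounds = np.r_[seg_start, n_period]
            seg_len = np.diff(seg_bounds)
            weights = np.minimum(k_attr, seg_len).astype(float)
            max_rate = weights.sum() / n_period

            def realized(c, lp_m=lp_m, seg_start=seg_start, seg_len=seg_len, weights=weights, n_period=n_period):
                p_seg = np.add.reduceat(expit(lp_m + c), seg_start) / seg_len
                return float(np.sum(weights * p_seg)) / n_period

        if rate >= max_rate:
            raise CalibrationError(
                f"{tag} target event rate {rate:g} unreachable; achievable range is (0, {max_rate:g}) "
                f"under attribution={config.attribution!r} with k={k_attr}"
            )
        lo, hi = -40.0, 40.0
        c_star = brentq(lambda c: realized(c) - rate, lo, hi, xtol=1e-10)

        rows_period = np.flatnonzero(period_mask)
        if config.attribution == "visit":
            y[rows_period] = rng.random(n_period) < expit(lp_m + c_star)
        else:
            seg_start = seg_bounds[:-1]
            seg_len = np.diff(seg_bounds)
            p_seg = np.add.reduceat(expit(lp_m + c_star), seg_start) / seg_len
            hit = rng.random(p_seg.size) < p_seg
            for s in np.flatnonzero(hit):  # events are rare: this loop is short
                end = seg_bounds[s + 1]
                n_mark = min(k_attr, seg_len[s])
                y[rows_period[end - n_mark:end]] = 1

    width = max(5, len(str(config.n_persons)))
    person_labels = np.array([f"P{i:0{width}d}" for i in range(config.n_persons)])
    person_id = person_labels[person_row]
    visit_id = np.char.add(np.char.add(person_id.astype(str), "-v"), np.char.zfill(visit_idx.astype(str), 3))

    data = {
        "person_id": person_id,
        "visit_id": visit_id,
        "period": np.where(is_prosp, PERIOD_PROSP, PERIOD_DEV),
        "y": y,
    }
    xcols = [f"x_{j + 1:04d}" for j in range(n_b + n_c)]
    table = pd.concat([pd.DataFrame(data), pd.DataFrame(X, columns=xcols)], axis=1)
    return table


def temporal_split(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition visits by period label (persons may appear in both)."""
    periods = set(table["period"].unique())
    missing = {PERIOD_DEV, PERIOD_PROSP} - periods
    if missing:
        raise ValueError(f"period(s) absent from table: {sorted(missing)}")
    dev = table[table["period"] == PERIOD_DEV].reset_index(drop=True)
    prosp = table[table["period"] == PERIOD_PROSP].reset_index(drop=True)
    return dev, prosp


def event_rate_per_100k(n_event_visits: int, n_visits: int) -> float:
    """Event-visit rate per 100,000 visits (exact, unrounded)."""
    if n_visits <= 0:
        raise ValueError("n_visits must be positive")
    return 1e5 * n_event_visits / n_visits


@dataclass(frozen=True)
class CohortSummary:
    n_visits: int
    n_persons: int
    n_event_visits: int
    n_event_persons: int
    event_rate_per_100k: float

    @property
    def event_rate_per_100k_display(self) -> int:
        return int(round(self.event_rate_per_100k))


def summarize_cohort(table: pd.DataFrame) -> CohortSummary:
    """Visit/person/event counts and the event rate per 100,000 visits."""
    if len(table) == 0:
        raise ValueError("empty table")
    events = table["y"].astype(int)
    event_persons = table.loc[events == 1, "person_id"].nunique()
    return CohortSummary(
        n_visits=len(table),
        n_persons=table["person_id"].nunique(),
        n_event_visits=int(events.sum()),
        n_event_persons=int(event_persons),
        event_rate_per_100k=event_rate_per_100k(int(events.sum()), len(table)),
    )


def write_visits(table: pd.DataFrame, path) -> None:
    """CSV serialization; continuous predictors kept to 12 significant digits."""
    table.to_csv(path, index=False, float_format="%.12g")


def read_visits(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"person_id": str, "visit_id": str, "period": str})
    table["y"] = table["y"].astype(int)
    return table
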