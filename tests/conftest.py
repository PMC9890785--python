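import logging

import numpy as np
import pandas as pd
import pytest

from optimism_lab import CohortConfig, SignalSpec, generate_cohort, temporal_split

logging.getLogger("optimism_lab").setLevel(logging.ERROR)


def make_table(visits_per_person, event_visits=(), periods=None):
    """Hand-built visit table: visits_per_person is a dict person -> n_visits;
    event_visits is a set of (person, visit_index) pairs marked y=1."""
    rows = []
    for pid, n in visits_per_person.items():
        for v in range(n):
            rows.append({
                "person_id": str(pid),
                "visit_id": f"{pid}-v{v}",
                "period": (periods or {}).get(pid, "development"),
                "y": int((pid, v) in set(event_visits)),
                "x_0001": float(v),
                "x_0002": float(hash(pid) % 7),
            })
    return pd.DataFrame(rows)


LINEAR_SIGNAL = SignalSpec(
    linear={0: 0.9, 2: 0.8, 4: -0.7, 6: 1.0, 8: 0.8, 10: -0.6, 12: 0.9, 14: 0.7, 15: 0.5, 16: 0.4}
)

# fits inside any predictor block with >= 6 binary columns
SMALL_SIGNAL = SignalSpec(linear={0: 1.0, 1: 0.8, 3: -0.7, 5: 0.9})


def linear_config(n_persons, seed, event_rate=0.02, **overrides):
    """A correctly specified visit-level logistic data process: purely
    linear log-odds, no frailty, no drift, equal period rates."""
    base = dict(
        n_persons=n_persons, visit_mean=5.0, n_binary=15, n_continuous=5,
        event_rate_dev=event_rate, event_rate_prosp=event_rate,
        signal=LINEAR_SIGNAL, frailty_sd=0.0, drift={},
        dev_period_fraction=0.5, attribution="visit", seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """~2k visits, moderate event rate, default nonlinear signal."""
    cfg = CohortConfig(n_persons=400, visit_mean=5.0, n_binary=12, n_continuous=3,
                       event_rate_dev=0.02, event_rate_prosp=0.015, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dev(small_cohort):
    dev, _ = temporal_split(small_cohort)
    return dev


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230)
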