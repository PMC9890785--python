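"""Generator contracts: calibration, clustering, determinism, round-trips."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from optimism_lab import (CalibrationError, CohortConfig, SignalSpec, auc,
                          event_rate_per_100k, fit, generate_cohort, predict_scores,
                          read_visits, summarize_cohort, temporal_split, write_visits)
from conftest import linear_config, make_table


@pytest.mark.parametrize("bad", [
    dict(n_persons=1),
    dict(event_rate_dev=0.0),
    dict(event_rate_prosp=1.0),
    dict(dev_period_fraction=0.0),
    dict(dev_period_fraction=1.0),
    dict(frailty_sd=-0.1),
    dict(attribution="household"),
    dict(n_binary=0),
])
def test_config_validation_rejects(bad):
    cfg = replace(CohortConfig(), **bad)
    with pytest.raises(ValueError):
        cfg.validate()


def test_unreachable_rate_names_achievable_range():
    # person attribution with k=1 caps the visit-level rate at 1/mean-visits
    cfg = CohortConfig(n_persons=200, visit_mean=6.0, event_rate_dev=0.9,
                       event_visits_per_event=1, seed=0)
    with pytest.raises(CalibrationError, match="achievable range"):
        generate_cohort(cfg)


def test_generation_is_byte_identical_for_same_config():
    cfg = CohortConfig(n_persons=150, n_binary=8, n_continuous=2,
                       event_rate_dev=0.03, event_rate_prosp=0.02, seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(replace(cfg, seed=43))
    assert not a["y"].equals(c["y"]) or not a["x_0001"].equals(c["x_0001"])


def test_csv_round_trip_lossless(tmp_path, small_cohort):
    path = tmp_path / "visits.csv"
    write_visits(small_cohort, path)
    back = read_visits(path)
    assert back["person_id"].tolist() == small_cohort["person_id"].tolist()
    assert back["visit_id"].tolist() == small_cohort["visit_id"].tolist()
    assert back["y"].tolist() == small_cohort["y"].tolist()
    x = [c for c in small_cohort.columns if c.startswith("x_")]
    np.testing.assert_allclose(back[x].to_numpy(), small_cohort[x].to_numpy(), rtol=1e-11)


def test_config_yaml_round_trip(tmp_path):
    cfg = linear_config(300, seed=5, drift={2: 0.1})
    path = tmp_path / "cohort.yaml"
    cfg.to_yaml(path)
    back = CohortConfig.from_yaml(path)
    assert back.to_dict() == cfg.to_dict()


def test_temporal_split_partitions_by_visit():
    table = make_table({"a": 3, "b": 2}, periods={"b": "prospective"})
    # give person a one prospective visit too
    table.loc[table.index[-3], "period"] = "prospective"
    dev, prosp = temporal_split(table)
    assert len(dev) + len(prosp) == len(table)
    assert set(dev["period"]) == {"development"} and set(prosp["period"]) == {"prospective"}
    assert "a" in set(dev["person_id"]) and "a" in set(prosp["person_id"])


def test_temporal_split_requires_both_periods():
    table = make_table({"a": 3})
    with pytest.raises(ValueError, match="absent"):
        temporal_split(table)


def test_summarize_counts_events_and_persons():
    table = make_table({"a": 3, "b": 2, "c": 1}, event_visits=[("a", 1), ("a", 2)])
    s = summarize_cohort(table)
    assert (s.n_visits, s.n_persons, s.n_event_visits, s.n_event_persons) == (6, 3, 2, 1)
    assert s.event_rate_per_100k == pytest.approx(1e5 * 2 / 6)
    none = summarize_cohort(make_table({"a": 2}))
    assert none.event_rate_per_100k == 0.0 and none.event_rate_per_100k_display == 0


def test_development_event_count_matches_configured_rate():
    # 1e6 development visits at 24 per 100k: realized count within 3 binomial SD
    cfg = CohortConfig(n_persons=400_000, visit_mean=5.0, n_binary=10, n_continuous=2,
                       event_rate_dev=24e-5, event_rate_prosp=19e-5,
                       event_visits_per_event=1, frailty_sd=0.3, seed=7)
    table = generate_cohort(cfg)
    dev, _ = temporal_split(table)
    mean = 24e-5 * len(dev)
    sd = np.sqrt(len(dev) * 24e-5 * (1 - 24e-5))
    assert abs(dev["y"].sum() - mean) < 3 * sd
    # 3 binomial SDs at this size is ~4.6 events per 100k around 24
    assert abs(summarize_cohort(dev).event_rate_per_100k - 24) < 3 * sd / len(dev) * 1e5


def test_calibration_holds_across_seeds():
    hits = 0
    for seed in range(10):
        cfg = CohortConfig(n_persons=1500, visit_mean=4.0, n_binary=20, n_continuous=3,
                           event_rate_dev=0.02, event_rate_prosp=0.015, seed=seed)
        dev, _ = temporal_split(generate_cohort(cfg))
        mean = 0.02 * len(dev)
        sd = np.sqrt(len(dev) * 0.02 * 0.98)
        hits += abs(dev["y"].sum() - mean) < 3 * sd
    assert hits >= 9


def test_no_signal_cohort_gives_null_auc():
    cfg = linear_config(2000, seed=3, signal=SignalSpec())
    dev, prosp = temporal_split(generate_cohort(cfg))
    model = fit(dev, __import__("optimism_lab").LearnerSpec(kind="logistic", penalty=1.0), seed=0)
    a = auc(predict_scores(model, prosp), prosp["y"])
    assert abs(a - 0.5) < 0.06


def _dispersion_pvalue(table, rng, n_perm=200):
    """Two-sided permutation test of within-person event-count dispersion."""
    codes = pd.factorize(table["person_id"])[0]
    y = table["y"].to_numpy()
    obs = np.bincount(codes, weights=y).var()
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = np.bincount(codes, weights=rng.permutation(y)).var()
    center = perm.mean()
    return np.mean(np.abs(perm - center) >= abs(obs - center))


def test_outcomes_independent_without_frailty_single_attribution():
    # frailty 0, one event visit per event, equal rates: no detectable
    # within-person clustering at alpha=0.01 in >= 18 of 20 seeds
    rng = np.random.default_rng(99)
    nonsig = 0
    for seed in range(20):
        cfg = CohortConfig(n_persons=600, visit_mean=4.0, n_binary=8, n_continuous=2,
                           event_rate_dev=0.02, event_rate_prosp=0.02,
                           frailty_sd=0.0, event_visits_per_event=1, drift={}, seed=seed)
        dev, _ = temporal_split(generate_cohort(cfg))
        nonsig += _dispersion_pvalue(dev, rng) > 0.01
    assert nonsig >= 18


def test_frailty_and_multi_visit_attribution_cluster_outcomes():
    rng = np.random.default_rng(7)
    cfg = CohortConfig(n_persons=3000, visit_mean=5.0, n_binary=8, n_continuous=2,
                       event_rate_dev=0.03, event_rate_prosp=0.03,
                       frailty_sd=1.5, event_visits_per_event=2, drift={}, seed=1)
    dev, _ = temporal_split(generate_cohort(cfg))
    assert _dispersion_pvalue(dev, rng) < 0.01


def test_event_rate_per_100k_requires_visits():
    with pytest.raises(ValueError):
        event_rate_per_100k(1, 0)
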