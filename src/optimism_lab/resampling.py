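"""Person-level partitioning and event-stratified person-level bootstrap.

Every validation scheme in this package resamples whole persons, never
individual visits: one event can mark several of a person's visits, so
visit-level resampling would split correlated rows across arms and
understate uncertainty. The bootstrap is additionally stratified by
event-person status so the (very small) event stratum keeps its exact size
in every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import rng_for

logger = logging.getLogger(__name__)


class EmptyStratumError(ValueError):
    """A required resampling stratum (event-persons or non-event-persons) is empty."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def person_event_status(table: pd.DataFrame) -> pd.Series:
    """person_id -> True if any of the person's visits carries an event."""
    return table.groupby("person_id", sort=True)["y"].any()


@dataclass
class PersonPartition:
    """Mapping person_id -> arm label ({'train','test'} or fold index)."""

    assignments: pd.Series  # index: person_id, values: arm label

    def __post_init__(self):
        if self.assignments.index.has_duplicates:
            raise ValueError("a person appears in more than one arm")

    @property
    def arms(self) -> list:
        return sorted(self.assignments.unique().tolist(), key=str)

    def persons(self, arm) -> np.ndarray:
        return self.assignments.index[self.assignments == arm].to_numpy()

    def select(self, table: pd.DataFrame, arm) -> pd.DataFrame:
        mask = table["person_id"].map(self.assignments) == arm
        return table[mask.to_numpy()].reset_index(drop=True)

    def select_not(self, table: pd.DataFrame, arm) -> pd.DataFrame:
        mask = table["person_id"].map(self.assignments) != arm
        return table[mask.to_numpy()].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.assignments.rename("arm").rename_axis("person_id").to_csv(path)


def split_persons(table: pd.DataFrame, fraction: float, seed) -> PersonPartition:
    """Assign round(fraction * n_persons) persons to 'train', the rest to
    'test'; all of a person's visits follow the person."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    status = person_event_status(table)
    persons = status.index.to_numpy()
    if persons.size < 2:
        raise ValueError("need at least 2 persons to split")
    rng = _as_rng(seed)
    n_train = int(round(fraction * persons.size))
    perm = rng.permutation(persons.size)
    arm = np.full(persons.size, "test", dtype=object)
    arm[perm[:n_train]] = "train"
    assignments = pd.Series(arm, index=persons)
    for label in ("train", "test"):
        if not status[assignments == label].any():
            logger.warning("split arm %r contains no event-persons", label)
    return PersonPartition(assignments)


def make_person_folds(table: pd.DataFrame, k: int, seed) -> PersonPartition:
    """k person-level folds, sizes within 1, event-persons balanced within 1.

    Persons are dealt round-robin in one continuous cycle, event-persons
    first, so both the total count and the event-person count differ by at
    most one between any two folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    status = person_event_status(table)
    persons = status.index.to_numpy()
    if persons.size < k:
        raise ValueError(f"need at least k={k} persons, got {persons.size}")
    rng = _as_rng(seed)
    event_persons = rng.permutation(persons[status.to_numpy()])
    other_persons = rng.permutation(persons[~status.to_numpy()])
    if event_persons.size == 0:
        logger.warning("no event-persons; folds will contain zero events")
    fold_order = rng.permutation(k)
    dealt = np.concatenate([event_persons, other_persons])
    labels = fold_order[np.arange(dealt.size) % k]
    assignments = pd.Series(labels, index=dealt).sort_index()
    if event_persons.size and event_persons.size < k:
        logger.warning("fewer event-persons (%d) than folds (%d); some folds have no events",
                       event_persons.size, k)
    return PersonPartition(assignments)


class PersonResampler:
    """Cached structure for repeated event-stratified person bootstrap draws.

    Build once per table; each :meth:`draw_rows` is then a vectorized
    ragged gather, which keeps bootstrap confidence-interval loops cheap.
    """

    def __init__(self, person_ids, event_flags):
        person_ids = np.asarray(person_ids)
        event_flags = np.asarray(event_flags, dtype=bool)
        codes, uniques = pd.factorize(person_ids)  # order of first appearance
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        self.person_labels = np.asarray(uniques)
        self.n_persons = len(uniques)
        self.row_order = order
        self.starts = np.searchsorted(sorted_codes, np.arange(self.n_persons))
        counts = np.bincount(codes, minlength=self.n_persons)
        self.counts = counts
        person_event = np.zeros(self.n_persons, dtype=bool)
        np.logical_or.at(person_event, codes, event_flags)
        self.person_event = person_event
        self.event_codes = np.flatnonzero(person_event)
        self.nonevent_codes = np.flatnonzero(~person_event)

    def draw_person_codes(self, rng: np.random.Generator) -> np.ndarray:
        """With-replacement stratum-preserving draw of person codes."""
        if self.event_codes.size == 0 or self.nonevent_codes.size == 0:
            raise EmptyStratumError(
                f"both strata must be non-empty (event persons: {self.event_codes.size}, "
                f"non-event persons: {self.nonevent_codes.size})"
            )
        ev = self.event_codes[rng.integers(0, self.event_codes.size, self.event_codes.size)]
        ne = self.nonevent_codes[rng.integers(0, self.nonevent_codes.size, self.nonevent_codes.size)]
        return np.concatenate([ev, ne])

    def draw_rows(self, rng: np.random.Generator):
        """Returns (row_indices, sampled_person_codes, visits_per_draw)."""
        codes = self.draw_person_codes(rng)
        counts = self.counts[codes]
        total = int(counts.sum())
        offsets = np.cumsum(counts) - counts
        within = np.arange(total) - np.repeat(offsets, counts)
        rows_sorted = np.repeat(self.starts[codes], counts) + within
        return self.row_order[rows_sorted], codes, counts


@dataclass
class BootstrapSample:
    """One event-stratified person-level bootstrap replicate.

    ``table`` carries all visits of every sampled person, once per draw,
    with replicate-disambiguated person/visit ids; ``provenance`` maps each
    replicate person id back to the original person.
    """

    table: pd.DataFrame
    provenance: pd.DataFrame  # columns: replicate_person_id, original_person_id, stratum
    n_event_persons: int
    n_nonevent_persons: int

    @property
    def distinct_person_fraction(self) -> float:
        n_orig = self.n_event_persons + self.n_nonevent_persons
        return self.provenance["original_person_id"].nunique() / n_orig


def stratified_person_bootstrap(table: pd.DataFrame, seed) -> BootstrapSample:
    """Event-stratified person-level bootstrap of a visit table.

    Samples, with replacement, as many event-persons and non-event-persons
    as the original table holds; a person drawn m times contributes m
    independent replicates, each carrying all of the person's visits.
    """
    rng = _as_rng(seed)
    rs = PersonResampler(table["person_id"].to_numpy(), (table["y"] == 1).to_numpy())
    rows, codes, counts = rs.draw_rows(rng)
    new = table.iloc[rows].reset_index(drop=True)
    draw_idx = np.arange(codes.size)
    suffix = np.char.add("~r", np.char.zfill(draw_idx.astype(str), 5))
    orig_pid = rs.person_labels[codes].astype(str)
    rep_pid = np.char.add(orig_pid, suffix)
    new["person_id"] = np.repeat(rep_pid, counts)
    new["visit_id"] = np.char.add(new["visit_id"].to_numpy(str), np.repeat(suffix, counts))
    provenance = pd.DataFrame({
        "replicate_person_id": rep_pid,
        "original_person_id": orig_pid,
        "stratum": np.where(rs.person_event[codes], "event", "nonevent"),
    })
    return BootstrapSample(
        table=new,
        provenance=provenance,
        n_event_persons=rs.event_codes.size,
        n_nonevent_persons=rs.nonevent_codes.size,
    )
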