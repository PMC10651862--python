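"""Remapping analysis via pairwise rate-map similarity.

For each condition, every unordered pair of simultaneously recorded neurons
gets a similarity score (Pearson correlation of their rate maps over jointly
valid bins).  The *stability* of this similarity structure between two
conditions is the Pearson correlation of the two pair-similarity vectors:
high when the same cell pairs stay co-active (no remapping), near zero under
full remapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .behavior import TrialRecord
from .data_model import Session
from .maps import MapError, RateMap2D, map_similarity, rate_map_2d

MIN_SHARED_PAIRS = 10


class RemappingError(ValueError):
    pass


@dataclass
class PairSimilarityVector:
    condition: str
    pairs: list[tuple[str, str]]
    similarity: np.ndarray


@dataclass(frozen=True)
class StabilityScore:
    r: float
    n_pairs: int


def pair_similarity(maps: dict[str, RateMap2D], condition: str = "") -> PairSimilarityVector:
    """Rate-map similarity for every unordered pair of neurons."""
    ids = sorted(maps)
    if len(ids) < 2:
        raise RemappingError("need at least 2 neurons with valid maps")
    pairs, sims = [], []
    for a, b in combinations(ids, 2):
        try:
            s = map_similarity(maps[a], maps[b])
        except MapError:
            continue
        pairs.append((a, b))
        sims.append(s)
    if not pairs:
        raise RemappingError("no valid pairs")
    return PairSimilarityVector(condition=condition, pairs=pairs, similarity=np.array(sims))


def stability(vec_a: PairSimilarityVector, vec_b: PairSimilarityVector) -> StabilityScore:
    """Pearson correlation of pair similarities over pairs defined in both
    conditions; requires at least 10 shared pairs."""
    index_b = {p: i for i, p in enumerate(vec_b.pairs)}
    shared = [(i, index_b[p]) for i, p in enumerate(vec_a.pairs) if p in index_b]
    if len(shared) < MIN_SHARED_PAIRS:
        raise RemappingError(f"only {len(shared)} shared pairs (need {MIN_SHARED_PAIRS})")
    ia, ib = zip(*shared)
    va = vec_a.similarity[list(ia)]
    vb = vec_b.similarity[list(ib)]
    return StabilityScore(r=float(np.corrcoef(va, vb)[0, 1]), n_pairs=len(shared))


@dataclass
class ConditionSubset:
    """A labeled set of time intervals within a session."""

    label: str
    intervals: list[tuple[float, float]]

    @property
    def empty(self) -> bool:
        return not self.intervals


def condition_partition(
    session: Session,
    trials: Sequence[TrialRecord],
    foraging_interval: Optional[tuple[float, float]] = None,
) -> dict[str, ConditionSubset]:
    """Label the data subsets used in remapping comparisons.

    RF1/RF2 are the temporal halves of an optional random-foraging epoch;
    A1/A2 are odd/even task trials; SL/SD/HL/HD are search/homing intervals
    of light/dark trials, each also split odd/even (SL1/SL2, ...).  Odd/even
    rather than first/second half decouples the split from slow drift.
    """
    subsets: dict[str, ConditionSubset] = {}
    if foraging_interval is not None:
        t0, t1 = foraging_interval
        mid = 0.5 * (t0 + t1)
        subsets["RF"] = ConditionSubset("RF", [(t0, t1)])
        subsets["RF1"] = ConditionSubset("RF1", [(t0, mid)])
        subsets["RF2"] = ConditionSubset("RF2", [(mid, t1)])
    usable = [tr for tr in trials if not tr.excluded]
    subsets["AutoPI"] = ConditionSubset("AutoPI", [(tr.t_open, tr.t_close) for tr in usable])
    subsets["A1"] = ConditionSubset("A1", [(tr.t_open, tr.t_close) for tr in usable[0::2]])
    subsets["A2"] = ConditionSubset("A2", [(tr.t_open, tr.t_close) for tr in usable[1::2]])
    for label, light, phase in (
        ("SL", True, "search"),
        ("SD", False, "search"),
        ("HL", True, "homing"),
        ("HD", False, "homing"),
    ):
        ivals = []
        for tr in usable:
            if tr.light != light:
                continue
            for j in tr.journeys:
                iv = j.search_interval if phase == "search" else j.homing_interval
                if j.lever_pressed and iv is not None:
                    ivals.append(iv)
        subsets[label] = ConditionSubset(label, ivals)
        subsets[f"{label}1"] = ConditionSubset(f"{label}1", ivals[0::2])
        subsets[f"{label}2"] = ConditionSubset(f"{label}2", ivals[1::2])
    return subsets


def condition_maps(
    session: Session,
    subset: ConditionSubset,
    bin_size: float = 3.0,
    smoothing_sd: float = 5.0,
    zone: Optional[tuple[float, float, float, float]] = None,
    min_rate: float = 0.0,
) -> dict[str, RateMap2D]:
    """Rate maps per neuron restricted to a condition subset.

    ``zone`` = (x_min, x_max, y_min, y_max) optionally restricts maps to a
    region (e.g. the rectangle between the bridge and the arena center).
    Neurons whose within-condition mean rate is below ``min_rate`` are
    dropped.
    """
    if subset.empty:
        raise RemappingError(f"condition {subset.label!r} is empty")
    pos = session.positions
    mask = np.zeros(len(pos), dtype=bool)
    t = pos["t"].to_numpy(float)
    for t0, t1 in subset.intervals:
        mask |= (t >= t0) & (t <= t1)
    if zone is not None:
        x = pos["x"].to_numpy(float)
        y = pos["y"].to_numpy(float)
        mask &= (x >= zone[0]) & (x <= zone[1]) & (y >= zone[2]) & (y <= zone[3])
    sel = pos.loc[mask]
    if len(sel) < 10:
        raise RemappingError(f"condition {subset.label!r} has too few samples")
    total_time = len(sel) / session.sample_rate
    ext = session.geometry.arena_radius + bin_size
    maps = {}
    for st in session.spikes:
        times = st.spike_times
        in_cond = np.zeros(times.size, dtype=bool)
        for t0, t1 in subset.intervals:
            in_cond |= (times >= t0) & (times <= t1)
        if total_time > 0 and in_cond.sum() / total_time < min_rate:
            continue
        try:
            maps[st.neuron_id] = rate_map_2d(
                sel, times[in_cond], bin_size=bin_size, smoothing_sd=smoothing_sd,
                extent=ext,
            )
        except MapError:
            continue
    return maps
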