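"""Trial and journey segmentation plus behavioral path metrics.

A *trial* runs from a door-open to the matching door-close event.  A *journey*
is one excursion from the bridge onto the arena and back.  Journeys with a
lever press are divided into a search path (arena entry until the animal is
within 10 cm of the lever-box wall), an at-lever interval, and a homing path
(leaving the 10 cm zone after the press until within 3 cm of the arena edge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .circular import angle_from_south, mean_vector_length, wrap_degrees
from .data_model import (
    ArenaGeometry,
    LeverPose,
    Session,
    dwell_times,
    lever_wall_distance,
)


class SegmentationError(ValueError):
    pass


@dataclass
class Journey:
    """One bridge->arena->bridge excursion."""

    t_start: float
    t_end: float
    lever_pressed: bool = False
    search_interval: Optional[tuple[float, float]] = None
    at_lever_interval: Optional[tuple[float, float]] = None
    homing_interval: Optional[tuple[float, float]] = None
    periphery_arrival: Optional[tuple[float, float]] = None
    incomplete: bool = False


@dataclass
class TrialRecord:
    trial_id: int
    t_open: float
    t_close: float
    light: bool
    lever_pose: LeverPose
    excluded: bool = False
    journeys: list[Journey] = field(default_factory=list)


@dataclass(frozen=True)
class PathMetrics:
    length: float  # cm
    duration: float  # s
    mean_speed: float  # cm/s
    complexity: float  # ln((1 - MVL) * 100)


@dataclass(frozen=True)
class HomingResult:
    homing_direction: float  # deg, signed, at the lever-box center
    error_at_periphery: float  # deg, absolute, in [0, 180]


# Bridge-occupancy rule: the animal is on the bridge when it is more than
# 2 cm beyond the arena edge on the bridge side.
_BRIDGE_MARGIN = 2.0
# MVL cap so perfectly straight paths get a finite complexity floor.
_MVL_CAP = 0.999


def _on_bridge(y: np.ndarray, geometry: ArenaGeometry) -> np.ndarray:
    return y < -(geometry.arena_radius + _BRIDGE_MARGIN)


def segment_trials(session: Session) -> list[TrialRecord]:
    """One TrialRecord per door_open/door_close pair.

    The light flag is the state of the light events at door opening; trials
    whose lever center lies beyond 75% of the arena radius are flagged
    excluded.  Journeys are filled in by :func:`segment_journeys`.
    """
    ev = session.events
    opens = ev.loc[ev["kind"] == "door_open", "t"].to_numpy(float)
    closes = ev.loc[ev["kind"] == "door_close", "t"].to_numpy(float)
    if opens.size != closes.size:
        extra = opens[closes.size:] if opens.size > closes.size else closes[opens.size:]
        raise SegmentationError(
            f"unpaired door events at t={np.round(extra, 3).tolist()}"
        )
    lights = ev.loc[ev["kind"].isin(["light_on", "light_off"])]
    trials = []
    for i, (t0, t1) in enumerate(zip(opens, closes)):
        if not t1 > t0 or (i + 1 < opens.size and opens[i + 1] < t1):
            raise SegmentationError(f"door events not properly nested at t={t0}")
        before = lights[lights["t"] <= t0]
        light = True if before.empty else before["kind"].iloc[-1] == "light_on"
        pose = session.lever_pose_at(0.5 * (t0 + min(t1, t0 + 1.0)))
        r = math.hypot(*pose.center)
        trials.append(
            TrialRecord(
                trial_id=i,
                t_open=t0,
                t_close=t1,
                light=light,
                lever_pose=pose,
                excluded=r > session.geometry.lever_center_max_radius,
            )
        )
    return trials


def segment_journeys(trial: TrialRecord, session: Session) -> list[Journey]:
    """Split one trial into journeys and their search/at-lever/homing parts."""
    geom = session.geometry
    pos = session.positions
    m = (pos["t"] >= trial.t_open) & (pos["t"] <= trial.t_close)
    t = pos.loc[m, "t"].to_numpy(float)
    x = pos.loc[m, "x"].to_numpy(float)
    y = pos.loc[m, "y"].to_numpy(float)
    if t.size == 0:
        raise SegmentationError(f"no position samples in trial {trial.trial_id}")
    on_arena = ~_on_bridge(y, geom)
    # maximal runs of arena occupancy
    edges = np.flatnonzero(np.diff(on_arena.astype(int)))
    starts = [0] if on_arena[0] else []
    starts += [e + 1 for e in edges if on_arena[e + 1]]
    ends = [e for e in edges if on_arena[e]]
    if on_arena[-1]:
        ends.append(t.size - 1)
    presses = session.events.loc[
        (session.events["kind"] == "lever_press")
        & (session.events["t"] >= trial.t_open)
        & (session.events["t"] <= trial.t_close),
        "t",
    ].to_numpy(float)
    wall = lever_wall_distance(x, y, trial.lever_pose, geom)
    radial = np.hypot(x, y)
    r_periph = geom.arena_radius - geom.periphery_threshold
    journeys = []
    for s_idx, e_idx in zip(starts, ends):
        j = Journey(t_start=float(t[s_idx]), t_end=float(t[e_idx]))
        j.lever_pressed = bool(np.any((presses >= j.t_start) & (presses <= j.t_end)))
        sl = slice(s_idx, e_idx + 1)
        near = np.flatnonzero(wall[sl] < geom.lever_proximity_threshold) + s_idx
        if near.size:
            first_near = near[0]
            j.search_interval = (float(t[s_idx]), float(t[first_near]))
        if j.lever_pressed:
            t_press = float(presses[(presses >= j.t_start) & (presses <= j.t_end)][0])
            after = np.flatnonzero(
                (t >= t_press) & (wall >= geom.lever_proximity_threshold)
            )
            after = after[(after >= s_idx) & (after <= e_idx)]
            if near.size and after.size:
                leave = after[0]
                j.at_lever_interval = (float(t[near[0]]), float(t[leave]))
                arr = np.flatnonzero(radial >= r_periph)
                arr = arr[(arr >= leave) & (arr <= e_idx)]
                if arr.size:
                    k = arr[0]
                    j.homing_interval = (float(t[leave]), float(t[k]))
                    j.periphery_arrival = (float(x[k]), float(y[k]))
                else:
                    j.incomplete = True
            else:
                j.incomplete = True
        journeys.append(j)
    trial.journeys = journeys
    return journeys


def positions_in(session: Session, interval: tuple[float, float]) -> pd.DataFrame:
    t0, t1 = interval
    m = (session.positions["t"] >= t0) & (session.positions["t"] <= t1)
    return session.positions.loc[m]


def path_metrics(positions: pd.DataFrame) -> PathMetrics:
    """Length, duration, mean speed, and complexity of a path.

    Complexity is ln((1 - MVL) * 100) where MVL is the mean vector length of
    the unit movement-direction vectors between consecutive samples; MVL is
    capped at 0.999 so perfectly straight paths stay finite.
    """
    if len(positions) < 3:
        raise SegmentationError("path_metrics needs at least 3 samples")
    t = positions["t"].to_numpy(float)
    x = positions["x"].to_numpy(float)
    y = positions["y"].to_numpy(float)
    dx, dy = np.diff(x), np.diff(y)
    steps = np.hypot(dx, dy)
    length = float(steps.sum())
    duration = float(t[-1] - t[0])
    moving = steps > 0
    if np.any(moving):
        angles = np.degrees(np.arctan2(dy[moving], dx[moving]))
        mvl = mean_vector_length(angles)
    else:
        mvl = 0.0
    complexity = path_complexity(mvl)
    return PathMetrics(
        length=length,
        duration=duration,
        mean_speed=length / duration if duration > 0 else 0.0,
        complexity=complexity,
    )


def path_complexity(mvl: float) -> float:
    """ln((1 - MVL) * 100), with MVL capped at 0.999."""
    return float(np.log((1.0 - min(mvl, _MVL_CAP)) * 100.0))


def homing_geometry(
    journey: Journey, trial: TrialRecord, geometry: ArenaGeometry
) -> HomingResult:
    """Homing direction at the lever box and absolute error at the periphery.

    The homing direction is the signed angle between the vector from the
    lever-box center to the bridge and the vector from the lever-box center to
    the periphery-arrival point.  The error at the periphery is the absolute
    angle, at the arena center, between the arrival point and the bridge
    center (uniform arrivals average 90 degrees).
    """
    if journey.periphery_arrival is None:
        raise SegmentationError("journey has no periphery arrival")
    ax, ay = journey.periphery_arrival
    cx, cy = trial.lever_pose.center
    bx, by = geometry.bridge_center
    direction = wrap_degrees(
        angle_from_south(ax - cx, ay - cy) - angle_from_south(bx - cx, by - cy)
    )
    err = abs(wrap_degrees(angle_from_south(ax, ay) - angle_from_south(bx, by)))
    return HomingResult(homing_direction=float(direction), error_at_periphery=float(err))


def split_trials_by_median(trials: Sequence, scores: Sequence[float]):
    """Partition trials at the within-session median of ``scores``.

    Deterministic tie policy: after a stable sort on score the first
    ceil(n/2) trials form the low group, so the median element goes low and
    group sizes differ by at most 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise SegmentationError("need at least 2 scored trials")
    if np.all(scores == scores[0]):
        raise SegmentationError("median split undefined: all scores identical")
    order = np.argsort(scores, kind="stable")
    n_low = int(math.ceil(scores.size / 2))
    low_idx = set(order[:n_low].tolist())
    low = [trials[i] for i in range(len(trials)) if i in low_idx]
    high = [trials[i] for i in range(len(trials)) if i not in low_idx]
    return low, high


def trial_path_features(session: Session, trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-trial feature table for the light/dark classifier.

    For each non-excluded trial with a complete lever-pressed journey:
    length, duration, mean speed and complexity of the search and homing
    paths (8 features), plus the light label and homing geometry.
    """
    rows = []
    for tr in trials:
        if tr.excluded:
            continue
        for j in tr.journeys:
            if not (j.lever_pressed and j.search_interval and j.homing_interval):
                continue
            sp = positions_in(session, j.search_interval)
            hp = positions_in(session, j.homing_interval)
            if len(sp) < 3 or len(hp) < 3:
                continue
            sm = path_metrics(sp)
            hm = path_metrics(hp)
            res = homing_geometry(j, tr, session.geometry)
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "light": tr.light,
                    "search_length": sm.length,
                    "search_duration": sm.duration,
                    "search_speed": sm.mean_speed,
                    "search_complexity": sm.complexity,
                    "homing_length": hm.length,
                    "homing_duration": hm.duration,
                    "homing_speed": hm.mean_speed,
                    "homing_complexity": hm.complexity,
                    "homing_direction": res.homing_direction,
                    "error_at_periphery": res.error_at_periphery,
                }
            )
            break  # one pressed journey per trial
    return pd.DataFrame(rows)


_FEATURES = [
    "search_length",
    "search_duration",
    "search_speed",
    "search_complexity",
    "homing_length",
    "homing_duration",
    "homing_speed",
    "homing_complexity",
]


def light_dark_classifier(
    features: pd.DataFrame, labels: Sequence[bool], seed: int = 0, n_folds: int = 10
) -> tuple[float, float]:
    """Cross-validated accuracy of a linear max-margin classifier predicting
    the light condition from the 8 search/homing path features.

    Returns (mean, SD) of stratified ``n_folds``-fold accuracies.  Features
    are standardized inside each fold.
    """
    X = features[_FEATURES].to_numpy(float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    yv = np.asarray(labels, dtype=int)
    if X.shape[0] < 20:
        raise SegmentationError("need at least 20 labeled trials")
    if len(np.unique(yv)) < 2:
        raise SegmentationError("both classes must be present")
    clf = make_pipeline(StandardScaler(), LinearSVC())
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, X, yv, cv=cv)
    return float(scores.mean()), float(scores.std())
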