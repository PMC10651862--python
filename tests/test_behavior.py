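import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homefield.behavior import (
    HomingResult,
    Journey,
    SegmentationError,
    TrialRecord,
    homing_geometry,
    light_dark_classifier,
    path_complexity,
    path_metrics,
    positions_in,
    segment_journeys,
    segment_trials,
    split_trials_by_median,
    trial_path_features,
)
from homefield.data_model import ArenaGeometry, LeverPose


def make_path(xy, dt=0.02):
    xy = np.asarray(xy, float)
    return pd.DataFrame({"t": np.arange(len(xy)) * dt, "x": xy[:, 0], "y": xy[:, 1]})


# -- segmentation --------------------------------------------------------------

def test_segment_trials_counts_and_lights(small_session, small_trials):
    assert len(small_trials) == 20
    assert [tr.trial_id for tr in small_trials] == list(range(20))


def test_unpaired_door_events_raise(small_session):
    session, _ = small_session
    ev = session.events
    dropped = ev.drop(ev.index[ev["kind"] == "door_close"][-1]).reset_index(drop=True)
    bad = dataclasses.replace(session, events=dropped) if dataclasses.is_dataclass(session) else None
    session2 = type(session)(
        geometry=session.geometry, positions=session.positions, spikes=session.spikes,
        events=dropped, lever_poses=session.lever_poses, sample_rate=session.sample_rate,
    )
    with pytest.raises(SegmentationError, match="unpaired"):
        segment_trials(session2)


def test_far_lever_trial_flagged_excluded(small_session):
    session, _ = small_session
    trials = segment_trials(session)
    far_pose = LeverPose(trials[4].lever_pose.t_start, trials[4].lever_pose.t_end,
                         center=(31.0, 0.0), lever_direction=(0.0, 1.0))
    record = TrialRecord(4, trials[4].t_open, trials[4].t_close, trials[4].light,
                         far_pose, excluded=np.hypot(31.0, 0.0) > session.geometry.lever_center_max_radius)
    assert record.excluded


def test_journeys_have_ordered_phases(small_session, small_trials):
    session, _ = small_session
    for tr in small_trials:
        for j in tr.journeys:
            assert tr.t_open <= j.t_start <= j.t_end <= tr.t_close
            if j.lever_pressed and not j.incomplete:
                s0, s1 = j.search_interval
                a0, a1 = j.at_lever_interval
                h0, h1 = j.homing_interval
                assert s0 <= s1 == a0 <= a1 == h0 <= h1
                assert j.periphery_arrival is not None
                r = np.hypot(*j.periphery_arrival)
                assert r >= session.geometry.arena_radius - session.geometry.periphery_threshold


def test_journey_durations_fit_in_trial(small_session, small_trials):
    for tr in small_trials:
        total = sum(j.t_end - j.t_start for j in tr.journeys)
        assert total <= (tr.t_close - tr.t_open) + 1e-9


# -- path metrics --------------------------------------------------------------

def test_straight_path_complexity_floor():
    path = make_path([(i, 0.0) for i in range(50)])
    m = path_metrics(path)
    assert m.complexity == pytest.approx(np.log((1 - 0.999) * 100), abs=1e-9)
    assert m.length == pytest.approx(49.0)
    assert m.mean_speed == pytest.approx(m.length / m.duration)


def test_semicircular_direction_spread_complexity():
    dirs = np.radians(np.linspace(-90, 90, 5000))
    xy = np.cumsum(np.column_stack([np.cos(dirs), np.sin(dirs)]), axis=0)
    xy = np.vstack([[0.0, 0.0], xy])
    m = path_metrics(make_path(xy))
    assert m.complexity == pytest.approx(np.log((1 - 2 / np.pi) * 100), abs=0.01)


def test_uniform_direction_complexity_approaches_ln100():
    dirs = np.radians(np.linspace(0, 360, 7200, endpoint=False))
    xy = np.cumsum(np.column_stack([np.cos(dirs), np.sin(dirs)]), axis=0)
    m = path_metrics(make_path(np.vstack([[0, 0], xy])))
    assert m.complexity == pytest.approx(np.log(100.0), abs=0.01)


def test_path_metrics_needs_three_samples():
    with pytest.raises(SegmentationError):
        path_metrics(make_path([(0, 0), (1, 1)]))


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 10_000), st.floats(-180, 180), st.floats(-30, 30), st.floats(-30, 30))
def test_complexity_invariant_under_rigid_motion(seed, angle, dx, dy):
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(0, 1, (30, 2)), axis=0)
    th = np.radians(angle)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved = xy @ rot.T + [dx, dy]
    c0 = path_metrics(make_path(xy)).complexity
    c1 = path_metrics(make_path(moved)).complexity
    assert c0 == pytest.approx(c1, abs=1e-9)


def test_complexity_strictly_decreasing_in_mvl():
    mvls = np.linspace(0, 0.99, 50)
    comps = [path_complexity(m) for m in mvls]
    assert all(a > b for a, b in zip(comps, comps[1:]))


# -- homing geometry -----------------------------------------------------------

def _journey_at(x, y):
    return Journey(0.0, 1.0, lever_pressed=True, periphery_arrival=(x, y))


def _trial(lever_center=(5.0, 5.0)):
    return TrialRecord(0, 0.0, 1.0, light=False,
                       lever_pose=LeverPose(0, 1, lever_center, (1.0, 0.0)))


def test_arrival_at_bridge_gives_zero_error():
    geom = ArenaGeometry()
    # lever on the bridge axis: lever->bridge and lever->arrival colinear
    res = homing_geometry(_journey_at(0.0, -38.0), _trial((0.0, 10.0)), geom)
    assert res.homing_direction == pytest.approx(0.0, abs=1e-9)
    assert res.error_at_periphery == pytest.approx(0.0, abs=1e-9)
    # the error at the periphery is lever-independent
    res2 = homing_geometry(_journey_at(0.0, -38.0), _trial((5.0, 5.0)), geom)
    assert res2.error_at_periphery == pytest.approx(0.0, abs=1e-9)


def test_arrival_opposite_bridge_gives_180():
    geom = ArenaGeometry()
    res = homing_geometry(_journey_at(0.0, 38.0), _trial((0.0, 10.0)), geom)
    assert res.error_at_periphery == pytest.approx(180.0)


def test_uniform_arrivals_average_90_degrees():
    geom = ArenaGeometry()
    trial = _trial()
    angles = np.linspace(-np.pi, np.pi, 3600, endpoint=False)
    errs = [
        homing_geometry(_journey_at(38 * np.cos(a), 38 * np.sin(a)), trial, geom).error_at_periphery
        for a in angles
    ]
    assert np.mean(errs) == pytest.approx(90.0, abs=0.1)


def test_missing_arrival_raises():
    with pytest.raises(SegmentationError):
        homing_geometry(Journey(0, 1, lever_pressed=True), _trial(), ArenaGeometry())


# -- median split --------------------------------------------------------------

def test_median_split_even_and_odd():
    low, high = split_trials_by_median(list(range(10)), list(range(1, 11)))
    assert low == [0, 1, 2, 3, 4] and high == [5, 6, 7, 8, 9]
    low, high = split_trials_by_median(list(range(11)), list(range(11)))
    assert len(low) == 6 and len(high) == 5  # median element goes low


def test_median_split_identical_scores_error():
    with pytest.raises(SegmentationError):
        split_trials_by_median([1, 2, 3], [5.0, 5.0, 5.0])


def test_high_search_group_has_larger_homing_error():
    from homefield.synthetic import BehaviorSpec, generate_session

    session, _ = generate_session(BehaviorSpec(n_trials=120), {}, seed=31)
    trials = segment_trials(session)
    for tr in trials:
        segment_journeys(tr, session)
    feats = trial_path_features(session, trials)
    dark = feats[~feats["light"]].reset_index(drop=True)
    low, high = split_trials_by_median(list(dark.index), dark["search_length"].tolist())
    assert dark.loc[high, "error_at_periphery"].mean() > dark.loc[low, "error_at_periphery"].mean()


# -- light/dark classifier -----------------------------------------------------

@pytest.fixture(scope="module")
def classifier_features():
    from homefield.synthetic import BehaviorSpec, generate_session

    session, _ = generate_session(BehaviorSpec(n_trials=40), {}, seed=71)
    trials = segment_trials(session)
    for tr in trials:
        segment_journeys(tr, session)
    return trial_path_features(session, trials)


def test_classifier_separates_light_dark(classifier_features):
    feats = classifier_features
    acc, sd = light_dark_classifier(feats, feats["light"], seed=0, n_folds=5)
    assert acc > 0.9


def test_classifier_at_chance_on_shuffled_labels(classifier_features):
    feats = classifier_features
    rng = np.random.default_rng(7)
    accs = []
    for s in range(5):
        acc, _ = light_dark_classifier(
            feats, rng.permutation(feats["light"].to_numpy()), seed=s, n_folds=5
        )
        accs.append(acc)
    assert 0.2 < np.mean(accs) < 0.8


def test_classifier_guards():
    X = pd.DataFrame(np.ones((10, 8)), columns=[
        "search_length", "search_duration", "search_speed", "search_complexity",
        "homing_length", "homing_duration", "homing_speed", "homing_complexity"])
    with pytest.raises(SegmentationError):
        light_dark_classifier(X, [True] * 10)
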