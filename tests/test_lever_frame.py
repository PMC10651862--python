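import numpy as np
import pandas as pd
import pytest

from homefield.circular import circular_correlation, wrap_degrees
from homefield.data_model import ArenaGeometry, LeverPose
from homefield.lever_frame import (
    DriftResult,
    LeverFrameData,
    LeverFrameError,
    classify_lever_anchored,
    collect_lever_frame,
    directional_tuning,
    drift_homing_coupling,
    preferred_direction_split_test,
    to_lever_frame,
    trial_drift,
)
from homefield.trial_matrix import TrialMatrix, build_trial_matrix
from conftest import spike_train

GEOM = ArenaGeometry()


def frame_data(directions, dwell=None, spike_directions=()):
    directions = np.asarray(directions, float)
    n = directions.size
    return LeverFrameData(
        frame="cardinal",
        x=np.zeros(n), y=np.zeros(n),
        direction=directions,
        wall_distance=np.full(n, 3.0),
        dwell=np.full(n, 0.02) if dwell is None else np.asarray(dwell, float),
        spike_x=np.zeros(len(spike_directions)), spike_y=np.zeros(len(spike_directions)),
        spike_direction=np.asarray(spike_directions, float),
    )


def positions_df(points, dt=0.02):
    pts = np.asarray(points, float)
    return pd.DataFrame({"t": np.arange(len(pts)) * dt, "x": pts[:, 0], "y": pts[:, 1]})


# -- reference frames ----------------------------------------------------------

def test_cardinal_direction_south_of_lever_is_zero():
    pose = LeverPose(0, 10, (5.0, 5.0), (1.0, 0.0))
    pos = positions_df([(5.0, 5.0 - r) for r in np.linspace(8, 10, 20)])
    data = to_lever_frame(pos, pose, GEOM, "cardinal")
    assert np.allclose(data.direction, 0.0, atol=1e-9)


def test_bridge_frame_equals_cardinal_for_lever_on_axis():
    """With the lever on the bridge-center axis the lever->bridge vector
    points south, so the bridge rotation is zero."""
    pose = LeverPose(0, 10, (0.0, 10.0), (1.0, 0.0))
    pos = positions_df([(0.0 + 9 * np.sin(a), 10.0 - 9 * np.cos(a)) for a in np.linspace(0, 3, 30)])
    d_card = to_lever_frame(pos, pose, GEOM, "cardinal").direction
    d_bridge = to_lever_frame(pos, pose, GEOM, "bridge").direction
    np.testing.assert_allclose(d_card, d_bridge, atol=1e-9)


def test_lever_frame_equals_cardinal_for_south_pointing_lever():
    pose = LeverPose(0, 10, (5.0, 5.0), (0.0, -1.0))
    pos = positions_df([(5.0 + 9 * np.sin(a), 5.0 - 9 * np.cos(a)) for a in np.linspace(0, 3, 30)])
    d_card = to_lever_frame(pos, pose, GEOM, "cardinal").direction
    d_lever = to_lever_frame(pos, pose, GEOM, "lever").direction
    np.testing.assert_allclose(d_card, d_lever, atol=1e-9)


def test_samples_beyond_12cm_excluded():
    pose = LeverPose(0, 10, (0.0, 0.0), (1.0, 0.0))
    pos = positions_df([(0.0, -5.0), (0.0, -25.0), (0.0, -6.0)])
    data = to_lever_frame(pos, pose, GEOM, "cardinal")
    assert data.direction.size == 2


# -- directional tuning --------------------------------------------------------

def test_delta_tuning_high_mvl():
    occ = np.repeat(np.linspace(-175, 175, 36), 50)  # uniform occupancy
    spikes = np.full(400, 5.0)  # all spikes in one bin
    t = directional_tuning(frame_data(occ, spike_directions=spikes))
    assert t.mvl >= 0.95
    assert abs(t.preferred_direction - 5.0) <= 10.0


def test_antipodal_tuning_mvl_zero():
    occ = np.repeat(np.linspace(-175, 175, 36), 50)
    spikes = np.concatenate([np.full(200, 5.0), np.full(200, -175.0)])
    t = directional_tuning(frame_data(occ, spike_directions=spikes))
    assert t.mvl == pytest.approx(0.0, abs=0.05)


def test_orthogonal_two_bin_tuning():
    occ = np.repeat(np.linspace(-175, 175, 36), 200)
    spikes = np.concatenate([np.full(300, 5.0), np.full(300, 95.0)])
    t = directional_tuning(frame_data(occ, spike_directions=spikes), smoothing_sd_bins=0.0)
    assert t.mvl == pytest.approx(np.sqrt(2) / 2, abs=0.03)


def test_uniform_tuning_mvl_zero():
    occ = np.repeat(np.linspace(-175, 175, 36), 100)
    rng = np.random.default_rng(0)
    spikes = rng.uniform(-180, 180, 3000)
    t = directional_tuning(frame_data(occ, spike_directions=spikes))
    assert t.mvl < 0.05


def test_zero_occupancy_errors():
    with pytest.raises(LeverFrameError):
        directional_tuning(frame_data(np.array([]), dwell=np.array([])))


# -- trial drift ---------------------------------------------------------------

def drift_matrix(rows, bin_width=10.0):
    rows = np.asarray(rows, float)
    n, b = rows.shape
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    meta = pd.DataFrame({"trial_id": np.arange(n), "lever_y": np.zeros(n),
                         "homing_direction": np.zeros(n), "light": [False] * n})
    return TrialMatrix("lever_direction", edges, rows, rows, meta)


def template(n_bins=36, width=3.0):
    i = np.arange(n_bins)
    d = np.minimum(i, n_bins - i)
    return np.exp(-(d**2) / (2 * width**2)) * 10.0


def test_unshifted_rows_have_zero_drift():
    rows = np.tile(template(), (8, 1))
    res = trial_drift(drift_matrix(rows))
    np.testing.assert_allclose(res.delta_deg[res.usable], 0.0, atol=1e-9)


def test_constant_shift_recovered_exactly():
    base = template()
    rows = np.vstack([np.roll(base, 4) for _ in range(8)])  # +40 deg at 10 deg bins
    res = trial_drift(drift_matrix(rows), roll_bins=0)
    np.testing.assert_allclose(res.delta_deg[res.usable], 40.0, atol=1e-9)


def test_drift_equivariance_with_fixed_roll():
    """Adding a constant circular shift c to every row adds c to every drift
    when the global alignment is held fixed."""
    rng = np.random.default_rng(5)
    base = template()
    shifts = rng.integers(-5, 6, 10)
    rows = np.vstack([np.roll(base, s) for s in shifts])
    res0 = trial_drift(drift_matrix(rows), roll_bins=0)
    rows_c = np.vstack([np.roll(base, s + 3) for s in shifts])
    res1 = trial_drift(drift_matrix(rows_c), roll_bins=0)
    expected = wrap_degrees(res0.delta_deg[res0.usable] + 30.0)
    np.testing.assert_allclose(res1.delta_deg[res1.usable], expected, atol=1e-9)


def test_injected_drift_recovered_from_spikes(drift_session):
    session, truth, trials = drift_session
    mat = build_trial_matrix(session, trials, session.spikes[0].spike_times,
                             "lever_direction", phase="at_lever", bin_size=10.0)
    res = trial_drift(mat)
    injected = truth.drifts["la"][mat.row_meta["trial_id"].to_numpy()]
    ok = np.isfinite(res.delta_deg)
    assert circular_correlation(injected[ok], res.delta_deg[ok]) >= 0.85


def test_drift_needs_five_rows():
    with pytest.raises(LeverFrameError):
        trial_drift(drift_matrix(np.tile(template(), (3, 1))))


# -- lever-anchored classification --------------------------------------------

def test_anchored_neuron_passes_all_criteria(drift_session):
    session, _, trials = drift_session
    res = classify_lever_anchored(session, trials, session.spikes[0].spike_times,
                                  n_shuffles=200, seed=0)
    assert res.anchored
    assert res.peak_distance_cm <= 10.0


def test_place_neuron_not_anchored(small_session, small_trials):
    session, _ = small_session
    res = classify_lever_anchored(session, small_trials, spike_train(session, "place"),
                                  n_shuffles=200, seed=0)
    assert not res.anchored


def test_rate_scaled_down_fails_peak_criterion(small_session, small_trials):
    """Thinning the spike train to ~40% scales all rates below the 7.5 Hz
    map-peak threshold."""
    session, _ = small_session
    st = spike_train(session, "anchored")
    rng = np.random.default_rng(0)
    thinned = np.sort(rng.choice(st, size=int(0.4 * st.size), replace=False))
    res = classify_lever_anchored(session, small_trials, thinned, n_shuffles=100, seed=0)
    assert not res.peak_rate_ok
    assert not res.anchored


def test_insufficient_journeys_error(small_session, small_trials):
    session, _ = small_session
    with pytest.raises(LeverFrameError):
        classify_lever_anchored(session, small_trials[:3], session.spikes[0].spike_times)


# -- drift-homing coupling -----------------------------------------------------

def test_identity_coupling():
    rng = np.random.default_rng(8)
    h = rng.uniform(-60, 60, 40)
    r, p, slope = drift_homing_coupling(h.copy(), h, n_shuffles=200, seed=0)
    assert r == pytest.approx(1.0)
    assert p < 0.01
    assert slope == pytest.approx(1.0, abs=1e-6)


def test_independent_drift_not_significant():
    rng = np.random.default_rng(9)
    d = rng.uniform(-90, 90, 40)
    h = rng.uniform(-90, 90, 40)
    r, p, _ = drift_homing_coupling(d, h, n_shuffles=200, seed=0)
    assert abs(r) < 0.35
    assert p > 0.05


def test_coupling_needs_ten_pairs():
    with pytest.raises(LeverFrameError):
        drift_homing_coupling(np.arange(5.0), np.arange(5.0))


def test_constant_drift_degenerate():
    with pytest.raises(ValueError):
        drift_homing_coupling(np.zeros(20), np.linspace(-50, 50, 20))


# -- preferred-direction split test -------------------------------------------

def test_identical_groups_zero_delta():
    rows = np.tile(template(), (12, 1))
    mat = drift_matrix(rows)
    homing = np.linspace(-40, 40, 12)
    delta, p = preferred_direction_split_test(mat, homing, n_shuffles=100, seed=0)
    assert delta == pytest.approx(0.0, abs=1e-9)


def test_coupled_groups_delta_matches_sign():
    base = template()
    homing = np.concatenate([np.full(8, -40.0), np.full(8, 40.0)])
    rows = np.vstack([np.roll(base, -3) for _ in range(8)]
                     + [np.roll(base, 3) for _ in range(8)])
    mat = drift_matrix(rows)
    delta, p = preferred_direction_split_test(mat, homing, n_shuffles=200, seed=0)
    assert delta > 30.0  # higher homing group rotated positively
    assert p < 0.05
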