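import dataclasses

import numpy as np
import pandas as pd
import pytest

from homefield.data_model import (
    ArenaGeometry,
    LeverPose,
    SessionLoadError,
    SessionValidationError,
    SpikeTrain,
    dwell_times,
    lever_wall_distance,
    read_session,
    rotate_session,
    write_session,
)


def test_roundtrip_identity(small_session, tmp_path):
    session, _ = small_session
    write_session(session, tmp_path / "s")
    loaded = read_session(tmp_path / "s")
    pd.testing.assert_frame_equal(loaded.positions, session.positions)
    pd.testing.assert_frame_equal(loaded.events, session.events)
    assert len(loaded.spikes) == len(session.spikes)
    for a, b in zip(
        sorted(loaded.spikes, key=lambda s: s.neuron_id),
        sorted(session.spikes, key=lambda s: s.neuron_id),
    ):
        assert a.neuron_id == b.neuron_id
        np.testing.assert_allclose(a.spike_times, b.spike_times)
    assert loaded.geometry == session.geometry
    assert [dataclasses.astuple(p) for p in loaded.lever_poses] == [
        dataclasses.astuple(p) for p in session.lever_poses
    ]


def test_write_is_deterministic(small_session, tmp_path):
    session, _ = small_session
    write_session(session, tmp_path / "a")
    write_session(session, tmp_path / "b")
    for name in ("positions.tsv", "events.tsv", "lever_poses.tsv", "geometry.yaml"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_empty_spike_list_roundtrip(small_session, tmp_path):
    session, _ = small_session
    bare = dataclasses.replace(session) if dataclasses.is_dataclass(session) else session
    bare = type(session)(
        geometry=session.geometry,
        positions=session.positions,
        spikes=[],
        events=session.events,
        lever_poses=session.lever_poses,
        sample_rate=session.sample_rate,
        metadata=session.metadata,
    )
    write_session(bare, tmp_path / "s")
    assert read_session(tmp_path / "s").spikes == []


def test_missing_events_component_errors(small_session, tmp_path):
    session, _ = small_session
    write_session(session, tmp_path / "s")
    (tmp_path / "s" / "events.tsv").unlink()
    with pytest.raises(SessionLoadError, match="events"):
        read_session(tmp_path / "s")


def test_lever_press_outside_epochs_rejected(small_session):
    session, _ = small_session
    bad_events = session.events.copy()
    last = session.lever_poses[-1].t_end
    bad_events = pd.concat(
        [bad_events, pd.DataFrame({"t": [last + 100.0], "kind": ["lever_press"], "payload": [""]})],
        ignore_index=True,
    )
    bad = type(session)(
        geometry=session.geometry,
        positions=session.positions,
        spikes=session.spikes,
        events=bad_events,
        lever_poses=session.lever_poses,
        sample_rate=session.sample_rate,
    )
    with pytest.raises(SessionValidationError, match="lever press"):
        bad.validate()


def test_geometry_invariants():
    with pytest.raises(SessionValidationError):
        ArenaGeometry(arena_radius=-1).validate()
    with pytest.raises(SessionValidationError):
        ArenaGeometry(bridge_center=(10.0, -45.0)).validate()
    ArenaGeometry(bridge_center=(10.0, -45.0)).validate(canonical=False)
    with pytest.raises(SessionValidationError):
        ArenaGeometry(lever_center_max_radius=20.0).validate()


def test_spike_train_must_be_sorted():
    with pytest.raises(SessionValidationError):
        SpikeTrain("n0", np.array([1.0, 0.5])).validate()


def test_dwell_time_cap_guards_dropouts():
    t = np.array([0.0, 0.02, 0.04, 2.0, 2.02])
    d = dwell_times(t)
    assert d[2] == pytest.approx(3 * 0.02)  # capped at 3x median gap
    assert d[0] == pytest.approx(0.02)


def test_lever_wall_distance_geometry():
    geom = ArenaGeometry()
    pose = LeverPose(0, 1, center=(0.0, 0.0), lever_direction=(1.0, 0.0))
    # on the long axis just beyond the box end wall
    assert lever_wall_distance(geom.lever_box_length / 2 + 3.0, 0.0, pose, geom) == pytest.approx(3.0)
    # inside the footprint
    assert lever_wall_distance(0.0, 0.0, pose, geom) == 0.0
    # across the short axis
    assert lever_wall_distance(0.0, geom.lever_box_width / 2 + 2.0, pose, geom) == pytest.approx(2.0)


def test_rotation_round_trip(small_session):
    session, _ = small_session
    back = rotate_session(rotate_session(session, 90.0), -90.0)
    np.testing.assert_allclose(
        back.positions[["x", "y"]].to_numpy(), session.positions[["x", "y"]].to_numpy(),
        atol=1e-9,
    )
    np.testing.assert_allclose(back.geometry.bridge_center, session.geometry.bridge_center, atol=1e-9)
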