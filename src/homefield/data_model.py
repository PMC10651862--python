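"""Shared domain types, coordinate conventions, and session container I/O.

Coordinate convention
---------------------
The arena is a circle centered at the origin.  The home-base bridge sits
outside the arena on the negative-y axis, so the unit vector (0, -1)
("south") points from the arena center toward the bridge.  All positions are
in cm, times in s, rates in Hz, angles in degrees in [-180, 180) with
counterclockwise positive.

Session container layout (one directory per session)
----------------------------------------------------
``positions.tsv``    t, x, y
``events.tsv``       t, kind, payload
``spikes/<id>.tsv``  t
``lever_poses.tsv``  t_start, t_end, cx, cy, dx, dy
``geometry.yaml``    ArenaGeometry fields
``metadata.yaml``    free-form mapping (animal id, date, condition flags)

All tables are UTF-8, tab-delimited, with a header row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

EVENT_KINDS = frozenset(
    {
        "door_open",
        "door_close",
        "lever_press",
        "magazine_beam",
        "light_on",
        "light_off",
        "arena_rotation",
    }
)


class SessionValidationError(ValueError):
    """A session component violates a documented invariant."""


class SessionLoadError(IOError):
    """A session container is missing a required component."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena, bridge and lever-related distances (cm).

    ``periphery_threshold`` is the distance from the arena *edge* within which
    the animal counts as having reached the periphery; the homing arrival
    point is the first sample with radial distance >= arena_radius -
    periphery_threshold.  ``lever_proximity_threshold`` is the distance from
    the lever-box wall defining "at the lever"; ``lever_frame_radius`` is the
    cut-off for lever-centered analyses.  Lever placements beyond
    ``lever_center_max_radius`` (75% of the arena radius) are excluded.
    """

    arena_radius: float = 40.0
    bridge_center: tuple[float, float] = (0.0, -45.0)
    periphery_threshold: float = 3.0
    lever_proximity_threshold: float = 10.0
    lever_frame_radius: float = 12.0
    lever_center_max_radius: float = 30.0
    # Lever-box footprint (cm); distances to the lever are measured to the
    # nearest point of this rectangle, not to its center.
    lever_box_length: float = 11.6
    lever_box_width: float = 8.2

    def validate(self, canonical: bool = True) -> None:
        if self.arena_radius <= 0:
            raise SessionValidationError("arena_radius must be positive")
        if not (
            0
            < self.periphery_threshold
            < self.lever_proximity_threshold
            < self.lever_frame_radius
            < self.arena_radius
        ):
            raise SessionValidationError(
                "expected 0 < periphery_threshold < lever_proximity_threshold"
                " < lever_frame_radius < arena_radius"
            )
        bx, by = self.bridge_center
        if math.hypot(bx, by) <= self.arena_radius:
            raise SessionValidationError("bridge_center must lie outside the arena")
        if canonical and not (abs(bx) < 1e-9 and by < 0):
            raise SessionValidationError(
                "canonical frame requires the bridge on the negative-y axis"
            )
        if not math.isclose(
            self.lever_center_max_radius, 0.75 * self.arena_radius, rel_tol=1e-9
        ):
            raise SessionValidationError(
                "lever_center_max_radius must equal 0.75 * arena_radius"
            )


@dataclass(frozen=True)
class SpikeTrain:
    neuron_id: str
    spike_times: np.ndarray  # s, non-decreasing

    def __post_init__(self):
        object.__setattr__(
            self, "spike_times", np.asarray(self.spike_times, dtype=float)
        )

    def validate(self) -> None:
        t = self.spike_times
        if t.ndim != 1:
            raise SessionValidationError(f"{self.neuron_id}: spike_times must be 1-D")
        if t.size and np.any(np.diff(t) < 0):
            raise SessionValidationError(
                f"{self.neuron_id}: spike_times must be non-decreasing"
            )


@dataclass(frozen=True)
class LeverPose:
    """Lever-box pose valid over a time interval.

    ``lever_direction`` is the unit vector from the box center toward the
    pressable lever part.
    """

    t_start: float
    t_end: float
    center: tuple[float, float]
    lever_direction: tuple[float, float]

    def validate(self) -> None:
        if not self.t_end > self.t_start:
            raise SessionValidationError("lever pose epoch must have t_end > t_start")
        norm = math.hypot(*self.lever_direction)
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise SessionValidationError("lever_direction must be a unit vector")

    def contains(self, t: float) -> bool:
        return self.t_start <= t <= self.t_end


@dataclass
class Session:
    """One recording session: positions, spike trains, events, lever poses."""

    geometry: ArenaGeometry
    positions: pd.DataFrame  # columns t, x, y
    spikes: list[SpikeTrain]
    events: pd.DataFrame  # columns t, kind, payload
    lever_poses: list[LeverPose]
    sample_rate: float = 50.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def validate(self, canonical: bool = True) -> "Session":
        self.geometry.validate(canonical=canonical)
        for name in ("positions", "events"):
            df = getattr(self, name)
            if df is None:
                raise SessionValidationError(f"{name} missing")
        for col in ("t", "x", "y"):
            if col not in self.positions.columns:
                raise SessionValidationError(f"positions missing column {col!r}")
        t = self.positions["t"].to_numpy(dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            bad = float(t[1:][np.diff(t) <= 0][0])
            raise SessionValidationError(f"position times not strictly increasing at t={bad}")
        xy = self.positions[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise SessionValidationError("non-finite position sample")
        for col in ("t", "kind"):
            if col not in self.events.columns:
                raise SessionValidationError(f"events missing column {col!r}")
        et = self.events["t"].to_numpy(dtype=float)
        if et.size and np.any(np.diff(et) < 0):
            raise SessionValidationError("event times must be non-decreasing")
        unknown = set(self.events["kind"]) - EVENT_KINDS
        if unknown:
            raise SessionValidationError(f"unknown event kinds: {sorted(unknown)}")
        for st in self.spikes:
            st.validate()
        prev_end = -math.inf
        for pose in self.lever_poses:
            pose.validate()
            if pose.t_start < prev_end:
                raise SessionValidationError("lever pose epochs must be disjoint and ordered")
            prev_end = pose.t_end
        presses = self.events.loc[self.events["kind"] == "lever_press", "t"]
        for tp in presses.to_numpy(dtype=float):
            if not any(p.contains(tp) for p in self.lever_poses):
                raise SessionValidationError(
                    f"lever press at t={tp} falls outside all lever pose epochs"
                )
        return self

    # -- convenience accessors -------------------------------------------------

    @property
    def t_start(self) -> float:
        return float(self.positions["t"].iloc[0])

    @property
    def t_end(self) -> float:
        return float(self.positions["t"].iloc[-1])

    def lever_pose_at(self, t: float) -> LeverPose:
        for pose in self.lever_poses:
            if pose.contains(t):
                return pose
        raise SessionValidationError(f"no lever pose covering t={t}")

    def dwell_times(self) -> np.ndarray:
        """Per-sample dwell time (s): gap to the next sample, capped at 3x the
        median gap to guard against tracking dropouts; the last sample gets the
        median gap."""
        t = self.positions["t"].to_numpy(dtype=float)
        return dwell_times(t)


def dwell_times(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        return np.full(t.shape, 0.02)
    gaps = np.diff(t)
    med = float(np.median(gaps))
    capped = np.minimum(gaps, 3.0 * med)
    return np.append(capped, med)


def lever_wall_distance(
    x, y, pose: LeverPose, geometry: ArenaGeometry
) -> np.ndarray:
    """Distance (cm) from points to the nearest wall of the lever box.

    The box is a ``lever_box_length`` x ``lever_box_width`` rectangle centered
    on ``pose.center`` with its long axis along ``pose.lever_direction``.
    Points inside the footprint get distance 0.
    """
    dx = np.asarray(x, dtype=float) - pose.center[0]
    dy = np.asarray(y, dtype=float) - pose.center[1]
    ux, uy = pose.lever_direction
    # coordinates in the box frame: u along the lever axis, v across
    pu = dx * ux + dy * uy
    pv = -dx * uy + dy * ux
    half_l = geometry.lever_box_length / 2.0
    half_w = geometry.lever_box_width / 2.0
    du = np.maximum(np.abs(pu) - half_l, 0.0)
    dv = np.maximum(np.abs(pv) - half_w, 0.0)
    return np.hypot(du, dv)


def rotate_session(session: Session, angle_deg: float) -> Session:
    """Rigidly rotate a session (positions, lever poses, bridge) about the
    arena center by ``angle_deg`` counterclockwise.

    The result is generally non-canonical (bridge off the negative-y axis);
    validate it with ``canonical=False``.
    """
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)

    def rot(px, py):
        return c * px - s * py, s * px + c * py

    pos = session.positions.copy()
    rx, ry = rot(pos["x"].to_numpy(float), pos["y"].to_numpy(float))
    pos["x"], pos["y"] = rx, ry
    poses = [
        replace(
            p,
            center=rot(*p.center),
            lever_direction=rot(*p.lever_direction),
        )
        for p in session.lever_poses
    ]
    geom = replace(session.geometry, bridge_center=rot(*session.geometry.bridge_center))
    return Session(
        geometry=geom,
        positions=pos,
        spikes=session.spikes,
        events=session.events,
        lever_poses=poses,
        sample_rate=session.sample_rate,
        metadata=dict(session.metadata),
    )


# -- container I/O -------------------------------------------------------------

_GEOMETRY_FIELDS = (
    "arena_radius",
    "bridge_center",
    "periphery_threshold",
    "lever_proximity_threshold",
    "lever_frame_radius",
    "lever_center_max_radius",
    "lever_box_length",
    "lever_box_width",
)


def write_session(session: Session, path) -> None:
    """Write a session container directory.  Deterministic for equal input."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    session.positions.to_csv(root / "positions.tsv", sep="\t", index=False, float_format="%.17g")
    ev = session.events.copy()
    if "payload" not in ev.columns:
        ev["payload"] = ""
    ev.to_csv(root / "events.tsv", sep="\t", index=False, float_format="%.17g")
    spikes_dir = root / "spikes"
    spikes_dir.mkdir(exist_ok=True)
    for old in spikes_dir.glob("*.tsv"):
        old.unlink()
    for st in session.spikes:
        pd.DataFrame({"t": st.spike_times}).to_csv(
            spikes_dir / f"{st.neuron_id}.tsv", sep="\t", index=False,
            float_format="%.17g",
        )
    rows = [
        {
            "t_start": p.t_start,
            "t_end": p.t_end,
            "cx": p.center[0],
            "cy": p.center[1],
            "dx": p.lever_direction[0],
            "dy": p.lever_direction[1],
        }
        for p in session.lever_poses
    ]
    pd.DataFrame(rows, columns=["t_start", "t_end", "cx", "cy", "dx", "dy"]).to_csv(
        root / "lever_poses.tsv", sep="\t", index=False, float_format="%.17g"
    )
    geom = {k: getattr(session.geometry, k) for k in _GEOMETRY_FIELDS}
    geom["bridge_center"] = list(geom["bridge_center"])
    with open(root / "geometry.yaml", "w") as fh:
        yaml.safe_dump(geom, fh, sort_keys=True)
    meta = dict(session.metadata)
    meta["sample_rate"] = session.sample_rate
    with open(root / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_session(path, canonical: bool = True) -> Session:
    """Read a session container written by :func:`write_session`."""
    root = Path(path)
    for name in ("positions.tsv", "events.tsv", "lever_poses.tsv", "geometry.yaml", "metadata.yaml"):
        if not (root / name).exists():
            raise SessionLoadError(f"{name.split('.')[0]} missing from {root}")
    positions = pd.read_csv(root / "positions.tsv", sep="\t", float_precision="round_trip")
    events = pd.read_csv(root / "events.tsv", sep="\t", float_precision="round_trip")
    if "payload" in events.columns:
        events["payload"] = events["payload"].fillna("")
    with open(root / "geometry.yaml") as fh:
        graw = yaml.safe_load(fh)
    graw["bridge_center"] = tuple(graw["bridge_center"])
    geometry = ArenaGeometry(**graw)
    with open(root / "metadata.yaml") as fh:
        meta = yaml.safe_load(fh) or {}
    sample_rate = float(meta.pop("sample_rate", 50.0))
    lp = pd.read_csv(root / "lever_poses.tsv", sep="\t", float_precision="round_trip")
    poses = [
        LeverPose(
            t_start=float(r.t_start),
            t_end=float(r.t_end),
            center=(float(r.cx), float(r.cy)),
            lever_direction=(float(r.dx), float(r.dy)),
        )
        for r in lp.itertuples()
    ]
    spikes = []
    spikes_dir = root / "spikes"
    if spikes_dir.exists():
        for f in sorted(spikes_dir.glob("*.tsv")):
            df = pd.read_csv(f, sep="\t", float_precision="round_trip")
            spikes.append(SpikeTrain(neuron_id=f.stem, spike_times=df["t"].to_numpy(float)))
    session = Session(
        geometry=geometry,
        positions=positions,
        spikes=spikes,
        events=events,
        lever_poses=poses,
        sample_rate=sample_rate,
        metadata=meta,
    )
    session.validate(canonical=canonical)
    return session
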