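"""Synthetic homing-task sessions with known ground truth.

The generator emulates the structure of an automated homing task on a
circular arena: on each trial a door opens, the mouse runs from a peripheral
home-base bridge onto the arena, searches for a small lever box placed at a
random location (within 75% of the arena radius), circles the box, presses
the lever, and returns ("homes") to the periphery.  The session starts with
seven light trials and then alternates light/dark.  The arena is rotated by a
multiple of 45 degrees between trials and the lever is moved to a fresh
random position every fourth trial.

Behavioral structure emulated:

* search paths are correlated random walks whose turning noise and
  goal-attraction differ between light and dark, so dark searches are longer
  and more tortuous;
* the homing direction is drawn from a von Mises centered on the true bridge
  direction whose concentration decays with search-path length, so homing
  error grows with search length;
* spike trains are inhomogeneous Poisson given the trajectory and one of
  three firing-field archetypes: a world-anchored place field, a
  lever-distance field, or a lever-anchored directional field whose per-trial
  orientation drifts with the homing direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .circular import angle_from_south, circular_mean, wrap_degrees
from .data_model import (
    ArenaGeometry,
    LeverPose,
    Session,
    SpikeTrain,
    lever_wall_distance,
)


class GenerationError(ValueError):
    """The requested synthetic session is geometrically infeasible."""


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic neuron's firing field.

    ``kind`` selects the archetype; only the parameters for that archetype are
    read.  Rates in Hz, lengths in cm, angles in degrees.
    """

    kind: str  # {place, lever_distance, lever_anchored}
    peak_rate: float = 10.0
    baseline_rate: float = 0.1
    # place
    place_center: tuple[float, float] = (0.0, 0.0)
    place_sd: float = 8.0
    # lever_distance (distance measured to the lever-box wall)
    preferred_distance: float = 4.0
    distance_sd: float = 3.0
    # lever_anchored
    preferred_direction: float = 0.0
    concentration: float = 4.0
    reference_frame: str = "cardinal"  # {cardinal, bridge, lever}
    drift_slope: float = 0.0
    drift_noise_sd: float = 5.0
    radial_center: float = 3.0
    radial_sd: float = 4.0

    def validate(self) -> None:
        if self.kind not in ("place", "lever_distance", "lever_anchored"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if not self.peak_rate > self.baseline_rate >= 0:
            raise ValueError("need peak_rate > baseline_rate >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.place_sd <= 0 or self.distance_sd <= 0:
            raise ValueError("place_sd and distance_sd must be > 0")
        if self.reference_frame not in ("cardinal", "bridge", "lever"):
            raise ValueError(f"unknown reference frame {self.reference_frame!r}")


@dataclass(frozen=True)
class BehaviorSpec:
    """Trial-level behavioral parameters of a synthetic session.

    Tortuosity values are the SD (deg) of per-step Gaussian turning noise of
    the correlated random walk at the position sampling rate.  The homing
    direction is drawn from a von Mises with concentration
    ``kappa_base / (1 + length_coupling * search_path_length)`` so that homing
    error grows with search length when ``length_coupling > 0``.
    """

    n_trials: int = 100
    light_dark_alternation: bool = True
    search_tortuosity_light: float = 5.0
    search_tortuosity_dark: float = 18.0
    attraction_light: float = 0.25
    attraction_dark: float = 0.0
    speed_light: float = 40.0
    speed_dark: float = 20.0
    homing_speed_light: float = 60.0
    homing_speed_dark: float = 30.0
    at_lever_speed: float = 8.0
    press_pause_s: float = 1.5
    homing_error_kappa_base: float = 300.0
    homing_error_length_coupling: float = 0.15
    lever_loop: bool = True
    multi_journey_prob_light: float = 0.0
    multi_journey_prob_dark: float = 0.0
    sample_rate: float = 50.0
    intertrial_s: float = 5.0

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for s in (
            self.speed_light,
            self.speed_dark,
            self.homing_speed_light,
            self.homing_speed_dark,
            self.at_lever_speed,
        ):
            if s <= 0:
                raise ValueError("speeds must be > 0")
        if self.homing_error_kappa_base <= 0:
            raise ValueError("homing_error_kappa_base must be > 0")


@dataclass
class SyntheticGroundTruth:
    """Injected parameters recorded during generation, for recovery tests.

    ``trials`` has one row per trial: trial_id, light, search_length (cm),
    homing_direction (deg, measured at the lever box as in the analysis),
    homing_error (deg, signed, at the arena center relative to the bridge),
    arrival_x/arrival_y.  ``drifts`` maps each lever-anchored neuron id to the
    per-trial field rotation delta (deg).
    """

    field_specs: dict[str, FieldSpec]
    trials: pd.DataFrame
    drifts: dict[str, np.ndarray] = field(default_factory=dict)


def _light_sequence(n_trials: int, alternate: bool) -> np.ndarray:
    light = np.ones(n_trials, dtype=bool)
    if alternate and n_trials > 7:
        # first seven trials in the light, then strict alternation
        tail = np.arange(n_trials - 7)
        light[7:] = tail % 2 == 1
    return light


def _draw_lever_poses(behavior, geometry, rng):
    """Lever center/direction per trial: fresh uniform draw within 75% of the
    arena radius every 4th trial, rotated by a random multiple of 45 degrees
    (the arena rotation) on the other trials."""
    centers, dirs = [], []
    cx = cy = 0.0
    ang = 0.0
    for i in range(behavior.n_trials):
        if i % 4 == 0:
            r = geometry.lever_center_max_radius * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            cx, cy = r * math.cos(th), r * math.sin(th)
            ang = rng.uniform(0.0, 2.0 * math.pi)
        else:
            rot = math.radians(45.0 * rng.integers(0, 8))
            c, s = math.cos(rot), math.sin(rot)
            cx, cy = c * cx - s * cy, s * cx + c * cy
            ang = ang + rot
        if math.hypot(cx, cy) > geometry.lever_center_max_radius + 1e-9:
            raise GenerationError("lever placed outside the allowed radius")
        centers.append((cx, cy))
        dirs.append((math.cos(ang), math.sin(ang)))
    return centers, dirs


def _search_walk(start, heading0, pose, geometry, speed, turn_sd_deg, attraction, fs, rng,
                 max_s=240.0):
    """Correlated random walk from ``start`` until within the lever proximity
    zone.  Goal attraction ramps up after 30 s so every search terminates."""
    dt = 1.0 / fs
    step = speed * dt
    sd = math.radians(turn_sd_deg)
    x, y = start
    h = heading0
    xs, ys = [], []
    n_max = int(max_s * fs)
    tcx, tcy = pose.center
    r_wall = geometry.arena_radius - 2.0
    for i in range(n_max):
        d = lever_wall_distance(x, y, pose, geometry)
        if d < geometry.lever_proximity_threshold:
            break
        bearing = math.atan2(tcy - y, tcx - x)
        attr = attraction
        if i * dt > 30.0:
            attr = min(0.5, attraction + (i * dt - 30.0) * 0.01)
        dh = (bearing - h + math.pi) % (2.0 * math.pi) - math.pi
        h = h + attr * dh + rng.normal(0.0, sd)
        x += step * math.cos(h)
        y += step * math.sin(h)
        rad = math.hypot(x, y)
        if rad > r_wall:
            # steer back toward the arena interior
            x, y = x * r_wall / rad, y * r_wall / rad
            h = math.atan2(-y, -x) + rng.normal(0.0, 0.3)
        xs.append(x)
        ys.append(y)
    return np.array(xs), np.array(ys)


def _failed_journey(entry, geometry, speed, turn_sd_deg, fs, rng, duration_s=6.0):
    """A short excursion onto the arena that returns to the bridge without
    reaching the lever: out along a noisy arc, then straight back."""
    dt = 1.0 / fs
    x, y = entry
    h = math.pi / 2.0
    xs, ys = [], []
    n_out = int(duration_s * fs / 2)
    sd = math.radians(turn_sd_deg)
    for _ in range(n_out):
        h += rng.normal(0.0, sd)
        x += speed * dt * math.cos(h)
        y += speed * dt * math.sin(h)
        rad = math.hypot(x, y)
        if rad > geometry.arena_radius - 2.0:
            x, y = x * (geometry.arena_radius - 2.0) / rad, y * (geometry.arena_radius - 2.0) / rad
        xs.append(x)
        ys.append(y)
    back = _straight(np.array([x, y]), np.array(entry), speed, fs)
    return np.concatenate([xs, back[0]]), np.concatenate([ys, back[1]])


def _straight(p0, p1, speed, fs):
    dist = float(np.hypot(*(p1 - p0)))
    n = max(int(dist * fs / speed), 1)
    frac = (np.arange(n) + 1.0) / n
    return p0[0] + frac * (p1[0] - p0[0]), p0[1] + frac * (p1[1] - p0[1])


def _arc(center, radius, a0, a1, speed, fs):
    """Arc at ``radius`` around ``center`` from angle a0 to a1 (rad, signed
    sweep taken literally)."""
    sweep = a1 - a0
    n = max(int(abs(sweep) * radius * fs / speed), 1)
    ang = a0 + (np.arange(n) + 1.0) / n * sweep
    return center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)


def generate_session(
    behavior: BehaviorSpec,
    fields: dict[str, FieldSpec] | list[FieldSpec],
    seed: int,
    geometry: ArenaGeometry = ArenaGeometry(),
    fields_dark: Optional[dict[str, FieldSpec]] = None,
) -> tuple[Session, SyntheticGroundTruth]:
    """Generate a full synthetic session plus its ground truth.

    ``fields`` maps neuron ids to field specs (a bare list gets ids n000,
    n001, ...).  ``fields_dark``, if given, replaces the field of the listed
    neurons during dark trials (full remapping between conditions); by
    default fields are condition-invariant.  Identical seed gives identical
    output.
    """
    behavior.validate()
    if not isinstance(fields, dict):
        fields = {f"n{i:03d}": f for i, f in enumerate(fields)}
    for f in fields.values():
        f.validate()
    fields_dark = fields_dark or {}
    for f in fields_dark.values():
        f.validate()
    rng = np.random.default_rng(seed)
    fs = behavior.sample_rate
    dt = 1.0 / fs
    light_seq = _light_sequence(behavior.n_trials, behavior.light_dark_alternation)
    centers, lever_dirs = _draw_lever_poses(behavior, geometry, rng)
    bridge = np.array(geometry.bridge_center)
    entry = np.array([0.0, -(geometry.arena_radius - 2.0)])
    bridge_az = angle_from_south(bridge[0], bridge[1])  # 0 by construction

    xs_all: list[np.ndarray] = []
    ys_all: list[np.ndarray] = []
    trial_of_sample: list[np.ndarray] = []
    events: list[tuple[float, str, str]] = []
    poses: list[LeverPose] = []
    truth_rows = []
    light_state = None
    n_samples = 0

    def emit(chunk_x, chunk_y, trial_idx):
        nonlocal n_samples
        xs_all.append(np.asarray(chunk_x, float))
        ys_all.append(np.asarray(chunk_y, float))
        trial_of_sample.append(np.full(len(chunk_x), trial_idx, dtype=int))
        n_samples += len(chunk_x)

    # initial settling period on the bridge
    n0 = int(2.0 * fs)
    emit(bridge[0] + rng.normal(0, 0.2, n0), bridge[1] + rng.normal(0, 0.2, n0), -1)

    for i in range(behavior.n_trials):
        light = bool(light_seq[i])
        speed = behavior.speed_light if light else behavior.speed_dark
        h_speed = behavior.homing_speed_light if light else behavior.homing_speed_dark
        turn_sd = behavior.search_tortuosity_light if light else behavior.search_tortuosity_dark
        attraction = behavior.attraction_light if light else behavior.attraction_dark
        pose = LeverPose(0.0, 1.0, centers[i], lever_dirs[i])

        t_open = n_samples * dt
        if light_state is None or light_state != light:
            events.append((t_open, "light_on" if light else "light_off", ""))
            light_state = light
        events.append((t_open, "door_open", f"trial={i}"))
        if i > 0:
            events.append((t_open, "arena_rotation", ""))

        # bridge -> arena entry
        bx, by = _straight(bridge, entry, speed, fs)
        emit(bx, by, i)

        # optional failed journey(s)
        p_fail = behavior.multi_journey_prob_light if light else behavior.multi_journey_prob_dark
        while rng.uniform() < p_fail:
            fx, fy = _failed_journey(entry, geometry, speed, turn_sd, fs, rng)
            emit(fx, fy, i)
            n_b = int(1.0 * fs)
            emit(bridge[0] + rng.normal(0, 0.2, n_b), bridge[1] + rng.normal(0, 0.2, n_b), i)
            bx, by = _straight(bridge, entry, speed, fs)
            emit(bx, by, i)

        # search
        sx, sy = _search_walk(
            entry, math.pi / 2.0, pose, geometry, speed, turn_sd, attraction, fs, rng
        )
        emit(sx, sy, i)
        search_pts_x = np.concatenate([bx, sx])
        search_pts_y = np.concatenate([by, sy])
        search_length = float(
            np.sum(np.hypot(np.diff(search_pts_x), np.diff(search_pts_y)))
        )
        cur = np.array([sx[-1] if len(sx) else entry[0], sy[-1] if len(sy) else entry[1]])

        # at-lever: one circumnavigation, then a pause at the pressable side
        cx, cy = pose.center
        r_loop = 7.0
        a_cur = math.atan2(cur[1] - cy, cur[0] - cx)
        ax, ay = _straight(cur, np.array([cx + r_loop * math.cos(a_cur), cy + r_loop * math.sin(a_cur)]),
                           behavior.at_lever_speed, fs)
        emit(ax, ay, i)
        if behavior.lever_loop:
            lx, ly = _arc((cx, cy), r_loop, a_cur, a_cur + 2.0 * math.pi,
                          behavior.at_lever_speed, fs)
            emit(lx, ly, i)
        a_press = math.atan2(lever_dirs[i][1], lever_dirs[i][0])
        px_, py_ = _arc((cx, cy), r_loop, a_cur,
                        a_cur + ((a_press - a_cur) % (2.0 * math.pi)),
                        behavior.at_lever_speed, fs)
        emit(px_, py_, i)
        n_pause = int(behavior.press_pause_s * fs)
        press_pt = (cx + r_loop * math.cos(a_press), cy + r_loop * math.sin(a_press))
        emit(press_pt[0] + rng.normal(0, 0.3, n_pause),
             press_pt[1] + rng.normal(0, 0.3, n_pause), i)
        t_press = (n_samples - n_pause // 2) * dt
        events.append((t_press, "lever_press", ""))

        # homing: straight run to a peripheral arrival point whose angular
        # error about the bridge direction shrinks with search length
        kappa = behavior.homing_error_kappa_base / (
            1.0 + behavior.homing_error_length_coupling * search_length
        )
        err = float(rng.vonmises(0.0, kappa))
        arrival_angle_std = -math.pi / 2.0 + math.radians(wrap_degrees(bridge_az)) + err
        r_arr = geometry.arena_radius - geometry.periphery_threshold + 1.0
        arrival = np.array(
            [r_arr * math.cos(arrival_angle_std), r_arr * math.sin(arrival_angle_std)]
        )
        hx, hy = _straight(np.array(press_pt), arrival, h_speed, fs)
        emit(hx, hy, i)

        # along the wall back to the bridge, then onto the bridge
        a_arr = math.atan2(arrival[1], arrival[0])
        a_home = -math.pi / 2.0
        sweep = (a_home - a_arr + math.pi) % (2.0 * math.pi) - math.pi
        wx, wy = _arc((0.0, 0.0), r_arr, a_arr, a_arr + sweep, h_speed, fs)
        emit(wx, wy, i)
        gx, gy = _straight(np.array([wx[-1], wy[-1]]), bridge, h_speed, fs)
        emit(gx, gy, i)
        t_beam = n_samples * dt
        events.append((t_beam, "magazine_beam", ""))
        t_close = t_beam + 0.5
        # intertrial interval on the bridge
        n_iti = int(behavior.intertrial_s * fs)
        emit(bridge[0] + rng.normal(0, 0.2, n_iti), bridge[1] + rng.normal(0, 0.2, n_iti), -1)
        events.append((t_close, "door_close", f"trial={i}"))

        poses.append(
            LeverPose(t_open - 2.0, t_close + 2.0, centers[i], lever_dirs[i])
        )
        homing_dir = float(
            wrap_degrees(
                angle_from_south(arrival[0] - cx, arrival[1] - cy)
                - angle_from_south(bridge[0] - cx, bridge[1] - cy)
            )
        )
        truth_rows.append(
            {
                "trial_id": i,
                "light": light,
                "search_length": search_length,
                "homing_direction": homing_dir,
                "homing_error": math.degrees(err),
                "arrival_x": float(arrival[0]),
                "arrival_y": float(arrival[1]),
            }
        )

    x = np.concatenate(xs_all)
    y = np.concatenate(ys_all)
    trial_idx = np.concatenate(trial_of_sample)
    t = np.arange(n_samples) * dt
    positions = pd.DataFrame({"t": t, "x": x, "y": y})
    truth_df = pd.DataFrame(truth_rows)

    # per-sample lever-relative covariates (for spike generation)
    wall_dist = np.full(n_samples, np.inf)
    cdir = np.zeros(n_samples)
    for i in range(behavior.n_trials):
        m = trial_idx == i
        if not np.any(m):
            continue
        pose = LeverPose(0.0, 1.0, centers[i], lever_dirs[i])
        wall_dist[m] = lever_wall_distance(x[m], y[m], pose, geometry)
        cdir[m] = angle_from_south(x[m] - centers[i][0], y[m] - centers[i][1])

    # per-trial drift of lever-anchored fields, coupled to the homing
    # direction's deviation from its circular mean
    hd = truth_df["homing_direction"].to_numpy()
    hd_dev = wrap_degrees(hd - circular_mean(hd))
    drifts: dict[str, np.ndarray] = {}
    spikes = []
    for nid in sorted(fields):
        spec = fields[nid]
        spec_dark = fields_dark.get(nid)
        delta = None
        if spec.kind == "lever_anchored":
            delta = wrap_degrees(
                spec.drift_slope * hd_dev
                + rng.normal(0.0, spec.drift_noise_sd, behavior.n_trials)
            )
            drifts[nid] = delta
        rate = _rate_trajectory(
            spec, spec_dark, x, y, wall_dist, cdir, trial_idx, delta,
            light_seq, centers, lever_dirs, bridge, behavior.n_trials
        )
        counts = rng.poisson(rate * dt)
        reps = np.repeat(np.arange(n_samples), counts)
        st = t[reps] + rng.uniform(0.0, dt, reps.size)
        spikes.append(SpikeTrain(neuron_id=nid, spike_times=np.sort(st)))

    ev_df = pd.DataFrame(events, columns=["t", "kind", "payload"]).sort_values(
        "t", kind="stable", ignore_index=True
    )
    session = Session(
        geometry=geometry,
        positions=positions,
        spikes=spikes,
        events=ev_df,
        lever_poses=poses,
        sample_rate=fs,
        metadata={"animal_id": f"sim{seed}", "synthetic": True, "seed": int(seed)},
    )
    session.validate()
    truth = SyntheticGroundTruth(field_specs=dict(fields), trials=truth_df, drifts=drifts)
    return session, truth


def _rate_trajectory(spec, spec_dark, x, y, wall_dist, cdir, trial_idx, delta,
                     light_seq, centers, lever_dirs, bridge, n_trials):
    """Firing rate (Hz) at every position sample for one neuron."""
    n = x.size
    rate = np.full(n, spec.baseline_rate)
    for i in range(n_trials):
        m = trial_idx == i
        if not np.any(m):
            continue
        s = spec
        if spec_dark is not None and not light_seq[i]:
            s = spec_dark
        amp = s.peak_rate - s.baseline_rate
        if s.kind == "place":
            d2 = (x[m] - s.place_center[0]) ** 2 + (y[m] - s.place_center[1]) ** 2
            bump = np.exp(-d2 / (2.0 * s.place_sd**2))
        elif s.kind == "lever_distance":
            bump = np.exp(
                -((wall_dist[m] - s.preferred_distance) ** 2) / (2.0 * s.distance_sd**2)
            )
        else:  # lever_anchored
            mu = s.preferred_direction
            if delta is not None:
                mu = mu + delta[i]
            if s.reference_frame == "bridge":
                mu = mu + angle_from_south(
                    bridge[0] - centers[i][0], bridge[1] - centers[i][1]
                )
            elif s.reference_frame == "lever":
                mu = mu + angle_from_south(lever_dirs[i][0], lever_dirs[i][1])
            ang = np.radians(cdir[m] - mu)
            bump = np.exp(s.concentration * (np.cos(ang) - 1.0))
            bump = bump * np.exp(
                -((wall_dist[m] - s.radial_center) ** 2) / (2.0 * s.radial_sd**2)
            )
        rate[m] = s.baseline_rate + amp * bump
    return rate


# -- unit-feature generator for the cell classifier ----------------------------

def generate_unit_features(n_pyramidal: int, n_interneuron: int, seed: int):
    """Synthetic unit features (mean rate, mean waveform, spike-time
    autocorrelation) for the pyramidal/interneuron classifier.

    Pyramidal units: low mean rate, broad waveform, bursty autocorrelation
    (mass at 3-6 ms).  Interneurons: high rate, narrow waveform, flat
    autocorrelation.  Returns (features, true_classes) where ``features`` is a
    list of :class:`homefield.cell_classify.UnitFeatures`.
    """
    from .cell_classify import UnitFeatures

    rng = np.random.default_rng(seed)
    t_w = np.arange(32) - 10.0  # waveform samples around the trough
    lags = (np.arange(50) + 0.5) * 0.5  # autocorr bin centers, ms
    features: list[UnitFeatures] = []
    classes: list[str] = []
    for kind, count in (("pyramidal", n_pyramidal), ("interneuron", n_interneuron)):
        for _ in range(count):
            if kind == "pyramidal":
                rate = float(np.exp(rng.normal(0.1, 0.5)))
                width = rng.normal(4.5, 0.4)
                burst = np.exp(-((lags - 4.5) ** 2) / (2 * 1.5**2)) * rng.normal(3.0, 0.3)
                ac = 1.0 + burst + 0.5 * (1 - np.exp(-lags / 8.0))
            else:
                rate = float(max(rng.normal(18.0, 5.0), 4.0))
                width = rng.normal(2.0, 0.25)
                ac = 1.0 + 1.5 * (1 - np.exp(-lags / 3.0)) + rng.normal(0, 0.05, lags.size)
            wf = -np.exp(-(t_w**2) / (2 * width**2)) + 0.3 * np.exp(
                -((t_w - 2.5 * width) ** 2) / (2 * (2 * width) ** 2)
            )
            wf = wf + rng.normal(0, 0.02, wf.size)
            ac = np.maximum(ac * rng.normal(1.0, 0.05, ac.size), 0.0)
            ac[lags < 2.0] *= 0.05  # refractory dip
            features.append(
                UnitFeatures(mean_rate=rate, waveform=wf, autocorrelation=ac)
            )
            classes.append(kind)
    return features, classes
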