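"""Lever-centered reference frames, directional tuning, lever-anchored-field
classification, trial drift, and drift-homing coupling.

The animal's position is expressed relative to the movable lever box, and its
direction around the box is measured in one of three reference frames:

* **cardinal** — from a vector pointing south (toward the bridge side of the
  room), i.e. the raw lever-centered data;
* **bridge** — from the vector pointing from the lever-box center toward the
  bridge center;
* **lever** — from the vector pointing from the box center toward the
  pressable lever part.

Samples more than 12 cm from the lever-box wall are excluded from
lever-centered analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .behavior import TrialRecord
from .circular import (
    angle_from_south,
    circular_correlation,
    circular_difference,
    circular_mean,
    weighted_mean_vector,
    wrap_degrees,
)
from .data_model import ArenaGeometry, LeverPose, Session, dwell_times, lever_wall_distance
from .maps import RateMap2D, _masked_smooth, map_similarity
from .trial_matrix import TrialMatrix

FRAMES = ("cardinal", "bridge", "lever")
LEVER_FRAME_MAX_WALL_CM = 12.0
DIRECTION_BIN_DEG = 10.0
PEAK_RATE_THRESHOLD_HZ = 7.5
SPLIT_HALF_THRESHOLD = 0.4
PEAK_DISTANCE_THRESHOLD_CM = 10.0


class LeverFrameError(ValueError):
    pass


@dataclass
class LeverFrameData:
    """Lever-centered samples (and spikes) in a stated reference frame."""

    frame: str
    x: np.ndarray  # cm, lever-centered, rotated into the frame
    y: np.ndarray
    direction: np.ndarray  # deg in the frame
    wall_distance: np.ndarray
    dwell: np.ndarray
    spike_x: np.ndarray
    spike_y: np.ndarray
    spike_direction: np.ndarray


@dataclass
class DirectionalTuning:
    bin_centers: np.ndarray  # 36 bins of 10 deg
    rate: np.ndarray  # Hz, smoothed
    mvl: float
    preferred_direction: float  # deg
    peak_rate: float


@dataclass
class LeverAnchoredResult:
    frame: str
    peak_near_lever: bool  # criterion 1
    peak_rate_ok: bool  # criterion 2
    split_half_stable: bool  # criterion 3
    anchored: bool
    preferred_direction: float
    peak_distance_cm: float
    map_peak_rate: float
    split_half_similarity: float


@dataclass
class DriftResult:
    idealized_tuning: np.ndarray
    delta_deg: np.ndarray  # per row; NaN where masked
    usable: np.ndarray  # boolean per row
    roll_bins: int


def frame_offset(pose: LeverPose, geometry: ArenaGeometry, frame: str) -> float:
    """Angle (deg from south) by which cardinal lever-centered data are
    rotated into ``frame``: 0 for cardinal, the lever->bridge angle for the
    bridge frame, the lever-direction angle for the lever frame."""
    if frame == "cardinal":
        return 0.0
    if frame == "bridge":
        bx, by = geometry.bridge_center
        return float(angle_from_south(bx - pose.center[0], by - pose.center[1]))
    if frame == "lever":
        return float(angle_from_south(*pose.lever_direction))
    raise LeverFrameError(f"unknown frame {frame!r}")


def _rotate(x, y, angle_deg):
    """Rotate vectors counterclockwise by ``angle_deg``."""
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return c * x - s * y, s * x + c * y


def to_lever_frame(
    positions, pose: LeverPose, geometry: ArenaGeometry, frame: str = "cardinal",
    spike_times: Optional[np.ndarray] = None,
) -> LeverFrameData:
    """Transform positions (and optionally spikes) into lever-centered
    coordinates in ``frame``, dropping samples more than 12 cm from the
    lever-box wall."""
    t = positions["t"].to_numpy(float)
    x = positions["x"].to_numpy(float)
    y = positions["y"].to_numpy(float)
    dwell = dwell_times(t)
    wall = lever_wall_distance(x, y, pose, geometry)
    keep = wall <= LEVER_FRAME_MAX_WALL_CM
    off = frame_offset(pose, geometry, frame)
    rx, ry = _rotate(x[keep] - pose.center[0], y[keep] - pose.center[1], -off)
    direction = wrap_degrees(angle_from_south(rx, ry))
    if spike_times is not None and len(t) > 1:
        st = np.asarray(spike_times, float)
        st = st[(st >= t[0]) & (st <= t[-1])]
        sx = np.interp(st, t, x)
        sy = np.interp(st, t, y)
        swall = lever_wall_distance(sx, sy, pose, geometry)
        skeep = swall <= LEVER_FRAME_MAX_WALL_CM
        srx, sry = _rotate(sx[skeep] - pose.center[0], sy[skeep] - pose.center[1], -off)
        sdir = wrap_degrees(angle_from_south(srx, sry))
    else:
        srx = sry = sdir = np.empty(0)
    return LeverFrameData(
        frame=frame,
        x=rx,
        y=ry,
        direction=direction,
        wall_distance=wall[keep],
        dwell=dwell[keep],
        spike_x=srx,
        spike_y=sry,
        spike_direction=sdir,
    )


def collect_lever_frame(
    session: Session,
    trials: Sequence[TrialRecord],
    spike_times: np.ndarray,
    frame: str = "cardinal",
    light: Optional[bool] = None,
    parity: Optional[int] = None,
    trial_ids: Optional[set] = None,
) -> LeverFrameData:
    """Pool lever-centered data over the lever-pressed journeys of the chosen
    trials.  ``parity`` (0 or 1) keeps only even/odd pressed journeys (used
    for split-half stability); ``trial_ids`` restricts to specific trials."""
    chunks = []
    journey_counter = 0
    for tr in trials:
        if tr.excluded or (light is not None and tr.light != light):
            continue
        if trial_ids is not None and tr.trial_id not in trial_ids:
            continue
        for j in tr.journeys:
            if not j.lever_pressed:
                continue
            take = parity is None or journey_counter % 2 == parity
            journey_counter += 1
            if not take:
                continue
            m = (session.positions["t"] >= j.t_start) & (session.positions["t"] <= j.t_end)
            pos = session.positions.loc[m]
            if len(pos) < 2:
                continue
            st = np.asarray(spike_times, float)
            st = st[(st >= j.t_start) & (st <= j.t_end)]
            chunks.append(to_lever_frame(pos, tr.lever_pose, session.geometry, frame, st))
    if not chunks:
        raise LeverFrameError("no lever-pressed journey data in the requested condition")
    return LeverFrameData(
        frame=frame,
        x=np.concatenate([c.x for c in chunks]),
        y=np.concatenate([c.y for c in chunks]),
        direction=np.concatenate([c.direction for c in chunks]),
        wall_distance=np.concatenate([c.wall_distance for c in chunks]),
        dwell=np.concatenate([c.dwell for c in chunks]),
        spike_x=np.concatenate([c.spike_x for c in chunks]),
        spike_y=np.concatenate([c.spike_y for c in chunks]),
        spike_direction=np.concatenate([c.spike_direction for c in chunks]),
    )


def directional_tuning(
    data: LeverFrameData, bin_width: float = DIRECTION_BIN_DEG,
    smoothing_sd_bins: float = 1.0,
) -> DirectionalTuning:
    """Occupancy-normalized firing rate per direction bin around the lever.

    Occupancy is smoothed circularly (SD 1 bin), rate = spikes / smoothed
    occupancy, then the rate is smoothed (SD 1 bin).  The mean vector length
    and preferred direction are computed from the rate-weighted resultant of
    the bin-center unit vectors.
    """
    edges = np.arange(-180.0, 180.0 + 0.5 * bin_width, bin_width)
    occ, _ = np.histogram(data.direction, bins=edges, weights=data.dwell)
    if occ.sum() <= 0:
        raise LeverFrameError("zero occupancy everywhere")
    spk, _ = np.histogram(data.spike_direction, bins=edges)
    valid = occ > 0
    occ_s = _masked_smooth(occ, valid, smoothing_sd_bins, wrap=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(valid & (occ_s > 0), spk / occ_s, np.nan)
    rate_s = _masked_smooth(np.where(valid, rate, 0.0), valid, smoothing_sd_bins, wrap=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    finite = np.isfinite(rate_s)
    weights = np.where(finite, rate_s, 0.0)
    if weights.sum() > 0:
        mvl, pref = weighted_mean_vector(centers, weights)
    else:
        mvl, pref = 0.0, 0.0
    return DirectionalTuning(
        bin_centers=centers,
        rate=rate_s,
        mvl=float(mvl),
        preferred_direction=float(pref),
        peak_rate=float(np.nanmax(rate_s)) if finite.any() else 0.0,
    )


def lever_centered_map(
    data: LeverFrameData, bin_size: float = 1.0, smoothing_sd: float = 2.0
) -> RateMap2D:
    """2D lever-centered firing rate map (1 cm bins, 2 cm SD kernel)."""
    ext = LEVER_FRAME_MAX_WALL_CM + 8.0  # box half-diagonal + wall cut-off
    edges = np.arange(-ext, ext + bin_size, bin_size)
    occ, _, _ = np.histogram2d(data.x, data.y, bins=(edges, edges), weights=data.dwell)
    spk, _, _ = np.histogram2d(data.spike_x, data.spike_y, bins=(edges, edges))
    valid = occ > 0
    if not valid.any():
        raise LeverFrameError("zero occupancy in lever-centered map")
    sigma = smoothing_sd / bin_size
    occ_s = _masked_smooth(occ, valid, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(valid, spk / occ_s, np.nan)
    rate_s = _masked_smooth(np.where(valid, rate, 0.0), valid, sigma)
    return RateMap2D(
        bin_size=bin_size,
        origin=(float(edges[0]), float(edges[0])),
        occupancy=np.where(valid, occ_s, np.nan),
        rate=rate_s,
        smoothing_sd=smoothing_sd,
        valid_mask=valid,
    )


# -- firing rate versus distance from the lever box ----------------------------

def _condition_sample_arrays(session, trials, spike_times, light):
    """Concatenated per-sample (wall distance, dwell) over pressed journeys,
    plus the sample index of every spike, for the distance-rate curve and its
    time-shift shuffle."""
    t = session.positions["t"].to_numpy(float)
    x = session.positions["x"].to_numpy(float)
    y = session.positions["y"].to_numpy(float)
    dwell = dwell_times(t)
    spike_times = np.asarray(spike_times, float)
    wall_parts, dwell_parts, spike_idx_parts = [], [], []
    offset = 0
    for tr in trials:
        if tr.excluded or (light is not None and tr.light != light):
            continue
        for j in tr.journeys:
            if not j.lever_pressed:
                continue
            m = np.flatnonzero((t >= j.t_start) & (t <= j.t_end))
            if m.size < 2:
                continue
            wall_parts.append(
                lever_wall_distance(x[m], y[m], tr.lever_pose, session.geometry)
            )
            dwell_parts.append(dwell[m])
            st = spike_times[(spike_times >= t[m[0]]) & (spike_times <= t[m[-1]])]
            sidx = np.searchsorted(t[m], st, side="right") - 1
            spike_idx_parts.append(np.clip(sidx, 0, m.size - 1) + offset)
            offset += m.size
    if offset == 0:
        raise LeverFrameError("no lever-pressed journey data in the requested condition")
    return (
        np.concatenate(wall_parts),
        np.concatenate(dwell_parts),
        np.concatenate(spike_idx_parts) if spike_idx_parts else np.empty(0, int),
    )


def distance_rate_curve(
    wall: np.ndarray, dwell: np.ndarray, spike_bin_counts: np.ndarray,
    edges: np.ndarray, smoothing_sd_bins: float = 1.0,
):
    occ, _ = np.histogram(wall, bins=edges, weights=dwell)
    valid = occ > 0
    occ_s = _masked_smooth(occ, valid, smoothing_sd_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(valid & (occ_s > 0), spike_bin_counts / occ_s, np.nan)
    return _masked_smooth(np.where(valid, rate, 0.0), valid, smoothing_sd_bins)


def classify_lever_anchored(
    session: Session,
    trials: Sequence[TrialRecord],
    spike_times: np.ndarray,
    frame: str = "cardinal",
    light: Optional[bool] = None,
    n_shuffles: int = 500,
    seed: int = 0,
    min_shift_s: float = 20.0,
) -> LeverAnchoredResult:
    """Three-criteria test for a firing field anchored to the lever box.

    1. The peak of the firing-rate-versus-lever-distance curve lies within
       10 cm of the box wall and exceeds the 95th percentile of a shuffle
       distribution (circular time shifts of the spike train, >= 20 s).
    2. The peak of the 2D lever-centered map (1 cm bins, 2 cm SD) > 7.5 Hz.
    3. The similarity of lever-centered maps from odd and even pressed
       journeys > 0.4.
    """
    n_journeys = sum(
        j.lever_pressed
        for tr in trials
        if not tr.excluded and (light is None or tr.light == light)
        for j in tr.journeys
    )
    if n_journeys < 10:
        raise LeverFrameError("need at least 10 lever-pressed journeys")

    # criterion 1: distance-rate peak near the box, against time-shift null
    wall, dwell, spike_idx = _condition_sample_arrays(session, trials, spike_times, light)
    edges = np.arange(0.0, 30.0 + 2.0, 2.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_of_sample = np.clip(np.searchsorted(edges, wall, side="right") - 1, 0, centers.size - 1)
    in_range = (wall >= edges[0]) & (wall < edges[-1])
    obs_counts = np.bincount(
        bin_of_sample[spike_idx][in_range[spike_idx]], minlength=centers.size
    )
    obs_curve = distance_rate_curve(wall[in_range], dwell[in_range], obs_counts[: centers.size], edges)
    finite = np.isfinite(obs_curve)
    if not finite.any():
        raise LeverFrameError("empty distance-rate curve")
    peak_bin = int(np.nanargmax(obs_curve))
    peak_distance = float(centers[peak_bin])
    obs_peak = float(obs_curve[peak_bin])
    rng = np.random.default_rng(seed)
    n_samples = wall.size
    fs = session.sample_rate
    min_shift = int(min_shift_s * fs)
    if n_samples <= 2 * min_shift:
        min_shift = max(n_samples // 4, 1)
    null_peaks = np.empty(n_shuffles)
    for k in range(n_shuffles):
        off = int(rng.integers(min_shift, n_samples - min_shift))
        sidx = (spike_idx + off) % n_samples
        counts = np.bincount(
            bin_of_sample[sidx][in_range[sidx]], minlength=centers.size
        )
        curve = distance_rate_curve(wall[in_range], dwell[in_range], counts[: centers.size], edges)
        null_peaks[k] = np.nanmax(curve) if np.isfinite(curve).any() else 0.0
    peak_near_lever = (
        peak_distance <= PEAK_DISTANCE_THRESHOLD_CM
        and obs_peak > np.percentile(null_peaks, 95)
    )

    # criteria 2 and 3: lever-centered map peak and split-half stability
    data = collect_lever_frame(session, trials, spike_times, frame, light)
    full_map = lever_centered_map(data)
    peak_rate_ok = full_map.peak_rate > PEAK_RATE_THRESHOLD_HZ
    try:
        m_even = lever_centered_map(
            collect_lever_frame(session, trials, spike_times, frame, light, parity=0)
        )
        m_odd = lever_centered_map(
            collect_lever_frame(session, trials, spike_times, frame, light, parity=1)
        )
        sim = map_similarity(m_even, m_odd)
    except (LeverFrameError, ValueError):
        sim = float("nan")
    split_half_stable = bool(np.isfinite(sim) and sim > SPLIT_HALF_THRESHOLD)
    tuning = directional_tuning(data)
    return LeverAnchoredResult(
        frame=frame,
        peak_near_lever=bool(peak_near_lever),
        peak_rate_ok=bool(peak_rate_ok),
        split_half_stable=split_half_stable,
        anchored=bool(peak_near_lever and peak_rate_ok and split_half_stable),
        preferred_direction=tuning.preferred_direction,
        peak_distance_cm=peak_distance,
        map_peak_rate=full_map.peak_rate,
        split_half_similarity=float(sim),
    )


# -- trial drift ---------------------------------------------------------------

def _circular_xcorr_lag(ideal: np.ndarray, row: np.ndarray) -> int:
    """Lag (bins) maximizing the circular cross-correlation of mean-subtracted
    vectors; ties broken toward the smaller absolute lag."""
    n = ideal.size
    a = ideal - ideal.mean()
    b = row - row.mean()
    cc = np.array([np.dot(a, np.roll(b, -lag)) for lag in range(n)])
    lags = np.arange(n)
    signed = np.where(lags < n - lags, lags, lags - n)
    best = cc.max()
    tied = np.flatnonzero(np.isclose(cc, best))
    return int(signed[tied[np.argmin(np.abs(signed[tied]))]])


def trial_drift(matrix: TrialMatrix, roll_bins: Optional[int] = None) -> DriftResult:
    """Per-trial circular displacement of a directional tuning curve.

    The direction trial matrix is rolled so the peak of the mean tuning curve
    sits at bin 0; an idealized tuning curve is the mean of the rows after
    aligning each row's own peak to bin 0; each row's drift is the lag (deg)
    maximizing its circular cross-correlation with the idealized curve.

    ``roll_bins`` fixes the global roll (e.g. to reuse the alignment of a
    reference matrix); by default it is derived from the mean tuning curve.
    """
    if matrix.variable != "lever_direction":
        raise LeverFrameError("trial drift requires a lever_direction matrix")
    rate = np.nan_to_num(matrix.rate, nan=0.0)
    n_rows, n_bins = rate.shape
    usable = rate.std(axis=1) > 0
    if usable.sum() < 5:
        raise LeverFrameError("need at least 5 usable rows")
    bin_width = float(matrix.bin_edges[1] - matrix.bin_edges[0])
    if roll_bins is None:
        mean_curve = rate[usable].mean(axis=0)
        roll_bins = -int(np.argmax(mean_curve))
    rolled = np.roll(rate, roll_bins, axis=1)
    aligned = np.vstack(
        [np.roll(rolled[i], -int(np.argmax(rolled[i]))) for i in range(n_rows) if usable[i]]
    )
    idealized = aligned.mean(axis=0)
    delta = np.full(n_rows, np.nan)
    for i in range(n_rows):
        if not usable[i]:
            continue
        lag = _circular_xcorr_lag(idealized, rolled[i])
        delta[i] = wrap_degrees(lag * bin_width)
    return DriftResult(
        idealized_tuning=idealized,
        delta_deg=delta,
        usable=usable,
        roll_bins=int(roll_bins),
    )


def drift_homing_coupling(
    delta_deg: np.ndarray,
    homing_direction_deg: np.ndarray,
    n_shuffles: int = 500,
    seed: int = 0,
):
    """Circular-circular correlation (Fisher-Lee) between trial drift and
    homing direction, with a homing-permutation p-value and the least-squares
    slope of drift on homing deviation (both centered on their circular means
    and wrapped to (-180, 180]).

    Returns (r, p, slope).
    """
    d = np.asarray(delta_deg, float)
    h = np.asarray(homing_direction_deg, float)
    ok = np.isfinite(d) & np.isfinite(h)
    d, h = d[ok], h[ok]
    if d.size < 10:
        raise LeverFrameError("need at least 10 paired (drift, homing) values")
    r = circular_correlation(d, h)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = circular_correlation(d, rng.permutation(h))
    p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_shuffles + 1))
    dd = circular_difference(d, circular_mean(d))
    hd = circular_difference(h, circular_mean(h))
    denom = float(np.sum(hd * hd))
    slope = float(np.sum(hd * dd) / denom) if denom > 0 else float("nan")
    return float(r), p, slope


def preferred_direction_split_test(
    matrix: TrialMatrix,
    homing_direction_deg: np.ndarray,
    n_shuffles: int = 500,
    seed: int = 0,
):
    """Change in preferred direction between trials with homing direction
    below versus above the (circular) median, with a shuffle p-value.

    Group tuning curves are the mean of the trial-matrix rows in each group;
    the preferred direction is the rate-weighted resultant direction.
    Returns (delta_preferred_deg, p).
    """
    rate = np.nan_to_num(matrix.rate, nan=0.0)
    h = np.asarray(homing_direction_deg, float)
    ok = np.isfinite(h) & (rate.std(axis=1) > 0)
    rate, h = rate[ok], h[ok]
    dev = circular_difference(h, circular_mean(h))
    med = np.median(dev)
    low = dev <= med
    if low.sum() < 5 or (~low).sum() < 5:
        raise LeverFrameError("each homing group needs at least 5 trials")
    centers = matrix.bin_centers

    def group_delta(mask):
        lo_curve = rate[mask].mean(axis=0)
        hi_curve = rate[~mask].mean(axis=0)
        if lo_curve.sum() <= 0 or hi_curve.sum() <= 0:
            return np.nan
        _, p_lo = weighted_mean_vector(centers, lo_curve)
        _, p_hi = weighted_mean_vector(centers, hi_curve)
        return float(circular_difference(p_hi, p_lo))

    observed = group_delta(low)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        null[k] = group_delta(rng.permutation(low))
    null = null[np.isfinite(null)]
    p = float((np.sum(np.abs(null) >= abs(observed)) + 1) / (null.size + 1))
    return observed, p
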