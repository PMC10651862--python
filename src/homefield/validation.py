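"""Ground-truth recovery benchmarks on synthetic sessions.

Each function generates synthetic data with known injected structure, runs
the corresponding analysis stage, and measures how well the structure is
recovered (or, for null calibrations, how well false positives are
controlled).  They are used by the test suite and by the reproduction script
and are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .behavior import (
    Journey,
    TrialRecord,
    homing_geometry,
    light_dark_classifier,
    path_metrics,
    segment_journeys,
    segment_trials,
    trial_path_features,
)
from .cell_classify import classify_units
from .circular import circular_correlation, circular_difference
from .data_model import ArenaGeometry, LeverPose, Session, rotate_session
from .lever_frame import (
    classify_lever_anchored,
    collect_lever_frame,
    directional_tuning,
    drift_homing_coupling,
    trial_drift,
)
from .maps import RateHistogram1D, information_score
from .remapping import condition_maps, condition_partition, pair_similarity, stability
from .synthetic import BehaviorSpec, FieldSpec, generate_session, generate_unit_features
from .trial_matrix import build_trial_matrix

import pandas as pd


def chance_homing_error(seed: int, n: int = 100_000) -> float:
    """Mean absolute error at the periphery for uniformly random arrival
    angles; converges to the 90 degree chance level."""
    rng = np.random.default_rng(seed)
    geom = ArenaGeometry()
    pose = LeverPose(0.0, 1.0, (5.0, 5.0), (1.0, 0.0))
    trial = TrialRecord(0, 0.0, 1.0, light=False, lever_pose=pose)
    r = geom.arena_radius - geom.periphery_threshold + 0.5
    angles = rng.uniform(-np.pi, np.pi, n)
    errors = np.empty(n)
    for i, a in enumerate(angles):
        j = Journey(0.0, 1.0, lever_pressed=True,
                    periphery_arrival=(r * np.cos(a), r * np.sin(a)))
        errors[i] = homing_geometry(j, trial, geom).error_at_periphery
    return float(errors.mean())


def information_score_oracle_deviation(seed: int, n_hist: int = 100) -> float:
    """Max |analytic - brute force| information score over random 20-bin
    histograms.  The oracle evaluates the defining sum term by term with
    explicit probabilities."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_hist):
        occ = rng.uniform(0.5, 10.0, 20)
        rate = rng.uniform(0.0, 30.0, 20)
        hist = RateHistogram1D(
            variable="y_coordinate",
            bin_edges=np.linspace(0, 20, 21),
            occupancy=occ,
            rate=rate,
            raw_occupancy=occ,
            raw_rate=rate,
            mean_rate=float(np.sum(occ * rate) / occ.sum()),
        )
        got = information_score(hist)
        # brute-force oracle
        p = occ / occ.sum()
        lam = sum(p[i] * rate[i] for i in range(20))
        expected = 0.0
        for i in range(20):
            if rate[i] > 0:
                expected += p[i] * (rate[i] / lam) * np.log2(rate[i] / lam)
        worst = max(worst, abs(got - expected))
    return worst


def complexity_reference_values(seed: int, n_paths: int = 1000):
    """(complexity at MVL=0, complexity of a semicircular direction spread,
    fraction of random path pairs ordered consistently with decreasing MVL).

    The semicircle case is built by dense sampling of a path whose step
    directions are uniform over 180 degrees (analytic MVL = 2/pi).
    """
    from .behavior import path_complexity

    c0 = path_complexity(0.0)
    n = 20_000
    dirs = np.radians(np.linspace(-90.0, 90.0, n))
    x = np.concatenate([[0.0], np.cumsum(np.cos(dirs))])
    y = np.concatenate([[0.0], np.cumsum(np.sin(dirs))])
    pm = path_metrics(pd.DataFrame({"t": np.arange(n + 1) * 0.02, "x": x, "y": y}))
    rng = np.random.default_rng(seed)
    mvls, comps = [], []
    for _ in range(n_paths):
        steps = rng.normal(0, 1.0, (rng.integers(10, 200), 2))
        px, py = np.cumsum(steps[:, 0]), np.cumsum(steps[:, 1])
        m = path_metrics(
            pd.DataFrame({"t": np.arange(px.size) * 0.02, "x": px, "y": py})
        )
        from .circular import mean_vector_length

        ang = np.degrees(np.arctan2(np.diff(py), np.diff(px)))
        mvls.append(mean_vector_length(ang))
        comps.append(m.complexity)
    order = np.argsort(mvls)
    comps_sorted = np.array(comps)[order]
    consistent = float(np.mean(np.diff(comps_sorted) <= 1e-12))
    return c0, pm.complexity, consistent


def _random_fields(rng, n_anchored, n_place, peak_range=(10.0, 15.0)):
    fields = {}
    for i in range(n_anchored):
        fields[f"anch{i:02d}"] = FieldSpec(
            kind="lever_anchored",
            peak_rate=float(rng.uniform(*peak_range)),
            preferred_direction=float(rng.uniform(-180, 180)),
            # broad directional tuning typical of object-vector-like fields
            concentration=float(rng.uniform(2.0, 4.0)),
            drift_slope=0.0,
            drift_noise_sd=10.0,
        )
    for i in range(n_place):
        fields[f"place{i:02d}"] = FieldSpec(
            kind="place",
            peak_rate=float(rng.uniform(*peak_range)),
            place_center=tuple(rng.uniform(-25, 25, 2)),
            place_sd=8.0,
        )
    return fields


def lever_anchored_recovery(
    seed: int, n_sessions: int = 20, n_trials: int = 50,
    n_anchored: int = 5, n_place: int = 5, n_shuffles: int = 500,
):
    """Sensitivity and false-positive rate of the three-criteria
    lever-anchored classifier on sessions mixing injected lever-anchored and
    world-anchored place fields.  Returns (sensitivity, false_positive_rate)."""
    rng = np.random.default_rng(seed)
    hits = misses = fps = tns = 0
    for k in range(n_sessions):
        fields = _random_fields(rng, n_anchored, n_place)
        session, _ = generate_session(
            BehaviorSpec(n_trials=n_trials), fields, seed=int(rng.integers(2**31))
        )
        trials = segment_trials(session)
        for tr in trials:
            segment_journeys(tr, session)
        for st in session.spikes:
            res = classify_lever_anchored(
                session, trials, st.spike_times, n_shuffles=n_shuffles,
                seed=int(rng.integers(2**31)),
            )
            if st.neuron_id.startswith("anch"):
                hits += res.anchored
                misses += not res.anchored
            else:
                fps += res.anchored
                tns += not res.anchored
    sensitivity = hits / (hits + misses)
    fpr = fps / (fps + tns)
    return float(sensitivity), float(fpr)


def drift_recovery(seed: int, n_trials: int = 50):
    """Circular correlation between injected and recovered per-trial field
    rotations for a lever-anchored neuron with large independent rotations
    (von-Mises-like spread of ~29 degrees)."""
    fields = {
        "la": FieldSpec(
            kind="lever_anchored", peak_rate=12.0, concentration=4.0,
            drift_slope=0.0, drift_noise_sd=28.6,
        )
    }
    session, truth = generate_session(BehaviorSpec(n_trials=n_trials), fields, seed=seed)
    trials = segment_trials(session)
    for tr in trials:
        segment_journeys(tr, session)
    mat = build_trial_matrix(
        session, trials, session.spikes[0].spike_times, "lever_direction",
        phase="at_lever", bin_size=10.0,
    )
    drift = trial_drift(mat)
    injected = truth.drifts["la"][mat.row_meta["trial_id"].to_numpy()]
    ok = np.isfinite(drift.delta_deg)
    return float(circular_correlation(injected[ok], drift.delta_deg[ok]))


def drift_slope_recovery(seed: int, n_trials: int = 100, injected_slope: float = 0.5):
    """Recovered drift-on-homing regression slope for a neuron whose field
    rotation is coupled to the homing direction with the given slope."""
    fields = {
        "la": FieldSpec(
            kind="lever_anchored", peak_rate=12.0, concentration=4.0,
            drift_slope=injected_slope, drift_noise_sd=5.0,
        )
    }
    session, _ = generate_session(BehaviorSpec(n_trials=n_trials), fields, seed=seed)
    trials = segment_trials(session)
    for tr in trials:
        segment_journeys(tr, session)
    mat = build_trial_matrix(
        session, trials, session.spikes[0].spike_times, "lever_direction",
        phase="at_lever", bin_size=10.0,
    )
    drift = trial_drift(mat)
    homing = mat.row_meta["homing_direction"].to_numpy(float)
    _, _, slope = drift_homing_coupling(drift.delta_deg, homing, seed=seed)
    return float(slope)


def coupling_null_type1_error(
    seed: int, n_neurons: int = 200, n_trials: int = 50,
    neurons_per_session: int = 20, alpha: float = 0.05, n_shuffles: int = 500,
):
    """Empirical rejection rate of the drift-homing shuffle test over
    lever-anchored neurons whose rotations are independent of homing."""
    rng = np.random.default_rng(seed)
    n_sessions = int(np.ceil(n_neurons / neurons_per_session))
    rejections = 0
    tested = 0
    for k in range(n_sessions):
        fields = {
            f"n{i:02d}": FieldSpec(
                kind="lever_anchored", peak_rate=12.0, concentration=4.0,
                preferred_direction=float(rng.uniform(-180, 180)),
                drift_slope=0.0, drift_noise_sd=28.6,
            )
            for i in range(min(neurons_per_session, n_neurons - tested))
        }
        session, _ = generate_session(
            BehaviorSpec(n_trials=n_trials), fields, seed=int(rng.integers(2**31))
        )
        trials = segment_trials(session)
        for tr in trials:
            segment_journeys(tr, session)
        for st in session.spikes:
            mat = build_trial_matrix(
                session, trials, st.spike_times, "lever_direction",
                phase="at_lever", bin_size=10.0,
            )
            drift = trial_drift(mat)
            homing = mat.row_meta["homing_direction"].to_numpy(float)
            _, p, _ = drift_homing_coupling(
                drift.delta_deg, homing, n_shuffles=n_shuffles,
                seed=int(rng.integers(2**31)),
            )
            rejections += p < alpha
            tested += 1
    return float(rejections / tested)


def frame_equivariance(seed: int, rotation_deg: float = 90.0, n_trials: int = 50):
    """Effect of a rigid session rotation on the preferred direction in each
    reference frame.

    Returns a dict frame -> absolute circular shift (deg) of the preferred
    direction after rotating positions, lever poses and bridge about the
    arena center.  The cardinal shift should equal the applied rotation;
    bridge and lever frames should be invariant.
    """
    fields = {
        "la": FieldSpec(
            kind="lever_anchored", peak_rate=14.0, concentration=5.0,
            preferred_direction=40.0, drift_slope=0.0, drift_noise_sd=2.0,
        )
    }
    session, _ = generate_session(BehaviorSpec(n_trials=n_trials), fields, seed=seed)
    trials = segment_trials(session)
    for tr in trials:
        segment_journeys(tr, session)
    rotated = rotate_session(session, rotation_deg)
    rotated.validate(canonical=False)
    # journey intervals are time-based, hence rotation-invariant; reuse them
    # with the rotated lever poses
    rot_trials = []
    for tr in trials:
        pose = rotated.lever_pose_at(0.5 * (tr.t_open + min(tr.t_close, tr.t_open + 1.0)))
        cp = TrialRecord(tr.trial_id, tr.t_open, tr.t_close, tr.light, pose, tr.excluded)
        cp.journeys = tr.journeys
        rot_trials.append(cp)
    shifts = {}
    spikes = session.spikes[0].spike_times
    for frame in ("cardinal", "bridge", "lever"):
        t0 = directional_tuning(collect_lever_frame(session, trials, spikes, frame))
        t1 = directional_tuning(collect_lever_frame(rotated, rot_trials, spikes, frame))
        shift = circular_difference(t1.preferred_direction, t0.preferred_direction)
        shifts[frame] = float(shift)
    return shifts


def remapping_contrast(seed: int, n_trials: int = 100, n_neurons: int = 20):
    """Within- and across-condition stability of pair-similarity structure
    for condition-invariant versus fully remapped synthetic place fields.

    Returns dict with keys within_invariant, across_invariant,
    within_remapped, across_remapped (stability r values between the
    Search-Light halves and between Search-Light and Search-Dark).
    """
    rng = np.random.default_rng(seed)
    zone = (-15.0, 15.0, -40.0, 0.0)

    def place_set():
        # fields drawn inside the analysis zone so every neuron contributes
        # signal to the zone-restricted maps
        return {
            f"n{i:02d}": FieldSpec(
                kind="place", peak_rate=float(rng.uniform(10, 15)),
                place_center=(
                    float(rng.uniform(-14, 14)), float(rng.uniform(-38, -2))
                ),
                place_sd=7.0,
            )
            for i in range(n_neurons)
        }

    out = {}
    for label, dark_fields in (("invariant", None), ("remapped", place_set())):
        fields = place_set()
        session, _ = generate_session(
            BehaviorSpec(n_trials=n_trials), fields,
            seed=int(rng.integers(2**31)), fields_dark=dark_fields,
        )
        trials = segment_trials(session)
        for tr in trials:
            segment_journeys(tr, session)
        subsets = condition_partition(session, trials)

        def stab(a, b):
            # drop neurons silent in the zone: search traversals are brief, so
            # the activity threshold sits between the 0.1 Hz baseline and the
            # ~1 Hz condition-mean of an in-zone field
            ma = condition_maps(session, subsets[a], bin_size=2.5, zone=zone, min_rate=0.5)
            mb = condition_maps(session, subsets[b], bin_size=2.5, zone=zone, min_rate=0.5)
            return stability(pair_similarity(ma, a), pair_similarity(mb, b)).r

        out[f"within_{label}"] = float(stab("SL1", "SL2"))
        out[f"across_{label}"] = float(stab("SL1", "SD1"))
    return out


def unit_classification_accuracy(seed: int, n_pyramidal: int = 50, n_interneuron: int = 20):
    """Closed-loop recovery rate of the pyramidal/interneuron classifier on
    synthetic unit features."""
    features, truth = generate_unit_features(n_pyramidal, n_interneuron, seed=seed)
    predicted = classify_units(features, seed=seed)
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def behavior_summary(seed: int, n_trials: int = 100):
    """Light/dark behavioral contrast of one synthetic session: median homing
    errors, search-length/error correlation in the dark, and the
    light-versus-dark classifier accuracy."""
    session, _ = generate_session(BehaviorSpec(n_trials=n_trials), {}, seed=seed)
    trials = segment_trials(session)
    for tr in trials:
        segment_journeys(tr, session)
    feats = trial_path_features(session, trials)
    dark = feats[~feats["light"]]
    light = feats[feats["light"]]
    acc, _ = light_dark_classifier(feats, feats["light"], seed=seed)
    return {
        "median_error_light": float(light["error_at_periphery"].median()),
        "median_error_dark": float(dark["error_at_periphery"].median()),
        "dark_search_error_corr": float(
            np.corrcoef(dark["search_length"], dark["error_at_periphery"])[0, 1]
        ),
        "light_dark_accuracy": float(acc),
    }
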