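"""End-to-end orchestration: simulate -> segment -> analyze, with config and
reproducible seeds.

``run_pipeline`` executes the per-session stages in order (behavior,
1D/2D firing-rate summaries, trial matrices, lever-frame analysis,
remapping, spike-train QC) and writes one TSV per stage plus a YAML manifest
recording the full configuration, so a rerun with the same config reproduces
the outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import lever_frame as lf
from . import remapping as rmp
from . import trial_matrix as tm
from .cell_classify import ClassificationError, refractory_ratio
from .data_model import Session, read_session
from .maps import ACTIVE_RATE_HZ, MapError, histogram_range, information_score, rate_histogram_1d
from .data_model import dwell_times, lever_wall_distance


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All tunable analysis parameters with their default thresholds."""

    seed: int = 0
    frame: str = "cardinal"
    map_bin_cm: float = 3.0
    map_smooth_cm: float = 5.0
    lever_map_bin_cm: float = 1.0
    lever_map_smooth_cm: float = 2.0
    hist_nbins: int = 20
    active_rate_hz: float = ACTIVE_RATE_HZ
    peak_rate_threshold_hz: float = lf.PEAK_RATE_THRESHOLD_HZ
    split_half_threshold: float = lf.SPLIT_HALF_THRESHOLD
    peak_distance_threshold_cm: float = lf.PEAK_DISTANCE_THRESHOLD_CM
    lever_frame_max_wall_cm: float = lf.LEVER_FRAME_MAX_WALL_CM
    lever_center_max_radius_cm: float = 30.0
    n_shuffles: int = 500
    alpha: float = 0.05
    out_dir: str = "homefield_out"

    def validate(self) -> "PipelineConfig":
        if self.hist_nbins < 1:
            raise ConfigError("hist_nbins must be >= 1")
        if self.frame not in lf.FRAMES:
            raise ConfigError(f"unknown frame {self.frame!r}")
        if self.map_bin_cm <= 0 or self.lever_map_bin_cm <= 0:
            raise ConfigError("bin sizes must be positive")
        if self.n_shuffles < 1:
            raise ConfigError("n_shuffles must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def analyze_behavior(session: Session) -> pd.DataFrame:
    """Segment trials/journeys and compute per-journey path metrics."""
    trials = bhv.segment_trials(session)
    for tr in trials:
        bhv.segment_journeys(tr, session)
    return bhv.trial_path_features(session, trials)


def analyze_histograms(session: Session, trials, config: PipelineConfig) -> pd.DataFrame:
    """Per-neuron information scores of the 1D firing rate histograms in the
    four task conditions (search/homing x light/dark), for the y coordinate
    and the lever distance."""
    t = session.positions["t"].to_numpy(float)
    x = session.positions["x"].to_numpy(float)
    y = session.positions["y"].to_numpy(float)
    dwell = dwell_times(t)
    cond_masks: dict[tuple[str, bool], np.ndarray] = {}
    cond_wall: dict[tuple[str, bool], np.ndarray] = {}
    for phase in ("search", "homing"):
        for light in (True, False):
            mask = np.zeros(t.size, bool)
            wall = np.full(t.size, np.nan)
            for tr in trials:
                if tr.excluded or tr.light != light:
                    continue
                for j in tr.journeys:
                    iv = j.search_interval if phase == "search" else j.homing_interval
                    if not (j.lever_pressed and iv):
                        continue
                    m = (t >= iv[0]) & (t <= iv[1])
                    mask |= m
                    wall[m] = lever_wall_distance(
                        x[m], y[m], tr.lever_pose, session.geometry
                    )
            cond_masks[(phase, light)] = mask
            cond_wall[(phase, light)] = wall
    rows = []
    for variable in ("y_coordinate", "lever_distance"):
        for phase in ("search", "homing"):
            vl = (
                y[cond_masks[(phase, True)]]
                if variable == "y_coordinate"
                else cond_wall[(phase, True)][cond_masks[(phase, True)]]
            )
            vd = (
                y[cond_masks[(phase, False)]]
                if variable == "y_coordinate"
                else cond_wall[(phase, False)][cond_masks[(phase, False)]]
            )
            if vl.size == 0 or vd.size == 0:
                continue
            rng_ = histogram_range(vl, vd, variable)
            for light in (True, False):
                mask = cond_masks[(phase, light)]
                vals = y[mask] if variable == "y_coordinate" else cond_wall[(phase, light)][mask]
                total = dwell[mask].sum()
                for st in session.spikes:
                    sm = np.zeros(st.spike_times.size, bool)
                    for tr in trials:
                        if tr.excluded or tr.light != light:
                            continue
                        for j in tr.journeys:
                            iv = j.search_interval if phase == "search" else j.homing_interval
                            if j.lever_pressed and iv:
                                sm |= (st.spike_times >= iv[0]) & (st.spike_times <= iv[1])
                    mean_rate = sm.sum() / total if total > 0 else 0.0
                    if mean_rate < config.active_rate_hz:
                        continue
                    sx = np.interp(st.spike_times[sm], t, x)
                    sy = np.interp(st.spike_times[sm], t, y)
                    if variable == "y_coordinate":
                        sv = sy
                    else:
                        # nearest-sample lever distance for the spike
                        idx = np.clip(np.searchsorted(t, st.spike_times[sm]) - 1, 0, t.size - 1)
                        sv = cond_wall[(phase, light)][idx]
                        sv = sv[np.isfinite(sv)]
                    try:
                        hist = rate_histogram_1d(vals, dwell[mask], sv, rng_, variable)
                        score = information_score(hist)
                    except MapError:
                        continue
                    rows.append(
                        {
                            "neuron_id": st.neuron_id,
                            "variable": variable,
                            "phase": phase,
                            "light": light,
                            "mean_rate": mean_rate,
                            "information_score": score,
                        }
                    )
    return pd.DataFrame(rows)


def analyze_trial_matrices(session: Session, trials, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for st in session.spikes:
        for variable, phase in (("y_coordinate", "search"), ("y_coordinate", "homing"),
                                ("lever_distance", "search"), ("lever_distance", "homing")):
            for light in (True, False):
                try:
                    mat = tm.build_trial_matrix(
                        session, trials, st.spike_times, variable, phase=phase, light=light
                    )
                    corr = tm.trial_matrix_correlation(mat)
                except tm.TrialMatrixError:
                    continue
                rows.append(
                    {
                        "neuron_id": st.neuron_id,
                        "variable": variable,
                        "phase": phase,
                        "light": light,
                        "trial_matrix_correlation": corr.value,
                        "n_pairs": corr.n_pairs,
                    }
                )
    return pd.DataFrame(rows)


def analyze_lever(session: Session, trials, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for st in session.spikes:
        for light in (True, False):
            try:
                res = lf.classify_lever_anchored(
                    session, trials, st.spike_times, frame=config.frame, light=light,
                    n_shuffles=config.n_shuffles, seed=config.seed,
                )
                data = lf.collect_lever_frame(
                    session, trials, st.spike_times, config.frame, light
                )
                tuning = lf.directional_tuning(data)
            except lf.LeverFrameError:
                continue
            row = {
                "neuron_id": st.neuron_id,
                "light": light,
                "frame": config.frame,
                "anchored": res.anchored,
                "peak_near_lever": res.peak_near_lever,
                "peak_rate_ok": res.peak_rate_ok,
                "split_half_stable": res.split_half_stable,
                "mvl": tuning.mvl,
                "preferred_direction": tuning.preferred_direction,
                "peak_rate": tuning.peak_rate,
            }
            if res.anchored:
                try:
                    mat = tm.build_trial_matrix(
                        session, trials, st.spike_times, "lever_direction",
                        phase="at_lever", light=light, bin_size=10.0,
                    )
                    drift = lf.trial_drift(mat)
                    homing = mat.row_meta["homing_direction"].to_numpy(float)
                    r, p, slope = lf.drift_homing_coupling(
                        drift.delta_deg, homing, n_shuffles=config.n_shuffles,
                        seed=config.seed,
                    )
                    row.update(drift_homing_r=r, drift_homing_p=p, drift_homing_slope=slope)
                except (tm.TrialMatrixError, lf.LeverFrameError):
                    pass
            rows.append(row)
    return pd.DataFrame(rows)


def analyze_remapping(session: Session, trials, config: PipelineConfig) -> pd.DataFrame:
    subsets = rmp.condition_partition(session, trials)
    zone = (-15.0, 15.0, -40.0, 0.0)
    sims = {}
    for label in ("SL1", "SL2", "SD1", "SD2", "HL1", "HL2", "HD1", "HD2"):
        try:
            maps = rmp.condition_maps(session, subsets[label], bin_size=2.5,
                                      smoothing_sd=config.map_smooth_cm, zone=zone)
            sims[label] = rmp.pair_similarity(maps, label)
        except rmp.RemappingError:
            continue
    rows = []
    comparisons = [
        ("SL1", "SL2"), ("SD1", "SD2"), ("HL1", "HL2"), ("HD1", "HD2"),
        ("SL1", "SD1"), ("HL1", "HD1"), ("SL1", "HL1"), ("SD1", "HD1"),
    ]
    for a, b in comparisons:
        if a in sims and b in sims:
            try:
                s = rmp.stability(sims[a], sims[b])
            except rmp.RemappingError:
                continue
            rows.append({"condition_a": a, "condition_b": b, "r": s.r, "n_pairs": s.n_pairs})
    return pd.DataFrame(rows)


def analyze_units(session: Session) -> pd.DataFrame:
    rows = []
    for st in session.spikes:
        duration = session.t_end - session.t_start
        rate = st.spike_times.size / duration if duration > 0 else 0.0
        try:
            ratio = refractory_ratio(st.spike_times)
            accepted = np.isfinite(ratio) and ratio <= 0.25
        except ClassificationError:
            ratio, accepted = float("nan"), False
        rows.append(
            {
                "neuron_id": st.neuron_id,
                "mean_rate": rate,
                "refractory_ratio": ratio,
                "accepted": accepted,
            }
        )
    return pd.DataFrame(rows)


STAGES = ("behavior", "histograms", "trial_matrices", "lever", "remapping", "units")


def run_pipeline(
    config: PipelineConfig,
    session_paths: Optional[list] = None,
    sessions: Optional[list[Session]] = None,
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage over the given sessions and write the per-
    stage TSVs plus a manifest into ``config.out_dir``."""
    config.validate()
    if sessions is None:
        sessions = [read_session(p) for p in (session_paths or [])]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, list[pd.DataFrame]] = {s: [] for s in STAGES}
    for idx, session in enumerate(sessions):
        sid = str(session.metadata.get("animal_id", idx))
        trials = bhv.segment_trials(session)
        for tr in trials:
            bhv.segment_journeys(tr, session)
        stage_frames = {
            "behavior": bhv.trial_path_features(session, trials),
            "histograms": analyze_histograms(session, trials, config),
            "trial_matrices": analyze_trial_matrices(session, trials, config),
            "lever": analyze_lever(session, trials, config),
            "remapping": analyze_remapping(session, trials, config),
            "units": analyze_units(session),
        }
        for name, df in stage_frames.items():
            if not df.empty:
                df.insert(0, "session", sid)
            results[name].append(df)
    merged = {
        name: (pd.concat(dfs, ignore_index=True) if dfs else pd.DataFrame())
        for name, dfs in results.items()
    }
    for name, df in merged.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    manifest = {"config": asdict(config), "config_digest": config.digest(),
                "n_sessions": len(sessions)}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return merged
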