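"""Single-trial firing-rate matrices and their reliability statistics.

A trial matrix holds one neuron's firing rate with one row per lever-pressed
journey and columns binning a behavioral variable: the animal's y coordinate
(2 cm bins), its distance from the lever box (2 cm bins), or its direction
around the lever-box center (20 degree bins, circular).  Rows are smoothed
with a 1D Gaussian kernel (SD 2 bins).  The *trial matrix correlation* — the
mean Pearson correlation over all distinct row pairs — measures how reliable
the firing pattern is across trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import Journey, TrialRecord, homing_geometry
from .circular import angle_from_south
from .data_model import Session, dwell_times, lever_wall_distance
from .maps import _masked_smooth


class TrialMatrixError(ValueError):
    pass


DEFAULT_BIN_SIZE = {"y_coordinate": 2.0, "lever_distance": 2.0, "lever_direction": 20.0}
DEFAULT_RANGE = {
    "y_coordinate": (-42.5, 40.0),
    "lever_distance": (0.0, 30.0),
    "lever_direction": (-180.0, 180.0),
}
ROW_SMOOTHING_SD_BINS = 2.0
MIN_OCCUPIED_BINS = 5


@dataclass
class TrialMatrix:
    variable: str
    bin_edges: np.ndarray
    rate: np.ndarray  # rows x bins, smoothed; NaN in unvisited bins
    raw_rate: np.ndarray
    row_meta: pd.DataFrame  # trial_id, lever_y, homing_direction, light

    @property
    def circular(self) -> bool:
        return self.variable == "lever_direction"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_rows(self) -> int:
        return self.rate.shape[0]


@dataclass(frozen=True)
class TrialMatrixCorrelation:
    value: float
    n_pairs: int
    n_excluded_rows: int = 0


def _journey_phase_interval(journey: Journey, phase: str):
    if phase == "search":
        return journey.search_interval
    if phase == "homing":
        return journey.homing_interval
    if phase == "at_lever":
        return journey.at_lever_interval
    if phase == "journey":
        return (journey.t_start, journey.t_end)
    raise TrialMatrixError(f"unknown phase {phase!r}")


def build_trial_matrix(
    session: Session,
    trials: Sequence[TrialRecord],
    spike_times: np.ndarray,
    variable: str,
    phase: str = "journey",
    light: Optional[bool] = None,
    bin_size: Optional[float] = None,
    value_range: Optional[tuple[float, float]] = None,
    smoothing_sd_bins: float = ROW_SMOOTHING_SD_BINS,
) -> TrialMatrix:
    """Build a trial matrix from the lever-pressed journeys of ``trials``.

    ``phase`` restricts each row to the search, homing or at-lever part of
    the journey (or the whole journey).  ``light`` filters trials by
    condition.  Rows occupying fewer than 5 bins are dropped; fewer than 2
    surviving rows is an error.
    """
    if variable not in DEFAULT_BIN_SIZE:
        raise TrialMatrixError(f"unknown variable {variable!r}")
    bin_size = bin_size or DEFAULT_BIN_SIZE[variable]
    lo, hi = value_range or DEFAULT_RANGE[variable]
    edges = np.arange(lo, hi + 0.5 * bin_size, bin_size)
    n_bins = edges.size - 1
    circular = variable == "lever_direction"
    spike_times = np.asarray(spike_times, float)
    t = session.positions["t"].to_numpy(float)
    x = session.positions["x"].to_numpy(float)
    y = session.positions["y"].to_numpy(float)
    dwell = dwell_times(t)
    rows, raw_rows, meta = [], [], []
    for tr in trials:
        if tr.excluded or (light is not None and tr.light != light):
            continue
        for j in tr.journeys:
            if not j.lever_pressed:
                continue
            interval = _journey_phase_interval(j, phase)
            if interval is None:
                continue
            m = (t >= interval[0]) & (t <= interval[1])
            if not np.any(m):
                continue
            if variable == "y_coordinate":
                vals = y[m]
            elif variable == "lever_distance":
                vals = lever_wall_distance(x[m], y[m], tr.lever_pose, session.geometry)
            else:
                vals = angle_from_south(
                    x[m] - tr.lever_pose.center[0], y[m] - tr.lever_pose.center[1]
                )
            sm = (spike_times >= interval[0]) & (spike_times <= interval[1])
            # evaluate the variable at spike positions (position interpolation
            # rather than value interpolation: direction wraps at +-180)
            sx = np.interp(spike_times[sm], t[m], x[m])
            sy = np.interp(spike_times[sm], t[m], y[m])
            if variable == "y_coordinate":
                sv = sy
            elif variable == "lever_distance":
                sv = lever_wall_distance(sx, sy, tr.lever_pose, session.geometry)
            else:
                sv = angle_from_south(
                    sx - tr.lever_pose.center[0], sy - tr.lever_pose.center[1]
                )
            occ, _ = np.histogram(vals, bins=edges, weights=dwell[m])
            spk, _ = np.histogram(sv, bins=edges)
            valid = occ > 0
            if valid.sum() < MIN_OCCUPIED_BINS:
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = np.where(valid, spk / occ, np.nan)
            smoothed = _masked_smooth(
                np.where(valid, raw, 0.0), valid, smoothing_sd_bins, wrap=circular
            )
            rows.append(smoothed)
            raw_rows.append(raw)
            if j.periphery_arrival is not None:
                hdir = homing_geometry(j, tr, session.geometry).homing_direction
            else:
                hdir = np.nan
            meta.append(
                {
                    "trial_id": tr.trial_id,
                    "lever_y": tr.lever_pose.center[1],
                    "homing_direction": hdir,
                    "light": tr.light,
                }
            )
    if len(rows) < 2:
        raise TrialMatrixError("need at least 2 usable lever-pressed journeys")
    return TrialMatrix(
        variable=variable,
        bin_edges=edges,
        rate=np.vstack(rows),
        raw_rate=np.vstack(raw_rows),
        row_meta=pd.DataFrame(meta),
    )


def _pairwise_mean_correlation(rate: np.ndarray) -> TrialMatrixCorrelation:
    finite = np.isfinite(rate)
    keep = []
    for i in range(rate.shape[0]):
        v = rate[i, finite[i]]
        if v.size >= 3 and np.std(v) > 0:
            keep.append(i)
    n_excluded = rate.shape[0] - len(keep)
    if len(keep) < 2:
        raise TrialMatrixError("fewer than 2 rows with nonzero variance")
    rs = []
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            i, j = keep[a], keep[b]
            m = finite[i] & finite[j]
            if m.sum() < 3:
                continue
            vi, vj = rate[i, m], rate[j, m]
            if vi.std() == 0 or vj.std() == 0:
                continue
            rs.append(np.corrcoef(vi, vj)[0, 1])
    if not rs:
        raise TrialMatrixError("no valid row pairs")
    return TrialMatrixCorrelation(
        value=float(np.mean(rs)), n_pairs=len(rs), n_excluded_rows=n_excluded
    )


def trial_matrix_correlation(matrix: TrialMatrix) -> TrialMatrixCorrelation:
    """Mean Pearson correlation over all distinct row pairs (the off-diagonal
    of the row-by-row correlation matrix).  Zero-variance rows are excluded
    and counted."""
    return _pairwise_mean_correlation(matrix.rate)


def _shuffle_rows(rate: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute the rate values within each row (finite entries only), exactly
    preserving each row's multiset of values."""
    out = rate.copy()
    for i in range(out.shape[0]):
        idx = np.flatnonzero(np.isfinite(out[i]))
        out[i, idx] = out[i, rng.permutation(idx)]
    return out


def trial_matrix_correlation_significance(
    matrix: TrialMatrix, n_shuffles: int = 500, seed: int = 0, alpha: float = 0.05
):
    """Significance of the trial matrix correlation against a within-row
    shuffle null.  Returns (observed, p, significant)."""
    obs = trial_matrix_correlation(matrix).value
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        try:
            null[k] = _pairwise_mean_correlation(_shuffle_rows(matrix.rate, rng)).value
        except TrialMatrixError:
            null[k] = 0.0
    p = float((np.sum(null >= obs) + 1) / (n_shuffles + 1))
    return obs, p, p < alpha


def _row_peaks(rate: np.ndarray, centers: np.ndarray, circular: bool) -> np.ndarray:
    """Peak location per row; ties resolved toward the row's center of mass."""
    peaks = np.empty(rate.shape[0])
    for i in range(rate.shape[0]):
        row = rate[i]
        finite = np.isfinite(row)
        vals = np.where(finite, row, -np.inf)
        mx = vals.max()
        tied = np.flatnonzero(vals == mx)
        if tied.size == 1:
            peaks[i] = centers[tied[0]]
            continue
        w = np.where(finite & (row > 0), row, 0.0)
        if circular:
            ang = np.radians(centers)
            if w.sum() > 0:
                com = np.degrees(
                    np.arctan2(np.sum(w * np.sin(ang)), np.sum(w * np.cos(ang)))
                )
            else:
                com = 0.0
            d = np.abs((centers[tied] - com + 180.0) % 360.0 - 180.0)
        else:
            com = np.sum(w * centers) / w.sum() if w.sum() > 0 else centers.mean()
            d = np.abs(centers[tied] - com)
        peaks[i] = centers[tied[np.argmin(d)]]
    return peaks


def peak_location_vs_lever(
    matrix: TrialMatrix,
    n_shuffles: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Test whether per-row peak locations track the lever's y position.

    r = Pearson(row peak locations, lever y positions).  The null permutes
    the rate values within each row (``n_shuffles`` times) and recomputes r;
    the correlation is significant when the observed r exceeds the null's
    95th percentile.  Returns (r, p, significant).
    """
    if matrix.variable != "y_coordinate":
        raise TrialMatrixError("peak-vs-lever test requires a y-coordinate matrix")
    if matrix.n_rows < 5:
        raise TrialMatrixError("need at least 5 usable rows")
    lever_y = matrix.row_meta["lever_y"].to_numpy(float)
    if np.std(lever_y) == 0:
        raise TrialMatrixError("lever position is constant")
    centers = matrix.bin_centers
    obs_peaks = _row_peaks(matrix.rate, centers, circular=False)
    r = float(np.corrcoef(obs_peaks, lever_y)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = _shuffle_rows(matrix.rate, rng)
        pk = _row_peaks(shuffled, centers, circular=False)
        if np.std(pk) == 0:
            null[k] = 0.0
        else:
            null[k] = np.corrcoef(pk, lever_y)[0, 1]
    p = float((np.sum(null >= r) + 1) / (n_shuffles + 1))
    significant = r > np.percentile(null, 100.0 * (1.0 - alpha))
    return r, p, bool(significant)
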