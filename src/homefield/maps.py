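"""2D firing-rate maps, 1D firing-rate histograms, and information scores.

Standard arena maps use 3 cm bins smoothed with a 5 cm SD Gaussian;
lever-centered maps use 1 cm bins and a 2 cm SD kernel.  The 1D histograms
(firing rate versus y coordinate or versus distance from the lever box)
always contain 20 bins; occupancy is smoothed (SD 1 bin), rate =
spikes / smoothed occupancy, then the rate is smoothed again (SD 1 bin).
Information scores are computed from the unsmoothed occupancy and rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .data_model import dwell_times

N_HIST_BINS = 20
Y_HIST_MIN = -42.5  # cm: gap between the arena and the bridge
LEVER_DIST_HIST_MIN = 12.0  # cm
ACTIVE_RATE_HZ = 2.0  # "active neuron" mean-rate threshold


class MapError(ValueError):
    pass


@dataclass
class RateMap2D:
    bin_size: float
    origin: tuple[float, float]  # position of the lower edge of bin (0, 0)
    occupancy: np.ndarray  # s, smoothed
    rate: np.ndarray  # Hz, NaN outside the valid mask
    smoothing_sd: float
    valid_mask: np.ndarray
    raw_occupancy: np.ndarray | None = None  # s, pre-smoothing
    raw_rate: np.ndarray | None = None  # Hz, spikes / raw occupancy

    @property
    def peak_rate(self) -> float:
        if not np.any(self.valid_mask):
            return float("nan")
        return float(np.nanmax(self.rate))


@dataclass
class RateHistogram1D:
    variable: str  # {y_coordinate, lever_distance}
    bin_edges: np.ndarray  # 21 edges
    occupancy: np.ndarray  # s per bin, smoothed
    rate: np.ndarray  # Hz per bin, smoothed; NaN where masked
    raw_occupancy: np.ndarray
    raw_rate: np.ndarray
    mean_rate: float  # overall spikes / overall time

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _masked_smooth(values: np.ndarray, valid: np.ndarray, sigma_bins: float,
                   wrap: bool = False) -> np.ndarray:
    """Gaussian smoothing with the kernel renormalized over valid bins, so
    mass never bleeds in from outside the sampled region."""
    mode = "wrap" if wrap else "constant"
    if sigma_bins <= 0:
        return np.where(valid, values, np.nan)
    v = np.where(valid, values, 0.0)
    if values.ndim == 1:
        num = gaussian_filter1d(v, sigma_bins, mode=mode)
        den = gaussian_filter1d(valid.astype(float), sigma_bins, mode=mode)
    else:
        num = gaussian_filter(v, sigma_bins, mode=mode)
        den = gaussian_filter(valid.astype(float), sigma_bins, mode=mode)
    out = np.full(values.shape, np.nan)
    ok = valid & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def interpolate_spike_positions(positions, spike_times: np.ndarray):
    """Spike (x, y) by linear interpolation of the tracked position."""
    t = positions["t"].to_numpy(float)
    sx = np.interp(spike_times, t, positions["x"].to_numpy(float))
    sy = np.interp(spike_times, t, positions["y"].to_numpy(float))
    return sx, sy


def rate_map_2d(
    positions,
    spike_times: np.ndarray,
    bin_size: float = 3.0,
    smoothing_sd: float = 5.0,
    extent: float | None = None,
) -> RateMap2D:
    """Occupancy-normalized 2D firing rate map.

    Occupancy (per-sample dwell time) is smoothed with a Gaussian kernel;
    spike counts per bin are divided by the smoothed occupancy and the
    resulting rate map is smoothed with the same kernel.  Bins never visited
    before smoothing are masked.
    """
    if bin_size <= 0:
        raise MapError("bin_size must be positive")
    t = positions["t"].to_numpy(float)
    x = positions["x"].to_numpy(float)
    y = positions["y"].to_numpy(float)
    if t.size == 0:
        raise MapError("zero total occupancy")
    dwell = dwell_times(t)
    if extent is None:
        lo_x, hi_x = x.min(), x.max()
        lo_y, hi_y = y.min(), y.max()
        lo = min(lo_x, lo_y) - bin_size
        hi = max(hi_x, hi_y) + bin_size
    else:
        lo, hi = -extent, extent
    edges = np.arange(lo, hi + bin_size, bin_size)
    occ, _, _ = np.histogram2d(x, y, bins=(edges, edges), weights=dwell)
    if occ.sum() <= 0:
        raise MapError("zero total occupancy")
    spike_times = np.asarray(spike_times, float)
    inside = (spike_times >= t[0]) & (spike_times <= t[-1])
    sx, sy = interpolate_spike_positions(positions, spike_times[inside])
    spk, _, _ = np.histogram2d(sx, sy, bins=(edges, edges))
    valid = occ > 0
    sigma = smoothing_sd / bin_size
    occ_s = _masked_smooth(occ, valid, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(valid, spk / occ_s, np.nan)
    rate_s = _masked_smooth(np.where(valid, rate, 0.0), valid, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_rate = np.where(valid, spk / occ, np.nan)
    return RateMap2D(
        bin_size=bin_size,
        origin=(float(edges[0]), float(edges[0])),
        occupancy=np.where(valid, occ_s, np.nan),
        rate=rate_s,
        smoothing_sd=smoothing_sd,
        valid_mask=valid,
        raw_occupancy=occ,
        raw_rate=raw_rate,
    )


def map_similarity(a: RateMap2D, b: RateMap2D) -> float:
    """Pearson correlation between two rate maps over jointly valid bins."""
    if a.rate.shape != b.rate.shape:
        raise MapError("maps must share their grid")
    m = a.valid_mask & b.valid_mask & np.isfinite(a.rate) & np.isfinite(b.rate)
    if m.sum() < 3:
        raise MapError("too few jointly valid bins")
    va, vb = a.rate[m], b.rate[m]
    if va.std() == 0 or vb.std() == 0:
        raise MapError("constant map; similarity undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def histogram_range(values_light, values_dark, variable: str) -> tuple[float, float]:
    """Shared histogram range for a behavioral variable across conditions.

    The maximum is the smaller of the two conditions' 90th percentiles
    (linear interpolation); the minimum is fixed per variable: -42.5 cm for
    the y coordinate (the arena-bridge gap) and 12.0 cm for the distance from
    the lever box.
    """
    values_light = np.asarray(values_light, float)
    values_dark = np.asarray(values_dark, float)
    if values_light.size == 0 or values_dark.size == 0:
        raise MapError("both conditions must be non-empty")
    hi = min(
        float(np.percentile(values_light, 90)), float(np.percentile(values_dark, 90))
    )
    if variable == "y_coordinate":
        lo = Y_HIST_MIN
    elif variable == "lever_distance":
        lo = LEVER_DIST_HIST_MIN
    else:
        raise MapError(f"unknown variable {variable!r}")
    return lo, hi


def rate_histogram_1d(
    values: np.ndarray,
    dwell: np.ndarray,
    spike_values: np.ndarray,
    value_range: tuple[float, float],
    variable: str = "y_coordinate",
    smoothing_sd_bins: float = 1.0,
) -> RateHistogram1D:
    """20-bin firing rate histogram of a behavioral variable.

    ``values``/``dwell`` are the per-sample variable values and dwell times
    (paths of one condition pooled); ``spike_values`` is the variable
    evaluated at each spike.  Bins with zero pre-smoothing occupancy are
    masked with a warning.
    """
    lo, hi = value_range
    if not hi > lo:
        raise MapError("empty histogram range")
    edges = np.linspace(lo, hi, N_HIST_BINS + 1)
    occ, _ = np.histogram(values, bins=edges, weights=dwell)
    spk, _ = np.histogram(spike_values, bins=edges)
    valid = occ > 0
    if not np.all(valid):
        warnings.warn(f"{int((~valid).sum())} histogram bins have zero occupancy")
    occ_s = _masked_smooth(occ, valid, smoothing_sd_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(valid & (occ_s > 0), spk / occ_s, np.nan)
        raw_rate = np.where(valid, spk / occ, np.nan)
    rate_s = _masked_smooth(np.where(valid, rate, 0.0), valid, smoothing_sd_bins)
    total_time = occ.sum()
    mean_rate = float(spk[valid].sum() / total_time) if total_time > 0 else 0.0
    return RateHistogram1D(
        variable=variable,
        bin_edges=edges,
        occupancy=occ_s,
        rate=rate_s,
        raw_occupancy=occ,
        raw_rate=raw_rate,
        mean_rate=mean_rate,
    )


def information_score(hist: RateHistogram1D) -> float:
    """Spatial information in bits per spike.

    sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda) over valid bins,
    where p_i is the occupancy probability of bin i and lambda the
    occupancy-weighted mean rate.  Computed from the **unsmoothed** occupancy
    and rates; 0 * log 0 is taken as 0.
    """
    occ = hist.raw_occupancy
    rate = hist.raw_rate
    valid = (occ > 0) & np.isfinite(rate)
    if not np.any(valid):
        raise MapError("no valid bins")
    p = occ[valid] / occ[valid].sum()
    lam = float(np.sum(p * rate[valid]))
    if lam <= 0:
        raise MapError("mean rate is zero; information undefined")
    ratio = rate[valid] / lam
    terms = np.zeros_like(ratio)
    nz = ratio > 0
    terms[nz] = p[nz] * ratio[nz] * np.log2(ratio[nz])
    return float(terms.sum())
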