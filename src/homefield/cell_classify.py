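"""Spike-train quality control and pyramidal/interneuron classification.

Cluster quality is screened with the refractory ratio: the mean of the
spike-time autocorrelation bins from 0 to 1.5 ms divided by the maximum bin
between 5 and 25 ms (0.5 ms bins); units with a ratio above 0.25 are
discarded.  Units are then classified by reducing the mean waveform and the
autocorrelation to three principal components each, appending the mean firing
rate (7 features), standardizing, and running 2-means clustering; the
cluster with the lower mean firing rate is labeled pyramidal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

AUTOCORR_BIN_MS = 0.5
AUTOCORR_MAX_MS = 25.0
REFRACTORY_WINDOW_MS = 1.5
COMPARISON_MIN_MS = 5.0
REFRACTORY_REJECT_RATIO = 0.25
MIN_SPIKES = 100


class ClassificationError(ValueError):
    pass


@dataclass
class UnitFeatures:
    mean_rate: float  # Hz
    waveform: np.ndarray
    autocorrelation: np.ndarray  # 50 bins of 0.5 ms over (0, 25] ms
    refractory_ratio: Optional[float] = None


def spike_time_autocorrelation(
    spike_times: np.ndarray,
    bin_ms: float = AUTOCORR_BIN_MS,
    max_ms: float = AUTOCORR_MAX_MS,
) -> np.ndarray:
    """Counts of spike-pair lags in (0, max_ms] at ``bin_ms`` resolution."""
    t = np.sort(np.asarray(spike_times, float))
    max_s = max_ms / 1000.0
    edges = np.arange(0.0, max_ms + bin_ms, bin_ms) / 1000.0
    counts = np.zeros(edges.size - 1)
    # sliding window: for each spike, lags to subsequent spikes within max_ms
    j_hi = np.searchsorted(t, t + max_s, side="right")
    for i in range(t.size):
        lags = t[i + 1 : j_hi[i]] - t[i]
        if lags.size:
            counts += np.histogram(lags, bins=edges)[0]
    return counts


def refractory_ratio(spike_times: np.ndarray) -> float:
    """Mean autocorrelation in (0, 1.5] ms over the maximum bin in [5, 25] ms.

    Near zero for a unit with a clean refractory period, near 1 for a
    homogeneous Poisson train.  Units with a ratio above 0.25 fail quality
    control (:func:`passes_refractory_criterion`).
    """
    t = np.asarray(spike_times, float)
    if t.size < MIN_SPIKES:
        raise ClassificationError(f"need at least {MIN_SPIKES} spikes, got {t.size}")
    ac = spike_time_autocorrelation(t)
    lags = (np.arange(ac.size) + 0.5) * AUTOCORR_BIN_MS
    early = ac[lags <= REFRACTORY_WINDOW_MS]
    late = ac[lags >= COMPARISON_MIN_MS]
    denom = late.max() if late.size else 0.0
    if denom <= 0:
        return float("inf")  # undefined; unit rejected
    return float(early.mean() / denom)


def passes_refractory_criterion(spike_times: np.ndarray) -> bool:
    r = refractory_ratio(spike_times)
    return np.isfinite(r) and r <= REFRACTORY_REJECT_RATIO


def _normalize_waveform(wf: np.ndarray) -> np.ndarray:
    """Peak-align (trough to center) and amplitude-normalize a waveform."""
    wf = np.asarray(wf, float)
    trough = int(np.argmin(wf))
    wf = np.roll(wf, wf.size // 2 - trough)
    amp = np.abs(wf).max()
    return wf / amp if amp > 0 else wf


def classify_units(
    features: Sequence[UnitFeatures], seed: int = 0, log_rate: bool = False
) -> list[str]:
    """Label each unit 'pyramidal' or 'interneuron'.

    PCA (3 components) of the aligned, normalized waveforms and of the
    autocorrelations plus the mean rate gives 7 standardized features for
    2-means clustering (best of 10 fixed-seed restarts); the lower-rate
    cluster is pyramidal.  ``log_rate`` optionally log-transforms the mean
    rate before clustering.
    """
    if len(features) < 4:
        raise ClassificationError("need at least 4 units")
    wf = np.vstack([_normalize_waveform(f.waveform) for f in features])
    ac = np.vstack([np.asarray(f.autocorrelation, float) for f in features])
    ac_sums = ac.sum(axis=1, keepdims=True)
    ac = np.divide(ac, ac_sums, out=np.zeros_like(ac), where=ac_sums > 0)
    rates = np.array([f.mean_rate for f in features])
    if log_rate:
        rates = np.log(np.maximum(rates, 1e-3))
    if np.linalg.matrix_rank(np.column_stack([wf, ac, rates])) < 2:
        raise ClassificationError("degenerate feature matrix")
    pcs_wf = PCA(n_components=3, random_state=seed).fit_transform(wf)
    pcs_ac = PCA(n_components=3, random_state=seed).fit_transform(ac)
    X = np.column_stack([pcs_wf, pcs_ac, rates])
    X = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    mean_rates = [rates[km.labels_ == k].mean() for k in (0, 1)]
    pyramidal_cluster = int(np.argmin(mean_rates))
    return [
        "pyramidal" if lbl == pyramidal_cluster else "interneuron"
        for lbl in km.labels_
    ]
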