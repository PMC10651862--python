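"""Circular statistics helpers.

All public functions take and return angles in **degrees** (the package-wide
API convention); radians are used internally.  Angles are wrapped to
[-180, 180) with counterclockwise positive.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_degrees",
    "angle_from_south",
    "mean_vector_length",
    "weighted_mean_vector",
    "circular_mean",
    "circular_difference",
    "circular_correlation",
    "rayleigh_test",
]


def wrap_degrees(angle):
    """Wrap angles (deg) to the half-open interval [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def angle_from_south(dx, dy):
    """Signed angle (deg) of vector (dx, dy) measured from south (0, -1).

    Counterclockwise positive: east is +90, north is +-180, west is -90.
    """
    return np.degrees(np.arctan2(np.asarray(dx, float), -np.asarray(dy, float)))


def mean_vector_length(angles_deg, weights=None):
    """Resultant length of unit vectors at ``angles_deg``.

    With ``weights`` (e.g. firing rates per direction bin) the resultant of
    the weighted unit vectors is normalized by the total weight, so a uniform
    weight profile gives 0 and a single-bin profile gives 1.
    """
    r, _ = weighted_mean_vector(angles_deg, weights)
    return r


def weighted_mean_vector(angles_deg, weights=None):
    """Return (resultant length, mean direction deg) of a weighted sample."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    c = float(np.sum(w * np.cos(a))) / total
    s = float(np.sum(w * np.sin(a))) / total
    return float(np.hypot(c, s)), float(wrap_degrees(np.degrees(np.arctan2(s, c))))


def circular_mean(angles_deg, weights=None):
    """Weighted circular mean direction in degrees."""
    _, mu = weighted_mean_vector(angles_deg, weights)
    return mu


def circular_difference(a_deg, b_deg):
    """Signed circular difference a - b, wrapped to [-180, 180)."""
    return wrap_degrees(np.asarray(a_deg, float) - np.asarray(b_deg, float))


def circular_correlation(a_deg, b_deg):
    """Fisher–Lee circular–circular correlation coefficient.

    r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j) /
        sqrt(sum sin^2(a_i - a_j) * sum sin^2(b_i - b_j))
    """
    a = np.radians(np.asarray(a_deg, dtype=float))
    b = np.radians(np.asarray(b_deg, dtype=float))
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired angles")
    da = np.sin(a[:, None] - a[None, :])
    db = np.sin(b[:, None] - b[None, :])
    iu = np.triu_indices(a.size, k=1)
    num = float(np.sum(da[iu] * db[iu]))
    den = float(np.sqrt(np.sum(da[iu] ** 2) * np.sum(db[iu] ** 2)))
    if den == 0.0:
        raise ValueError("degenerate (constant) angular sample")
    return num / den


def rayleigh_test(angles_deg):
    """Rayleigh test for uniformity of directions.

    Returns (R, p) where R is the mean resultant length and p the
    large-sample approximation of the Rayleigh p-value.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 angles")
    r = mean_vector_length(a)
    z = n * r * r
    # Approximation from Zar, Biostatistical Analysis.
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - z * n)) - (1.0 + 2.0 * n))
    return r, float(min(max(p, 0.0), 1.0))
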