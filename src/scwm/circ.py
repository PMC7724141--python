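"""Circular statistics on angles in degrees.

Convention (used package-wide): polar angle is measured counterclockwise
from the right horizontal meridian, in degrees on [0, 360); Cartesian
y > 0 is the upper visual field.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_deg",
    "circdist_deg",
    "circ_mean_deg",
    "circular_correlation",
]


def wrap_deg(angles):
    """Wrap angles into [0, 360)."""
    w = np.asarray(angles, dtype=float) % 360.0
    # floating modulo of tiny negatives can round up to exactly 360
    return np.where(w == 360.0, 0.0, w)


def circdist_deg(a, b):
    """Signed minimal angular difference a - b in degrees, in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def circ_mean_deg(angles, axis=None):
    """Circular mean of angles in degrees, wrapped to [0, 360)."""
    rad = np.deg2rad(np.asarray(angles, dtype=float))
    s = np.sin(rad).mean(axis=axis)
    c = np.cos(rad).mean(axis=axis)
    return wrap_deg(np.rad2deg(np.arctan2(s, c)))


def _fl_sums(sin_a, cos_a, sin_b, cos_b):
    """Fisher-Lee numerator over all ordered pairs, computed in O(n).

    sum_{i,j} sin(a_i - a_j) sin(b_i - b_j)
      = 2 [ (Σ s_a s_b)(Σ c_a c_b) - (Σ s_a c_b)(Σ c_a s_b) ]
    """
    return 2.0 * (
        (sin_a @ sin_b) * (cos_a @ cos_b) - (sin_a @ cos_b) * (cos_a @ sin_b)
    )


def _fl_denom_term(angles_rad):
    """sum_{i,j} sin^2(a_i - a_j) in O(n) via double-angle sums."""
    n = angles_rad.size
    c2 = np.cos(2.0 * angles_rad).sum()
    s2 = np.sin(2.0 * angles_rad).sum()
    return 0.5 * (n * n - c2 * c2 - s2 * s2)


def circular_correlation(angles_a, angles_b, n_perm=10000, seed=None):
    """Fisher-Lee circular-circular correlation with a permutation p value.

    Parameters
    ----------
    angles_a, angles_b : array-like of angles in degrees, equal length >= 3.
    n_perm : int
        Number of label permutations for the two-sided p value. 0 disables
        the permutation test (p is returned as nan).
    seed : int or numpy Generator, optional

    Returns
    -------
    (r, p) : float, float

    The estimator is invariant to adding a constant rotation to either
    input, and equals 1 when ``angles_b`` is a rotation of ``angles_a``.
    """
    a = np.deg2rad(wrap_deg(angles_a))
    b = np.deg2rad(wrap_deg(angles_b))
    if a.ndim != 1 or a.shape != b.shape:
        raise ValueError("angle sequences must be 1D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 angle pairs")

    sa, ca = np.sin(a), np.cos(a)
    sb, cb = np.sin(b), np.cos(b)
    da, db = _fl_denom_term(a), _fl_denom_term(b)
    tiny = 1e-12 * a.size ** 2
    if da < tiny or db < tiny:
        raise ValueError("degenerate (constant) angle sequence")
    denom = np.sqrt(da * db)
    r = _fl_sums(sa, ca, sb, cb) / denom

    if n_perm <= 0:
        return float(r), float("nan")

    rng = np.random.default_rng(seed)
    # Permute b against a; r under permutation, vectorized over permutations.
    idx = np.argsort(rng.random((int(n_perm), a.size)), axis=1)
    sbp, cbp = sb[idx], cb[idx]
    num = 2.0 * ((sbp @ sa) * (cbp @ ca) - (cbp @ sa) * (sbp @ ca))
    r_perm = num / denom
    p = (1.0 + np.count_nonzero(np.abs(r_perm) >= abs(r))) / (n_perm + 1.0)
    return float(r), float(p)
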