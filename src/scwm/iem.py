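"""Spatial inverted encoding model (IEM) over polar angle.

Voxel responses are modeled as weighted sums of nine information
channels, each a raised-cosine (half-angle squared cosine) basis
function centered on one of nine equally spaced polar angles. Weights
are estimated by least squares on training trials in which no spatial
transformation was required ("same" condition); the weight matrix is
then pseudo-inverted to recover channel coefficients — and hence a
reconstructed sensitivity profile over polar angle — from held-out
trials of the transformed conditions.

Trial preprocessing follows the delay-period logic: per-trial responses
are the mean of the last four TRs of the memory delay, and trials are
combined in seeded twofold averages within (condition x angular bin)
cells to raise SNR while preserving counterbalancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circ import circ_mean_deg, circdist_deg, wrap_deg

ANGLE_COLUMNS = ("visual_angle_deg", "vgs_angle_deg", "mgs_angle_deg")


@dataclass
class ChannelBasis:
    """Raised-cosine channel basis tiling polar angle.

    f_k(theta) = (1 + cos(theta - c_k)) / 2 = cos^2((theta - c_k)/2),
    unimodal over 360 degrees with unit peak at its center. For n
    equally spaced channels the basis sums to the constant n/2.
    """

    n_channels: int = 9
    centers_deg: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")
        if self.centers_deg is None:
            self.centers_deg = (360.0 / self.n_channels
                                * np.arange(self.n_channels))

    @property
    def partition_constant(self) -> float:
        return self.n_channels / 2.0

    @property
    def intrinsic_rank(self) -> int:
        """Dimension of the function space the channels span.

        The exponent-1 raised cosine contains only a DC term and the
        first circular harmonic, so any channel design matrix built from
        it has rank at most 3 however many channels or training angles
        are used; weight estimation solves the least-squares problem in
        that subspace (minimum-norm solution).
        """
        dense = self.evaluate(np.arange(0.0, 360.0, 5.0))
        return int(np.linalg.matrix_rank(dense))

    def evaluate(self, theta_deg):
        """Basis matrix at angles theta: shape (..., n_channels)."""
        theta = np.asarray(theta_deg, dtype=float)
        d = np.deg2rad(theta[..., None] - self.centers_deg)
        return (1.0 + np.cos(d)) / 2.0


def make_channel_basis(n_channels=9) -> ChannelBasis:
    """Nine equally spaced raised-cosine channels by default."""
    return ChannelBasis(n_channels=n_channels)


@dataclass
class TrialResponseMatrix:
    """Delay-period responses (trials x voxels) with trial labels.

    ``trials`` carries at least condition and the three reference angles
    (visual, VGS, MGS) aligned row-for-row with ``responses``.
    """

    responses: np.ndarray
    trials: pd.DataFrame

    def __post_init__(self):
        if self.responses.shape[0] != len(self.trials):
            raise ValueError("responses and trial table lengths differ")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("non-finite responses")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]

    def subset(self, mask):
        return TrialResponseMatrix(
            responses=self.responses[mask],
            trials=self.trials.loc[mask].reset_index(drop=True))


def delay_window_average(bold, trials: pd.DataFrame, tr_s=1.5,
                         delay_s=10.5, n_avg=4, trials_per_run=16,
                         trial_s=22.5) -> TrialResponseMatrix:
    """Average each voxel over the last ``n_avg`` TRs of the memory delay.

    A TR belongs to the delay if its acquisition midpoint falls inside
    [t_delay, t_delay + delay_s) of the trial (times within run).
    ``bold`` is (n_voxels, n_TR) spanning the session with equal-length
    runs laid out consecutively in run_id order.
    """
    bold = np.asarray(bold, dtype=float)
    tr_per_run = int(round(trial_s / tr_s)) * trials_per_run
    run_ids = np.sort(trials["run_id"].unique())
    if bold.shape[1] != tr_per_run * len(run_ids):
        raise ValueError(
            f"expected {tr_per_run * len(run_ids)} TRs "
            f"({len(run_ids)} runs x {tr_per_run}), got {bold.shape[1]}")
    run_offset = {rid: i * tr_per_run for i, rid in enumerate(run_ids)}

    rows = np.empty((len(trials), bold.shape[0]))
    for i, row in enumerate(trials.itertuples()):
        t0, t1 = row.t_delay_s, row.t_delay_s + delay_s
        first = int(np.ceil((t0 - 0.5 * tr_s) / tr_s))
        last = int(np.ceil((t1 - 0.5 * tr_s) / tr_s))  # exclusive
        n_delay = last - first
        if n_delay < n_avg:
            raise ValueError(
                f"delay spans only {n_delay} TRs (< {n_avg}) for trial {i}")
        sel = np.arange(last - n_avg, last) + run_offset[row.run_id]
        rows[i] = bold[:, sel].mean(axis=1)
    return TrialResponseMatrix(responses=rows,
                               trials=trials.reset_index(drop=True))


def twofold_combine(trm: TrialResponseMatrix, seed=None,
                    on_odd="error") -> TrialResponseMatrix:
    """Average random trial pairs within (condition x angular bin) cells.

    Halves the trial count while keeping the proportions of conditions
    and bins; combined angle labels are circular means of the pair.
    Cells with odd counts raise by default; ``on_odd='drop'`` discards
    one random trial from each offending cell instead.
    """
    rng = np.random.default_rng(seed)
    trials = trm.trials
    keys = list(zip(trials["condition"], trials["bin_index"]))
    cells = {}
    for i, k in enumerate(keys):
        cells.setdefault(k, []).append(i)

    pair_rows = []
    for k in sorted(cells):
        idx = np.array(cells[k])
        if len(idx) % 2 != 0:
            if on_odd == "drop":
                drop = rng.integers(len(idx))
                idx = np.delete(idx, drop)
            else:
                raise ValueError(
                    f"odd trial count ({len(idx)}) in cell "
                    f"(condition={k[0]!r}, bin={k[1]})")
        perm = rng.permutation(len(idx))
        idx = idx[perm]
        pair_rows.extend(idx.reshape(-1, 2).tolist())

    resp = np.empty((len(pair_rows), trm.n_voxels))
    recs = []
    for j, (a, b) in enumerate(pair_rows):
        resp[j] = 0.5 * (trm.responses[a] + trm.responses[b])
        ra, rb = trials.iloc[a], trials.iloc[b]
        rec = dict(condition=ra["condition"], bin_index=ra["bin_index"])
        for col in ANGLE_COLUMNS:
            rec[col] = float(circ_mean_deg([ra[col], rb[col]]))
        for col in ("visual_ecc_deg", "vgs_ecc_deg", "mgs_ecc_deg"):
            if col in trials.columns:
                rec[col] = 0.5 * (ra[col] + rb[col])
        recs.append(rec)
    return TrialResponseMatrix(responses=resp, trials=pd.DataFrame(recs))


def make_channel_coefficients(angles_deg, basis: ChannelBasis):
    """Hypothetical channel coefficient matrix C for given trial angles."""
    return basis.evaluate(np.asarray(angles_deg, dtype=float))


def estimate_weights(b_train, c_train, required_rank=3):
    """Least-squares voxel-channel weights W (voxels x channels).

    Solves min_W ||B - C W^T||^2 (minimum-norm solution). The design
    must reach the basis's intrinsic rank (3 for the exponent-1 raised
    cosine: DC plus one harmonic), which needs at least 3 distinct
    training angles; a design of fewer distinct angles is rejected.
    The residual is orthogonal to the columns of C by construction.
    """
    b_train = np.asarray(b_train, dtype=float)
    c_train = np.asarray(c_train, dtype=float)
    if b_train.shape[0] != c_train.shape[0]:
        raise ValueError("B_train and C_train row counts differ")
    rank = np.linalg.matrix_rank(c_train)
    if rank < min(required_rank, c_train.shape[1]):
        raise ValueError(
            f"training design is rank deficient (rank {rank} < "
            f"{required_rank}): too few distinct training angles "
            f"({c_train.shape[0]} rows)")
    w_t, *_ = np.linalg.lstsq(c_train, b_train, rcond=None)
    return w_t.T


def invert_channel_responses(b_test, weights):
    """Estimated channel coefficients C_test = B_test (W^T)^+."""
    b_test = np.atleast_2d(np.asarray(b_test, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if b_test.shape[1] != weights.shape[0]:
        raise ValueError("B_test voxel count does not match W")
    if not np.any(weights):
        raise ValueError("weight matrix is all zero; cannot invert")
    return b_test @ np.linalg.pinv(weights.T)


def reconstruction_profiles(coeffs, basis: ChannelBasis, grid_step=1.0):
    """Sensitivity profiles over polar angle from channel coefficients.

    Returns (grid_deg, profiles) with profiles shaped (n_trials, n_grid).
    """
    grid = np.arange(0.0, 360.0, grid_step)
    bmat = basis.evaluate(grid)  # (n_grid, n_channels)
    return grid, np.atleast_2d(coeffs) @ bmat.T


def invert_and_reconstruct(b_test, weights, basis: ChannelBasis,
                           grid_step=1.0):
    """Per-trial reconstructions: (grid_deg, profiles, coeffs)."""
    coeffs = invert_channel_responses(b_test, weights)
    grid, profiles = reconstruction_profiles(coeffs, basis, grid_step)
    return grid, profiles, coeffs


def align_and_average(coeffs, reference_angles_deg, basis: ChannelBasis,
                      grid_step=1.0):
    """Align per-trial reconstructions to their reference and average.

    Each trial's profile is evaluated at (grid + reference), i.e.
    circularly shifted so its reference location maps to 0 degrees, then
    profiles are averaged pointwise. Evaluation is analytic in the basis,
    so alignment introduces no interpolation error.
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    refs = np.atleast_1d(np.asarray(reference_angles_deg, dtype=float))
    if coeffs.shape[0] != refs.size:
        raise ValueError("one reference angle per trial is required")
    grid = np.arange(0.0, 360.0, grid_step)
    acc = np.zeros_like(grid)
    for c, r in zip(coeffs, refs):
        acc += basis.evaluate(grid + r) @ c
    return grid, acc / coeffs.shape[0]


def profile_peak_deg(grid_deg, profile, flat_tol=1e-12):
    """Peak angle of a sampled profile; NaN for flat profiles.

    Ties are broken by the circular mean of the tied maxima.
    """
    profile = np.asarray(profile, dtype=float)
    if np.ptp(profile) < flat_tol:
        return float("nan")
    mx = profile.max()
    tied = np.asarray(grid_deg)[profile >= mx - flat_tol]
    return float(circ_mean_deg(tied))


def voxel_tuning_from_weights(weights, basis: ChannelBasis, grid_step=1.0):
    """Polar-angle tuning curve and peak per voxel from fitted weights.

    tuning_v(theta) = sum_k W[v, k] f_k(theta). Returns
    (grid_deg, tunings (n_voxels x n_grid), peaks_deg) with NaN peaks
    for flat (untuned) voxels.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    grid = np.arange(0.0, 360.0, grid_step)
    tunings = weights @ basis.evaluate(grid).T
    peaks = np.array([profile_peak_deg(grid, t) for t in tunings])
    return grid, tunings, peaks


def train_and_reconstruct(trm: TrialResponseMatrix, basis: ChannelBasis,
                          reference="mgs", train_condition="same",
                          grid_step=1.0, shuffle_labels_rng=None):
    """One full IEM pass on a (possibly twofold-combined) trial matrix.

    Trains on ``train_condition`` rows using their visual-stimulus angle,
    reconstructs all remaining rows, and aligns them to the requested
    reference. Returns a dict with weights, per-trial coefficients, the
    aligned average profile, and the aligned peak error.

    ``shuffle_labels_rng`` permutes the training angle labels before the
    fit (the permutation-null path).
    """
    cond = trm.trials["condition"].to_numpy()
    train_mask = cond == train_condition
    test_mask = ~train_mask
    if not train_mask.any() or not test_mask.any():
        raise ValueError("need both training and test trials")
    train_angles = trm.trials.loc[train_mask, "visual_angle_deg"].to_numpy()
    if shuffle_labels_rng is not None:
        train_angles = train_angles[shuffle_labels_rng.permutation(
            train_angles.size)]
    c_train = make_channel_coefficients(train_angles, basis)
    weights = estimate_weights(trm.responses[train_mask], c_train)
    coeffs = invert_channel_responses(trm.responses[test_mask], weights)
    refs = trm.trials.loc[test_mask, f"{reference}_angle_deg"].to_numpy()
    grid, avg = align_and_average(coeffs, refs, basis, grid_step)
    peak = profile_peak_deg(grid, avg)
    err = float("nan") if np.isnan(peak) else float(
        abs(circdist_deg(peak, 0.0)))
    return dict(weights=weights, coeffs=coeffs, grid_deg=grid,
                profile=avg, reference=reference, peak_error_deg=err,
                train_mask=train_mask)


def bootstrap_reconstruction(trm: TrialResponseMatrix, basis: ChannelBasis,
                             reference="mgs", n_iter=10000, seed=None,
                             grid_step=1.0, refit=True, on_odd="error"):
    """Bootstrap over twofold trial arrangements.

    Per iteration the raw trials are re-paired (new twofold arrangement),
    the model is retrained on same-condition rows (or, with
    ``refit=False``, trained once on the first arrangement and only the
    test rows re-paired), the transformed rows are reconstructed and
    aligned. Returns (grid_deg, profiles (n_iter x n_grid)).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, 360.0, grid_step)
    profiles = np.empty((n_iter, grid.size))
    fixed_weights = None
    for i in range(n_iter):
        combined = twofold_combine(trm, seed=rng, on_odd=on_odd)
        if refit or fixed_weights is None:
            out = train_and_reconstruct(combined, basis, reference,
                                        grid_step=grid_step)
            profiles[i] = out["profile"]
            fixed_weights = out["weights"]
        else:
            test_mask = combined.trials["condition"].to_numpy() != "same"
            coeffs = invert_channel_responses(
                combined.responses[test_mask], fixed_weights)
            refs = combined.trials.loc[test_mask,
                                       f"{reference}_angle_deg"].to_numpy()
            _, profiles[i] = align_and_average(coeffs, refs, basis,
                                               grid_step)
    return grid, profiles
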