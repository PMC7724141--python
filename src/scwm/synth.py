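"""Synthetic retinotopy and memory-guided-saccade (MGS) datasets.

Generates voxel populations with known 2D Gaussian receptive fields and
drives them through the same forward model the fitting code inverts:

* retinotopy runs: bar-sweep aperture movie -> aperture/RF overlap ->
  HRF convolution -> gain, baseline and white noise;
* spatial working-memory runs: a four-condition MGS task (identity and
  three mirror transformations of the sample location), with voxel
  responses tuned to the polar angle of a chosen reference location
  (visual sample, visually guided saccade target, or MGS goal).

Every generator takes a ``seed`` and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circ import circdist_deg, wrap_deg
from .hrf import DEFAULT_PEAK_S, DEFAULT_UNDERSHOOT_S, convolve_hrf
from .stimulus import StimulusMovie, neural_drive

CONDITIONS = ("same", "mirror_h", "mirror_v", "mirror_both")
BIN_CENTERS_DEG = 22.5 + 45.0 * np.arange(8)

# Trial timing (seconds from stimulus onset). The 400 ms saccade-cue dot
# falls inside the 1.4 s allotted for the two saccades, which makes the
# event chain sum exactly to the 22.5 s trial.
STIM_S = 0.3
DELAY_S = 10.5
SACCADE_S = 1.4
FEEDBACK_S = 0.5
ITI_S = 9.8
TRIAL_S = STIM_S + DELAY_S + SACCADE_S + FEEDBACK_S + ITI_S  # 22.5
TRIALS_PER_RUN = 16


@dataclass
class GroundTruthVoxel:
    """Generative parameters of one simulated voxel."""

    x_deg: float
    y_deg: float
    sigma_deg: float
    hrf_peak_s: float = DEFAULT_PEAK_S
    hrf_undershoot_s: float = DEFAULT_UNDERSHOOT_S
    baseline: float = 0.0
    amplitude: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.sigma_deg <= 0:
            raise ValueError("sigma_deg must be positive")

    @property
    def polar_angle_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.y_deg, self.x_deg)) % 360.0)

    @property
    def eccentricity_deg(self) -> float:
        return float(np.hypot(self.x_deg, self.y_deg))


def _truncated_normal(rng, sd, size, bound_sds=2.0):
    """Draw N(0, sd) truncated at +/- bound_sds standard deviations."""
    if sd == 0:
        return np.zeros(size)
    z = rng.standard_normal(size)
    bad = np.abs(z) > bound_sds
    while bad.any():
        z[bad] = rng.standard_normal(bad.sum())
        bad = np.abs(z) > bound_sds
    return sd * z


def sample_ground_truth_voxels(n_voxels, hemifield="both", size_slope=0.2,
                               size_intercept=1.0, size_noise_sd=0.3,
                               ecc_range=(0.5, 12.0), amplitude=1.0,
                               baseline=0.0, noise_sd=0.0, sigma_floor=0.1,
                               seed=None):
    """Sample voxels with linearly eccentricity-scaled pRF sizes.

    Centers are drawn uniformly in polar angle within the requested
    hemifield ("left": x<0, "right": x>0, or "both") and uniformly in
    eccentricity; sigma = intercept + slope*ecc + truncated Gaussian
    noise, floored at ``sigma_floor``.
    """
    if n_voxels < 0:
        raise ValueError("n_voxels must be >= 0")
    if size_slope < 0:
        raise ValueError("size_slope must be >= 0")
    rng = np.random.default_rng(seed)
    if hemifield == "both":
        angles = rng.uniform(0.0, 360.0, n_voxels)
    elif hemifield == "right":
        angles = wrap_deg(rng.uniform(-90.0, 90.0, n_voxels))
    elif hemifield == "left":
        angles = rng.uniform(90.0, 270.0, n_voxels)
    else:
        raise ValueError(f"unknown hemifield {hemifield!r}")
    eccs = rng.uniform(ecc_range[0], ecc_range[1], n_voxels)
    sigmas = size_intercept + size_slope * eccs
    sigmas = sigmas + _truncated_normal(rng, size_noise_sd, n_voxels)
    sigmas = np.maximum(sigmas, sigma_floor)
    rad = np.deg2rad(angles)
    return [
        GroundTruthVoxel(
            x_deg=float(e * np.cos(a)), y_deg=float(e * np.sin(a)),
            sigma_deg=float(s), amplitude=amplitude, baseline=baseline,
            noise_sd=noise_sd)
        for a, e, s in zip(rad, eccs, sigmas)
    ]


def simulate_retinotopy_run(movie: StimulusMovie, voxels, seed=None):
    """Simulate one retinotopy run: (n_voxels, n_TR) BOLD matrix.

    BOLD = amplitude * (drive conv HRF) + baseline + N(0, noise_sd),
    with the same drive computation used by the pRF model's predictions.
    """
    rng = np.random.default_rng(seed)
    n = movie.n_frames
    out = np.empty((len(voxels), n))
    for i, v in enumerate(voxels):
        drive = neural_drive(movie, v.x_deg, v.y_deg, v.sigma_deg)
        pred = convolve_hrf(drive, movie.tr_s, v.hrf_peak_s,
                            v.hrf_undershoot_s)
        out[i] = v.amplitude * pred + v.baseline
        if v.noise_sd > 0:
            out[i] += rng.normal(0.0, v.noise_sd, n)
    return out


def apply_transformation(angle_deg, ecc_deg, condition):
    """Map a visual location to the MGS goal for one task condition.

    same -> identity; mirror_h reflects across the horizontal meridian;
    mirror_v across the vertical meridian; mirror_both across both
    (a 180 degree rotation). Eccentricity is unchanged.
    """
    angle = wrap_deg(angle_deg)
    if condition == "same":
        out = angle
    elif condition == "mirror_h":
        out = wrap_deg(360.0 - angle)
    elif condition == "mirror_v":
        out = wrap_deg(180.0 - angle)
    elif condition == "mirror_both":
        out = wrap_deg(angle + 180.0)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if np.isscalar(angle_deg):
        return float(out), ecc_deg
    return out, ecc_deg


def make_wm_trial_schedule(n_runs, jitter_deg=10.0, ecc_range=(9.0, 11.0),
                           seed=None):
    """Build the MGS task trial table.

    Each run has 16 trials (22.5 s each) sampling the 8 angular bins
    (22.5 to 337.5 in 45 degree steps, jittered uniformly within
    +/- jitter_deg) exactly twice, at eccentricities uniform in
    ``ecc_range``. The four transformation conditions are counterbalanced
    across successive run pairs: within each pair, every (condition, bin)
    cell occurs exactly once. VGS targets are uniform in angle and in the
    same eccentricity band; the MGS goal is the condition's transformation
    of the visual location.
    """
    if n_runs % 2 != 0:
        raise ValueError(
            "n_runs must be even: conditions are counterbalanced across "
            "pairs of successive runs")
    rng = np.random.default_rng(seed)
    rows = []
    for pair in range(n_runs // 2):
        # Per bin, deal the 4 conditions 2/2 between the pair's two runs,
        # so each run keeps exactly two trials per bin.
        run_conditions = {0: [], 1: []}  # list of (bin_idx, condition)
        for b in range(8):
            order = rng.permutation(4)
            for j, c in enumerate(order):
                run_conditions[0 if j < 2 else 1].append((b, CONDITIONS[c]))
        for local_run in (0, 1):
            run_id = 2 * pair + local_run
            trials = run_conditions[local_run]
            order = rng.permutation(len(trials))
            for t, k in enumerate(order):
                b, cond = trials[k]
                vis_angle = wrap_deg(
                    BIN_CENTERS_DEG[b]
                    + rng.uniform(-jitter_deg, jitter_deg))
                vis_ecc = rng.uniform(*ecc_range)
                vgs_angle = rng.uniform(0.0, 360.0)
                vgs_ecc = rng.uniform(*ecc_range)
                mgs_angle, mgs_ecc = apply_transformation(
                    float(vis_angle), vis_ecc, cond)
                t0 = t * TRIAL_S
                rows.append(dict(
                    run_id=run_id, trial_index=t, condition=cond,
                    bin_index=b,
                    visual_angle_deg=float(vis_angle),
                    visual_ecc_deg=vis_ecc,
                    vgs_angle_deg=vgs_angle, vgs_ecc_deg=vgs_ecc,
                    mgs_angle_deg=float(mgs_angle), mgs_ecc_deg=mgs_ecc,
                    t_stim_s=t0, t_delay_s=t0 + STIM_S,
                    t_cue_s=t0 + STIM_S + DELAY_S,
                    t_feedback_s=t0 + STIM_S + DELAY_S + SACCADE_S,
                    t_iti_s=t0 + STIM_S + DELAY_S + SACCADE_S + FEEDBACK_S,
                ))
    return pd.DataFrame(rows)


def raised_cosine_tuning(delta_deg, exponent=1.0):
    """Unimodal polar-angle tuning curve, max 1 at delta = 0.

    T(d) = ((1 + cos d)/2) ** exponent — the same functional family as
    the encoding-model basis; larger exponents narrow the tuning.
    """
    return ((1.0 + np.cos(np.deg2rad(delta_deg))) / 2.0) ** exponent


def simulate_wm_dataset(trials: pd.DataFrame, voxels,
                        encoded_reference="mgs", tuning_exponent=1.0,
                        snr=2.0, mode="trialwise", seed=None, tr_s=1.5):
    """Simulate delay-period voxel responses tuned to one task reference.

    Each voxel responds with amplitude * T(angular distance between its
    pRF polar angle and the trial's ``encoded_reference`` location) plus
    white noise of SD amplitude/snr. In ``trialwise`` mode the result is
    a (n_trials, n_voxels) matrix; in ``timeseries`` mode responses are
    placed as a boxcar over the memory delay, convolved with each voxel's
    HRF, and returned as a (n_voxels, n_TR) matrix spanning all runs.
    """
    if not np.isinf(snr) and snr <= 0:
        raise ValueError("snr must be positive (np.inf for noiseless)")
    if encoded_reference not in ("visual", "vgs", "mgs"):
        raise ValueError(f"unknown reference {encoded_reference!r}")
    rng = np.random.default_rng(seed)
    pref = np.array([v.polar_angle_deg for v in voxels])
    amp = np.array([v.amplitude for v in voxels])
    ref_angles = trials[f"{encoded_reference}_angle_deg"].to_numpy()
    delta = circdist_deg(ref_angles[:, None], pref[None, :])
    signal = amp[None, :] * raised_cosine_tuning(delta, tuning_exponent)
    noise_sd = 0.0 if np.isinf(snr) else amp / snr

    if mode == "trialwise":
        resp = signal.copy()
        if not np.isinf(snr):
            resp += rng.normal(0.0, 1.0, resp.shape) * noise_sd[None, :]
        return resp
    if mode != "timeseries":
        raise ValueError(f"unknown mode {mode!r}")

    tr_per_run = int(round(TRIAL_S / tr_s)) * TRIALS_PER_RUN
    run_ids = np.sort(trials["run_id"].unique())
    n_tr = tr_per_run * len(run_ids)
    bold = np.zeros((len(voxels), n_tr))
    t_delay = trials["t_delay_s"].to_numpy()
    t_cue = trials["t_cue_s"].to_numpy()
    run_col = trials["run_id"].to_numpy()
    for r_pos, rid in enumerate(run_ids):
        positions = np.flatnonzero(run_col == rid)
        drive = np.zeros((len(voxels), tr_per_run))
        for pos in positions:
            lo = int(round(t_delay[pos] / tr_s))
            hi = int(round(t_cue[pos] / tr_s))
            drive[:, lo:hi] += signal[pos][:, None]
        conv = convolve_hrf(drive, tr_s)
        sl = slice(r_pos * tr_per_run, (r_pos + 1) * tr_per_run)
        bold[:, sl] = conv
        if not np.isinf(snr):
            bold[:, sl] += (rng.normal(0.0, 1.0, (len(voxels), tr_per_run))
                            * noise_sd[:, None])
    bold += np.array([v.baseline for v in voxels])[:, None]
    return bold
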