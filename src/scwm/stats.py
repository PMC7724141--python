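"""Representational fidelity and inference for IEM reconstructions.

Two fidelity statistics are provided:

* basic fidelity — the projection of the reconstruction, treated as a
  set of weighted unit vectors around the circle, onto the true
  direction: F = mean_theta recon(theta) * cos(theta - true). Flat
  reconstructions score exactly 0 and the statistic is sign-symmetric,
  so its permutation null is centered on 0.
* modified fidelity — the inner product between the reconstruction and
  a standard tuning curve centered on the true location, multiplied by
  a cost g(err) that discounts reconstructions whose peak deviates from
  the true location: F = <f_std, f_recon> * g(err). The standard tuning
  is the same raised cosine as the IEM basis; the default cost is
  Gaussian in the peak error with scale kappa = 90 degrees (the
  standard tuning's half width at half maximum) and g(0) = 1.

Inference follows a permutation scheme: the training-trial angle labels
are shuffled, the IEM is refit, and fidelity recomputed, yielding a null
distribution compared with the real bootstrap distribution by a
two-sample KS test (per subject) and a paired t test over bootstrap-
stabilized subject means (group level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .circ import circ_mean_deg, circdist_deg, circular_correlation
from .iem import (ChannelBasis, TrialResponseMatrix, profile_peak_deg,
                  train_and_reconstruct, twofold_combine,
                  voxel_tuning_from_weights)

DEFAULT_KAPPA_DEG = 90.0


def standard_tuning(grid_deg, center_deg=0.0):
    """Raised-cosine standard tuning with unit peak at the true location."""
    return (1.0 + np.cos(np.deg2rad(np.asarray(grid_deg) - center_deg))) / 2.0


def fidelity_basic(profile, grid_deg, true_angle_deg=0.0):
    """Projection of the reconstruction onto the true direction.

    F = mean over the grid of recon(theta) * cos(theta - true); 0 for
    flat profiles, positive when tuned toward the true location,
    negative when tuned away.
    """
    profile = np.asarray(profile, dtype=float)
    grid = np.asarray(grid_deg, dtype=float)
    if profile.size == 0:
        raise ValueError("empty reconstruction grid")
    return float(np.mean(profile * np.cos(np.deg2rad(grid - true_angle_deg))))


def gaussian_cost(err_deg, kappa_deg=DEFAULT_KAPPA_DEG):
    """Peak-error cost g with g(0) = 1, decreasing in |err|."""
    if kappa_deg <= 0:
        raise ValueError("kappa must be positive")
    return float(np.exp(-(err_deg ** 2) / (2.0 * kappa_deg ** 2)))


def fidelity_modified(profile, grid_deg, true_angle_deg=0.0,
                      kappa_deg=DEFAULT_KAPPA_DEG):
    """Inner product with the standard tuning times the peak-error cost.

    F = mean_l f_std(l) * f_recon(l) * g(err), where err is the circular
    distance between the reconstruction peak and the true location; a
    flat (peakless) reconstruction gets cost from the maximal 180 degree
    error. For a fixed-shape tuned profile rotated away from the target
    both factors decrease, so F is strictly decreasing in the rotation.
    Unlike the basic statistic, F is not sign-symmetric (its null is
    positively offset by the reconstruction's mean level), so null
    calibration checks use :func:`fidelity_basic`.
    """
    profile = np.asarray(profile, dtype=float)
    grid = np.asarray(grid_deg, dtype=float)
    if profile.size == 0:
        raise ValueError("empty reconstruction grid")
    std = standard_tuning(grid, true_angle_deg)
    inner = float(np.mean(std * profile))
    peak = profile_peak_deg(grid, profile)
    err = 180.0 if np.isnan(peak) else abs(
        float(circdist_deg(peak, true_angle_deg)))
    return inner * gaussian_cost(err, kappa_deg)


@dataclass
class FidelityResult:
    """Fidelity with its bootstrap and permutation-null distributions."""

    reference: str
    value_basic: float
    value_modified: float
    bootstrap_basic: np.ndarray = field(default=None, repr=False)
    bootstrap_modified: np.ndarray = field(default=None, repr=False)
    null_basic: np.ndarray = field(default=None, repr=False)
    null_modified: np.ndarray = field(default=None, repr=False)


def _fidelities(grid, profile, kappa_deg):
    return (fidelity_basic(profile, grid),
            fidelity_modified(profile, grid, kappa_deg=kappa_deg))


def permutation_null(trm: TrialResponseMatrix, basis: ChannelBasis,
                     reference="mgs", n_perm=10000, seed=None,
                     kappa_deg=DEFAULT_KAPPA_DEG, grid_step=1.0,
                     shuffle="labels", on_odd="error", pair_seed=None):
    """Null fidelity distribution from IEMs trained on shuffled data.

    The twofold arrangement is fixed (``pair_seed``); per permutation
    the training rows' angle labels (default) or voxel order
    (``shuffle='voxels'``) are randomly permuted, the weights refit, the
    transformed rows reconstructed and aligned to ``reference``, and
    both fidelity statistics recorded.

    Returns a DataFrame with columns basic, modified (n_perm rows).
    """
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives unstable tail estimates",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    combined = twofold_combine(trm, seed=pair_seed if pair_seed is not None
                               else rng, on_odd=on_odd)
    rows = np.empty((n_perm, 2))
    for i in range(n_perm):
        if shuffle == "labels":
            out = train_and_reconstruct(combined, basis, reference,
                                        grid_step=grid_step,
                                        shuffle_labels_rng=rng)
        elif shuffle == "voxels":
            perm = rng.permutation(combined.n_voxels)
            shuffled = TrialResponseMatrix(
                responses=combined.responses.copy(),
                trials=combined.trials)
            train = combined.trials["condition"].to_numpy() == "same"
            shuffled.responses[train] = shuffled.responses[train][:, perm]
            out = train_and_reconstruct(shuffled, basis, reference,
                                        grid_step=grid_step)
        else:
            raise ValueError(f"unknown shuffle mode {shuffle!r}")
        rows[i] = _fidelities(out["grid_deg"], out["profile"], kappa_deg)
    return pd.DataFrame(rows, columns=["basic", "modified"])


def bootstrap_fidelity(trm: TrialResponseMatrix, basis: ChannelBasis,
                       reference="mgs", n_iter=1000, seed=None,
                       kappa_deg=DEFAULT_KAPPA_DEG, grid_step=1.0,
                       on_odd="error"):
    """Fidelity over bootstrap re-pairings of the twofold combination."""
    from .iem import bootstrap_reconstruction

    grid, profiles = bootstrap_reconstruction(
        trm, basis, reference=reference, n_iter=n_iter, seed=seed,
        grid_step=grid_step, on_odd=on_odd)
    vals = np.array([_fidelities(grid, p, kappa_deg) for p in profiles])
    return pd.DataFrame(vals, columns=["basic", "modified"])


def subject_level_test(real_dist, null_dist):
    """Two-sample Kolmogorov-Smirnov test of real vs null fidelities."""
    real = np.asarray(real_dist, dtype=float)
    null = np.asarray(null_dist, dtype=float)
    if real.size == 0 or null.size == 0:
        raise ValueError("distributions must be nonempty")
    if np.ptp(real) == 0 and np.ptp(null) == 0 and real[0] == null[0]:
        # Degenerate identical point masses: no separation.
        return 0.0, 1.0
    res = sps.ks_2samp(real, null)
    return float(res.statistic), float(res.pvalue)


def group_level_test(per_subject_real, per_subject_null, n_boot=1000,
                     seed=None):
    """Paired t test of subject mean fidelity, real vs permutation null.

    Procedure: per bootstrap iteration, resample subjects with
    replacement and record the group-mean real and null fidelity (the
    returned bootstrap arrays give a group-level CI); the reported t and
    p come from a paired t test across the per-subject means.
    """
    reals = [np.asarray(r, dtype=float) for r in per_subject_real]
    nulls = [np.asarray(n, dtype=float) for n in per_subject_null]
    if len(reals) < 2 or len(reals) != len(nulls):
        raise ValueError("need >= 2 subjects with paired real/null")
    rng = np.random.default_rng(seed)
    mean_real = np.array([r.mean() for r in reals])
    mean_null = np.array([n.mean() for n in nulls])
    n_sub = len(reals)
    idx = rng.integers(0, n_sub, size=(n_boot, n_sub))
    boot_real = mean_real[idx].mean(axis=1)
    boot_null = mean_null[idx].mean(axis=1)
    diff = mean_real - mean_null
    if np.ptp(diff) == 0:
        t, p = (0.0, 1.0) if diff[0] == 0 else (np.inf * np.sign(diff[0]),
                                                0.0)
    else:
        res = sps.ttest_rel(mean_real, mean_null)
        t, p = float(res.statistic), float(res.pvalue)
    return dict(t=t, p=p, boot_real_means=boot_real,
                boot_null_means=boot_null,
                mean_real=mean_real, mean_null=mean_null)


@dataclass
class TuningComparison:
    """pRF polar angles vs IEM tuning peaks for eccentric voxels."""

    prf_angles_deg: np.ndarray
    iem_peaks_deg: np.ndarray
    ecc_min_deg: float
    r: float
    p: float

    @property
    def n_voxels(self) -> int:
        return self.prf_angles_deg.size


def compare_prf_iem_tuning(prf_fits, weights, basis: ChannelBasis,
                           ecc_min=5.0, n_perm=10000, seed=None):
    """Circular correlation of pRF polar angle with IEM tuning peak.

    Voxels are filtered to pRF eccentricity >= ecc_min (the encoding
    task only stimulates the periphery); untuned voxels (flat IEM
    tuning) are excluded.
    """
    weights = np.asarray(weights, dtype=float)
    if len(prf_fits) != weights.shape[0]:
        raise ValueError("fits and weight rows must index the same voxels")
    ecc = np.array([f.eccentricity_deg for f in prf_fits])
    angles = np.array([f.polar_angle_deg for f in prf_fits])
    keep = ecc >= ecc_min
    if keep.sum() < 3:
        raise ValueError(
            f"fewer than 3 voxels with eccentricity >= {ecc_min}")
    _, _, peaks = voxel_tuning_from_weights(weights[keep], basis)
    tuned = ~np.isnan(peaks)
    if tuned.sum() < 3:
        raise ValueError("fewer than 3 tuned voxels after filtering")
    r, p = circular_correlation(angles[keep][tuned], peaks[tuned],
                                n_perm=n_perm, seed=seed)
    return TuningComparison(prf_angles_deg=angles[keep][tuned],
                            iem_peaks_deg=peaks[tuned], ecc_min_deg=ecc_min,
                            r=r, p=p)


def delay_activity_summary(bold, trials: pd.DataFrame, voxel_hemis=None,
                           baseline_window=(-3.0, 0.0), delay_last_n=4,
                           tr_s=1.5, delay_s=10.5, trials_per_run=16,
                           trial_s=22.5):
    """Univariate delay-period signal change vs pretrial baseline.

    Per trial, the ROI-mean of the last ``delay_last_n`` delay TRs minus
    the ROI-mean of the pretrial baseline window (seconds relative to
    stimulus onset; trials without baseline TRs, e.g. the first of a
    run, are dropped). When per-voxel hemisphere labels ("left"/"right")
    are given, trials are split by whether the MGS target lies in the
    hemifield contralateral or ipsilateral to the voxels' hemisphere and
    summarized per group; otherwise a single "all" summary is returned.

    Returns a DataFrame with columns group, mean_change, ci_low,
    ci_high, t, p (one-tailed, change > 0).
    """
    if baseline_window[1] > 0.3:
        raise ValueError("baseline window overlaps the trial events")
    bold = np.asarray(bold, dtype=float)
    tr_per_run = int(round(trial_s / tr_s)) * trials_per_run
    run_ids = np.sort(trials["run_id"].unique())
    run_offset = {rid: i * tr_per_run for i, rid in enumerate(run_ids)}

    def window_trs(t0, t1, run_id):
        first = int(np.ceil((t0 - 0.5 * tr_s) / tr_s))
        last = int(np.ceil((t1 - 0.5 * tr_s) / tr_s))
        sel = np.arange(first, last)
        sel = sel[(sel >= 0) & (sel < tr_per_run)]
        return sel + run_offset[run_id]

    if voxel_hemis is None:
        groups = {"all": np.arange(bold.shape[0])}
    else:
        voxel_hemis = np.asarray(voxel_hemis)
        groups = {h: np.flatnonzero(voxel_hemis == h)
                  for h in ("left", "right")}

    changes = {"contra": [], "ipsi": [], "all": []}
    for row in trials.itertuples():
        base = window_trs(row.t_stim_s + baseline_window[0],
                          row.t_stim_s + baseline_window[1], row.run_id)
        if base.size == 0:
            continue
        t1 = row.t_delay_s + delay_s
        first = int(np.ceil((row.t_delay_s - 0.5 * tr_s) / tr_s))
        last = int(np.ceil((t1 - 0.5 * tr_s) / tr_s))
        delay = (np.arange(last - delay_last_n, last)
                 + run_offset[row.run_id])
        mgs_right = np.cos(np.deg2rad(row.mgs_angle_deg)) > 0
        for gname, vox in groups.items():
            if vox.size == 0:
                continue
            change = (bold[np.ix_(vox, delay)].mean()
                      - bold[np.ix_(vox, base)].mean())
            if gname == "all":
                changes["all"].append(change)
            else:
                contra = (gname == "left") == mgs_right
                changes["contra" if contra else "ipsi"].append(change)

    out = []
    for gname, vals in changes.items():
        if not vals:
            continue
        vals = np.asarray(vals)
        m = vals.mean()
        if vals.size > 1 and vals.std(ddof=1) > 0:
            res = sps.ttest_1samp(vals, 0.0, alternative="greater")
            t, p = float(res.statistic), float(res.pvalue)
            half = (sps.t.ppf(0.975, vals.size - 1)
                    * vals.std(ddof=1) / np.sqrt(vals.size))
        else:
            t, p, half = 0.0, 1.0, 0.0
        out.append(dict(group=gname, n_trials=vals.size,
                        mean_change=m, ci_low=m - half, ci_high=m + half,
                        t=t, p=p))
    return pd.DataFrame(out)


def fidelity_result(trm, basis, reference="mgs", n_boot=1000, n_perm=1000,
                    seed=None, kappa_deg=DEFAULT_KAPPA_DEG,
                    on_odd="error") -> FidelityResult:
    """Bootstrap fidelity plus its permutation null for one reference."""
    rng = np.random.default_rng(seed)
    s1, s2, s3 = rng.integers(0, 2 ** 31 - 1, 3)
    boot = bootstrap_fidelity(trm, basis, reference, n_iter=n_boot,
                              seed=int(s1), kappa_deg=kappa_deg,
                              on_odd=on_odd)
    null = permutation_null(trm, basis, reference, n_perm=n_perm,
                            seed=int(s2), kappa_deg=kappa_deg,
                            on_odd=on_odd, pair_seed=int(s3))
    return FidelityResult(
        reference=reference,
        value_basic=float(boot["basic"].mean()),
        value_modified=float(boot["modified"].mean()),
        bootstrap_basic=boot["basic"].to_numpy(),
        bootstrap_modified=boot["modified"].to_numpy(),
        null_basic=null["basic"].to_numpy(),
        null_modified=null["modified"].to_numpy())
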