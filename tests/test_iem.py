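import numpy as np
import pandas as pd
import pytest

from scwm import iem, synth
from scwm.circ import circdist_deg, wrap_deg


class TestChannelBasis:
    def test_unit_peak_and_zero_at_antipode(self, basis):
        at_centers = basis.evaluate(basis.centers_deg)
        np.testing.assert_allclose(np.diagonal(at_centers), 1.0)
        at_antipodes = basis.evaluate(basis.centers_deg + 180.0)
        np.testing.assert_allclose(np.diagonal(at_antipodes), 0.0,
                                   atol=1e-12)

    def test_partition_property_on_degree_grid(self, basis):
        grid = np.arange(0.0, 360.0, 1.0)
        total = basis.evaluate(grid).sum(axis=1)
        assert np.max(np.abs(total - 4.5)) < 1e-12

    def test_minimum_channel_count_enforced(self):
        with pytest.raises(ValueError):
            iem.make_channel_basis(2)

    def test_intrinsic_rank_is_three(self, basis):
        assert basis.intrinsic_rank == 3


class TestDelayWindowAverage:
    def _bold(self, trials, fill=0.0):
        n_tr = 240 * trials["run_id"].nunique()
        return np.full((3, n_tr), fill)

    def test_constant_series_returns_constant(self):
        trials = synth.make_wm_trial_schedule(2, seed=1)
        trm = iem.delay_window_average(self._bold(trials, 1.7), trials)
        np.testing.assert_allclose(trm.responses, 1.7)
        assert trm.n_trials == 32

    def test_window_is_last_four_of_seven_delay_trs(self):
        trials = synth.make_wm_trial_schedule(2, seed=2)
        bold = self._bold(trials)
        row = trials.iloc[0]
        base = int(round(row.t_stim_s / 1.5))
        # delay TRs are trial-relative TRs 0..6; impulse in TR 0 of the
        # delay must not contribute, TR 3 must.
        bold_a = bold.copy()
        bold_a[:, base + 0] = 99.0
        trm_a = iem.delay_window_average(bold_a, trials)
        assert trm_a.responses[0, 0] == 0.0
        bold_b = bold.copy()
        bold_b[:, base + 3] = 4.0
        trm_b = iem.delay_window_average(bold_b, trials)
        assert trm_b.responses[0, 0] == pytest.approx(1.0)  # 4/4 TRs

    def test_short_delay_rejected(self):
        trials = synth.make_wm_trial_schedule(2, seed=3)
        with pytest.raises(ValueError, match="delay spans"):
            iem.delay_window_average(self._bold(trials), trials,
                                     delay_s=4.0)


class TestTwofoldCombine:
    def test_halves_trials_and_preserves_label_proportions(self, wm_trm):
        comb = iem.twofold_combine(wm_trm, seed=4)
        assert comb.n_trials == wm_trm.n_trials // 2
        before = wm_trm.trials.groupby(
            ["condition", "bin_index"]).size() / wm_trm.n_trials
        after = comb.trials.groupby(
            ["condition", "bin_index"]).size() / comb.n_trials
        pd.testing.assert_series_equal(before, after)

    def test_identical_rows_average_to_themselves(self):
        trials = synth.make_wm_trial_schedule(2, seed=5)
        resp = np.tile(np.arange(32, dtype=float) % 16, (3, 1)).T
        trm = iem.TrialResponseMatrix(responses=resp, trials=trials)
        # force both members of every pair identical by duplicating rows
        dup = iem.TrialResponseMatrix(
            responses=np.vstack([resp, resp]),
            trials=pd.concat([trials, trials], ignore_index=True))
        comb = iem.twofold_combine(dup, seed=6)
        # every output row must equal one of the input rows exactly when
        # its pair was a duplicate; at minimum values stay in range
        assert comb.responses.min() >= resp.min()
        assert comb.responses.max() <= resp.max()

    def test_odd_cells_rejected_with_cell_identity(self):
        # 6 runs -> 3 trials per (condition, bin) cell: odd everywhere
        trials = synth.make_wm_trial_schedule(6, seed=7)
        trm = iem.TrialResponseMatrix(
            responses=np.zeros((96, 2)), trials=trials)
        with pytest.raises(ValueError, match="condition="):
            iem.twofold_combine(trm, seed=8)
        comb = iem.twofold_combine(trm, seed=8, on_odd="drop")
        assert comb.n_trials == 32  # one pair per 32 cells

    def test_combined_angle_is_circular_mean(self):
        trials = synth.make_wm_trial_schedule(4, seed=9)
        trm = iem.TrialResponseMatrix(
            responses=np.zeros((64, 2)), trials=trials)
        comb = iem.twofold_combine(trm, seed=10)
        # combined labels stay within the jittered bin of their members
        centers = synth.BIN_CENTERS_DEG[
            comb.trials["bin_index"].to_numpy()]
        d = np.abs(circdist_deg(comb.trials["visual_angle_deg"], centers))
        assert d.max() <= 10.0 + 1e-9


class TestWeightsAndInversion:
    def test_exact_recovery_in_model_subspace(self, generative_trm, basis):
        trm, w_true, _ = generative_trm
        c = iem.make_channel_coefficients(
            trm.trials["mgs_angle_deg"].to_numpy(), basis)
        w_hat = iem.estimate_weights(trm.responses, c)
        np.testing.assert_allclose(w_hat, w_true, atol=1e-8)

    def test_zero_data_zero_weights(self, basis):
        c = basis.evaluate(np.arange(0, 360, 30.0))
        w = iem.estimate_weights(np.zeros((12, 5)), c)
        np.testing.assert_allclose(w, 0.0)
        with pytest.raises(ValueError, match="all zero"):
            iem.invert_channel_responses(np.ones((2, 5)), w)

    def test_rank_deficient_design_rejected(self, basis):
        c = basis.evaluate(np.full(10, 45.0))  # single distinct angle
        with pytest.raises(ValueError, match="rank deficient"):
            iem.estimate_weights(np.zeros((10, 4)), c)

    def test_weight_error_shrinks_with_trials(self, basis):
        rng = np.random.default_rng(11)
        prefs = rng.uniform(0, 360, 30)
        w_true = basis.evaluate(prefs)
        errs = []
        for n in (72, 720):
            angles = rng.uniform(0, 360, n)
            c = basis.evaluate(angles)
            b = c @ w_true.T + rng.normal(0, 1.0, (n, 30))
            w_hat = iem.estimate_weights(b, c)
            errs.append(np.linalg.norm(w_hat - w_true))
        assert errs[1] < errs[0] / 2  # ~1/sqrt(10) expected

    def test_round_trip_reconstruction_peaks_at_training_angle(
            self, generative_trm, basis):
        trm, w_true, _ = generative_trm
        grid, profiles, coeffs = iem.invert_and_reconstruct(
            trm.responses, w_true, basis)
        angles = trm.trials["mgs_angle_deg"].to_numpy()
        for profile, angle in zip(profiles, angles):
            peak = iem.profile_peak_deg(grid, profile)
            assert abs(circdist_deg(peak, angle)) <= 0.5 + 1e-9

    def test_zero_test_data_flat_zero_reconstruction(self, generative_trm,
                                                     basis):
        trm, w_true, _ = generative_trm
        grid, profiles, _ = iem.invert_and_reconstruct(
            np.zeros((1, trm.n_voxels)), w_true, basis)
        np.testing.assert_allclose(profiles, 0.0, atol=1e-12)

    def test_pinv_matches_normal_equation_solve(self, basis):
        rng = np.random.default_rng(12)
        w = basis.evaluate(rng.uniform(0, 360, 25))
        b = rng.normal(0, 1, (6, 25))
        c_pinv = iem.invert_channel_responses(b, w)
        # independent oracle: least-squares solve of C W^T = B per trial
        c_ne = np.linalg.lstsq(w, b.T, rcond=None)[0].T
        grid = np.arange(0, 360, 1.0)
        p1 = c_pinv @ basis.evaluate(grid).T
        p2 = c_ne @ basis.evaluate(grid).T
        for a, bb in zip(p1, p2):
            pk1 = iem.profile_peak_deg(grid, a)
            pk2 = iem.profile_peak_deg(grid, bb)
            assert abs(circdist_deg(pk1, pk2)) <= 1.0


class TestAlignment:
    def test_single_trial_zero_reference_unchanged(self, basis):
        coeffs = basis.evaluate(0.0)[None, :]
        grid, avg = iem.align_and_average(coeffs, [0.0], basis)
        _, prof = iem.reconstruction_profiles(coeffs, basis)
        np.testing.assert_allclose(avg, prof[0], atol=1e-12)

    def test_aligned_average_peaks_at_zero(self, basis):
        angles = np.array([40.0, 200.0, 333.0])
        coeffs = basis.evaluate(angles)
        grid, avg = iem.align_and_average(coeffs, angles, basis)
        assert abs(circdist_deg(iem.profile_peak_deg(grid, avg), 0.0)) \
            <= 0.5 + 1e-9

    def test_rotational_equivariance_exact(self, basis):
        rng = np.random.default_rng(13)
        angles = rng.uniform(0, 360, 10)
        coeffs = basis.evaluate(angles)
        g1, a1 = iem.align_and_average(coeffs, angles, basis)
        rotated = basis.evaluate(wrap_deg(angles + 40.0))
        g2, a2 = iem.align_and_average(rotated, wrap_deg(angles + 40.0),
                                       basis)
        assert np.max(np.abs(a1 - a2)) < 1e-10

    def test_length_mismatch_rejected(self, basis):
        with pytest.raises(ValueError):
            iem.align_and_average(basis.evaluate([0.0, 90.0]), [0.0], basis)

    def test_constant_coefficient_shift_adds_constant(self, basis):
        # partition property: adding c to all channels adds c * 4.5 ... /1
        coeffs = basis.evaluate(123.0)[None, :]
        grid, base = iem.align_and_average(coeffs, [0.0], basis)
        _, shifted = iem.align_and_average(coeffs + 2.0, [0.0], basis)
        np.testing.assert_allclose(shifted - base,
                                   2.0 * basis.partition_constant,
                                   atol=1e-10)


class TestTrainingPurity:
    def test_weights_ignore_transformed_rows(self, wm_trm, basis):
        out1 = iem.train_and_reconstruct(
            iem.twofold_combine(wm_trm, seed=20), basis, "mgs")
        # scramble non-training rows, re-run with same pairing seed
        scrambled = iem.TrialResponseMatrix(
            responses=wm_trm.responses.copy(),
            trials=wm_trm.trials)
        mask = (wm_trm.trials["condition"] == "mirror_h").to_numpy()
        scrambled.responses[mask] = np.random.default_rng(21).normal(
            0, 5, scrambled.responses[mask].shape)
        out2 = iem.train_and_reconstruct(
            iem.twofold_combine(scrambled, seed=20), basis, "mgs")
        np.testing.assert_array_equal(out1["weights"], out2["weights"])


class TestVoxelTuning:
    def test_indicator_weight_peaks_at_channel_center(self, basis):
        w = np.zeros((1, 9))
        w[0, 3] = 1.0
        grid, _, peaks = iem.voxel_tuning_from_weights(w, basis)
        assert peaks[0] == pytest.approx(basis.centers_deg[3])

    def test_uniform_weights_flagged_flat(self, basis):
        grid, _, peaks = iem.voxel_tuning_from_weights(
            np.ones((1, 9)), basis)
        assert np.isnan(peaks[0])

    def test_recovers_preferred_angle_at_snr2(self, wm_dataset, wm_trm,
                                              basis):
        voxels, _, _ = wm_dataset
        comb = iem.twofold_combine(wm_trm, seed=22)
        out = iem.train_and_reconstruct(comb, basis, "mgs")
        _, _, peaks = iem.voxel_tuning_from_weights(out["weights"], basis)
        prefs = np.array([v.polar_angle_deg for v in voxels])
        err = np.abs(circdist_deg(peaks, prefs))
        assert np.median(err) < 20.0


class TestBootstrap:
    def test_single_iteration_matches_deterministic_pass(self, wm_trm,
                                                         basis):
        rng_seed = 30
        grid, profiles = iem.bootstrap_reconstruction(
            wm_trm, basis, "mgs", n_iter=1, seed=rng_seed)
        comb = iem.twofold_combine(
            wm_trm, seed=np.random.default_rng(rng_seed))
        out = iem.train_and_reconstruct(comb, basis, "mgs")
        np.testing.assert_allclose(profiles[0], out["profile"])

    def test_generative_data_every_iteration_peaks_at_zero(
            self, generative_trm, basis):
        trm, _, _ = generative_trm
        grid, profiles = iem.bootstrap_reconstruction(trm, basis, "mgs",
                                                      n_iter=10, seed=31)
        for p in profiles:
            assert abs(circdist_deg(iem.profile_peak_deg(grid, p), 0.0)) \
                <= 0.5 + 1e-9

    def test_mean_profile_converges_with_iterations(self, basis):
        # 8 runs -> 4 trials per cell, so re-pairing has real freedom
        voxels = synth.sample_ground_truth_voxels(40, seed=34,
                                                  ecc_range=(9, 11))
        trials = synth.make_wm_trial_schedule(8, seed=35)
        resp = synth.simulate_wm_dataset(trials, voxels, "mgs", snr=1.0,
                                         seed=36)
        trm = iem.TrialResponseMatrix(responses=resp, trials=trials)
        g, p_small = iem.bootstrap_reconstruction(trm, basis, "mgs",
                                                  n_iter=40, seed=32)
        _, p_big = iem.bootstrap_reconstruction(trm, basis, "mgs",
                                                n_iter=160, seed=33)
        across = p_big.std(axis=0).max()
        assert across > 0  # re-pairing actually perturbs the profile
        mc_scale = across / np.sqrt(40)
        assert np.max(np.abs(p_small.mean(0) - p_big.mean(0))) < 6 * mc_scale

    def test_invalid_iteration_count_rejected(self, wm_trm, basis):
        with pytest.raises(ValueError):
            iem.bootstrap_reconstruction(wm_trm, basis, n_iter=0)
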