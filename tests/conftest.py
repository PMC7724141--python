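import numpy as np
import pytest

from scwm import iem, stimulus, synth


@pytest.fixture(scope="session")
def movie():
    return stimulus.make_bar_aperture_sequence()


@pytest.fixture(scope="session")
def basis():
    return iem.make_channel_basis(9)


@pytest.fixture(scope="session")
def wm_dataset():
    """Small noisy MGS-encoded dataset: (voxels, trials, responses)."""
    voxels = synth.sample_ground_truth_voxels(60, seed=101,
                                              ecc_range=(9.0, 11.0))
    trials = synth.make_wm_trial_schedule(4, seed=102)
    responses = synth.simulate_wm_dataset(trials, voxels, "mgs", snr=2.0,
                                          seed=103)
    return voxels, trials, responses


@pytest.fixture(scope="session")
def wm_trm(wm_dataset):
    _, trials, responses = wm_dataset
    return iem.TrialResponseMatrix(responses=responses, trials=trials)


@pytest.fixture(scope="session")
def generative_trm(basis):
    """Noise-free dataset generated exactly from the channel model.

    Voxel weights are the basis evaluated at each voxel's preferred
    angle (the recoverable subspace), responses are C @ W^T.
    """
    rng = np.random.default_rng(7)
    prefs = rng.uniform(0.0, 360.0, 40)
    w_true = basis.evaluate(prefs)  # (40 voxels, 9 channels)
    trials = synth.make_wm_trial_schedule(4, seed=8)
    angles = trials["mgs_angle_deg"].to_numpy()
    c = iem.make_channel_coefficients(angles, basis)
    responses = c @ w_true.T
    trm = iem.TrialResponseMatrix(responses=responses, trials=trials)
    return trm, w_true, prefs
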