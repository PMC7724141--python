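"""Parametric hemodynamic response function and BOLD convolution.

The HRF is a difference of two gamma densities parameterized directly by
their modes: the delay to peak and the delay to undershoot (both in
seconds). Each component is scaled to unit peak before the undershoot is
subtracted with a fixed amplitude ratio, so the only free temporal
parameters are the two delays.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

DEFAULT_PEAK_S = 6.0
DEFAULT_UNDERSHOOT_S = 16.0
UNDERSHOOT_RATIO = 1.0 / 6.0
KERNEL_LENGTH_S = 33.0


def double_gamma_hrf(t, peak_s=DEFAULT_PEAK_S, undershoot_s=DEFAULT_UNDERSHOOT_S,
                     undershoot_ratio=UNDERSHOOT_RATIO):
    """Evaluate the HRF at times ``t`` (seconds).

    Gamma densities with unit scale have mode = shape - 1, so shape is set
    to delay + 1 for each component; components are normalized by their
    value at the mode (unit peak) before subtraction.
    """
    t = np.asarray(t, dtype=float)
    if peak_s <= 0 or undershoot_s <= 0:
        raise ValueError("HRF delays must be positive")
    pos = sps.gamma.pdf(t, a=peak_s + 1.0) / sps.gamma.pdf(peak_s, a=peak_s + 1.0)
    und = sps.gamma.pdf(t, a=undershoot_s + 1.0) / sps.gamma.pdf(
        undershoot_s, a=undershoot_s + 1.0)
    return pos - undershoot_ratio * und


def hrf_kernel(tr_s, peak_s=DEFAULT_PEAK_S, undershoot_s=DEFAULT_UNDERSHOOT_S):
    """HRF sampled on the TR grid, long enough to cover the undershoot."""
    t = np.arange(0.0, KERNEL_LENGTH_S, tr_s)
    return double_gamma_hrf(t, peak_s, undershoot_s)


def convolve_hrf(drive, tr_s, peak_s=DEFAULT_PEAK_S,
                 undershoot_s=DEFAULT_UNDERSHOOT_S):
    """Convolve neural drive (last axis = time, TR units) with the HRF.

    The result is truncated to the input length (causal filtering).
    """
    drive = np.asarray(drive, dtype=float)
    kern = hrf_kernel(tr_s, peak_s, undershoot_s)
    n = drive.shape[-1]
    if drive.ndim == 1:
        return np.convolve(drive, kern)[:n]
    from scipy.signal import fftconvolve

    shape = (1,) * (drive.ndim - 1) + (kern.size,)
    return fftconvolve(drive, kern.reshape(shape), axes=-1)[..., :n]
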