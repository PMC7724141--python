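"""Retinotopic mapping stimuli and the pRF forward model.

The effective stimulus is a binary aperture movie in visual-field
coordinates: a checkerboard bar 8 degrees wide sweeps across the display
in four 30 s passes (left-to-right, right-to-left, top-to-bottom,
bottom-to-top, in any order), with 12 s mean-luminance blanks at the
start and end of each run. At TR = 1.5 s that is 8 + 4*20 + 8 = 96
frames.

The same module houses the neural-drive computation (aperture projected
onto a 2D Gaussian receptive field) shared by the simulator and the pRF
fitting code, so the generative model and the fitted model are the same
code path by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

SWEEP_DIRECTIONS = ("L2R", "R2L", "T2B", "B2T")
DEFAULT_SWEEP_ORDER = SWEEP_DIRECTIONS
BAR_WIDTH_DEG = 8.0
SWEEP_S = 30.0
BLANK_S = 12.0


@dataclass
class StimulusMovie:
    """Aperture frames over TRs in visual-field coordinates.

    frames : (n_TR, height, width) array with values in [0, 1]
        (binary for rendered bars; fractional after downsampling).
    extent_deg : half-width of the modeled field of view.
    tr_s : frame duration (one frame per TR).
    """

    frames: np.ndarray
    extent_deg: float = 16.0
    tr_s: float = 1.5
    bar_centers_deg: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def xs(self) -> np.ndarray:
        """Pixel-center x coordinates (deg), ascending."""
        return np.linspace(-self.extent_deg, self.extent_deg,
                           self.frames.shape[2])

    @property
    def ys(self) -> np.ndarray:
        """Pixel-center y coordinates (deg), ascending (y up)."""
        return np.linspace(-self.extent_deg, self.extent_deg,
                           self.frames.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.tr_s


def bar_center_trajectory(n_steps, extent_deg):
    """Bar-center positions for one sweep: linear traversal of the extent.

    Centers sit at the midpoints of ``n_steps`` equal segments of
    [-extent, extent], so the bar's center crosses the full display over
    one sweep and sits nearest 0 at the sweep midpoint.
    """
    step = 2.0 * extent_deg / n_steps
    return -extent_deg + (np.arange(n_steps) + 0.5) * step


def make_bar_aperture_sequence(sweep_order=DEFAULT_SWEEP_ORDER, grid_size=64,
                               tr_s=1.5, extent_deg=16.0,
                               bar_width_deg=BAR_WIDTH_DEG,
                               sweep_s=SWEEP_S, blank_s=BLANK_S):
    """Render the bar-sweep aperture movie for one retinotopy run.

    Parameters
    ----------
    sweep_order : sequence of direction tokens from
        {"L2R", "R2L", "T2B", "B2T"}.
    grid_size : pixels per axis (>= 32).

    Returns
    -------
    StimulusMovie with blank_s/tr_s blank frames, then
    len(sweep_order) sweeps of sweep_s/tr_s frames each, then blanks.
    """
    if grid_size < 32:
        raise ValueError("grid_size must be >= 32")
    for d in sweep_order:
        if d not in SWEEP_DIRECTIONS:
            raise ValueError(
                f"unknown sweep direction {d!r}; expected one of "
                f"{SWEEP_DIRECTIONS}")
    n_blank = int(round(blank_s / tr_s))
    n_sweep = int(round(sweep_s / tr_s))

    xs = np.linspace(-extent_deg, extent_deg, grid_size)
    X, Y = np.meshgrid(xs, xs)
    centers = bar_center_trajectory(n_sweep, extent_deg)
    half = bar_width_deg / 2.0

    frames = []
    traj = []
    blank = np.zeros((grid_size, grid_size))
    frames.extend([blank] * n_blank)
    traj.extend([np.nan] * n_blank)
    for d in sweep_order:
        for c in centers:
            if d == "L2R":
                mask = np.abs(X - c) <= half
                pos = c
            elif d == "R2L":
                mask = np.abs(X + c) <= half
                pos = -c
            elif d == "B2T":
                mask = np.abs(Y - c) <= half
                pos = c
            else:  # T2B
                mask = np.abs(Y + c) <= half
                pos = -c
            frames.append(mask.astype(float))
            traj.append(pos)
    frames.extend([blank] * n_blank)
    traj.extend([np.nan] * n_blank)
    return StimulusMovie(frames=np.array(frames), extent_deg=extent_deg,
                         tr_s=tr_s, bar_centers_deg=np.array(traj))


def downsample_movie(movie: StimulusMovie, fraction=0.05, min_pixels=16):
    """Spatially downsample the movie by 2D bilinear interpolation.

    The target resolution is ``fraction`` of the original, floored at
    ``min_pixels`` pixels per axis so the coarse stage retains enough
    spatial structure on movies that are already low resolution.
    """
    h = movie.frames.shape[1]
    target = max(int(round(h * fraction)), int(min_pixels))
    target = min(target, h)
    if target == h:
        return movie
    zoom = target / h
    frames = ndimage.zoom(movie.frames, (1.0, zoom, zoom), order=1)
    frames = np.clip(frames, 0.0, 1.0)
    return StimulusMovie(frames=frames, extent_deg=movie.extent_deg,
                         tr_s=movie.tr_s, bar_centers_deg=movie.bar_centers_deg)


def gaussian_rf(xs, ys, x_deg, y_deg, sigma_deg):
    """Unit-height 2D Gaussian receptive field on the pixel grid."""
    if sigma_deg <= 0:
        raise ValueError("sigma must be positive")
    dx = xs[None, :] - x_deg
    dy = ys[:, None] - y_deg
    return np.exp(-(dx * dx + dy * dy) / (2.0 * sigma_deg ** 2))


def neural_drive(movie: StimulusMovie, x_deg, y_deg, sigma_deg):
    """Per-TR neural drive: aperture-RF overlap, full-field drive = 1.

    drive(t) = sum_pixels frame(t) * G / sum_pixels G, i.e. the
    Gaussian-weighted fraction of the field covered by the aperture.
    """
    g = gaussian_rf(movie.xs, movie.ys, x_deg, y_deg, sigma_deg)
    s = g.sum()
    if s == 0.0:  # RF so small/remote that it underflows between pixels
        return np.zeros(movie.n_frames)
    return movie.frames.reshape(movie.n_frames, -1) @ (g / s).ravel()
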