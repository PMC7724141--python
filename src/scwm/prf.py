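"""Gaussian population-receptive-field (pRF) model fitting.

Each voxel's time series is modeled as

    BOLD(t) = amplitude * (drive(t; x, y, sigma) conv HRF(peak, undershoot))
              + baseline

where drive is the overlap between the stimulus aperture and a 2D
Gaussian receptive field. Fitting proceeds in three stages, each seeding
the next:

1. a sparse grid search over (x, y, sigma) on a spatially downsampled
   aperture movie, with amplitude and baseline solved in closed form at
   every grid point;
2. a grid search over the two HRF delay parameters (time to peak, time
   to undershoot) holding the spatial parameters fixed;
3. a bounded quasi-Newton refinement of (x, y, sigma, peak, undershoot)
   against the full-resolution movie, amplitude and baseline again
   profiled out linearly.

Model goodness is r^2 = 1 - SSR/SST; the refinement never returns a fit
worse than its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .hrf import DEFAULT_PEAK_S, DEFAULT_UNDERSHOOT_S, convolve_hrf
from .stimulus import StimulusMovie, downsample_movie, gaussian_rf, neural_drive

DEFAULT_SIGMAS = (0.5, 1.0, 2.0, 4.0, 8.0)
PEAK_BOUNDS = (4.0, 9.0)
UNDERSHOOT_BOUNDS = (10.0, 20.0)


@dataclass
class PRFFit:
    """Fitted pRF parameters for one voxel."""

    x_deg: float
    y_deg: float
    sigma_deg: float
    hrf_peak_s: float = DEFAULT_PEAK_S
    hrf_undershoot_s: float = DEFAULT_UNDERSHOOT_S
    baseline: float = 0.0
    amplitude: float = 0.0
    r2: float = 0.0
    converged: bool = True
    hrf_identifiable: bool = True

    @property
    def polar_angle_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.y_deg, self.x_deg)) % 360.0)

    @property
    def eccentricity_deg(self) -> float:
        return float(np.hypot(self.x_deg, self.y_deg))


@dataclass
class GridSpec:
    """Coarse search grid over pRF position and size."""

    x_min: float = -16.0
    x_max: float = 16.0
    y_min: float = -16.0
    y_max: float = 16.0
    step: float = 2.0
    sigmas: tuple = DEFAULT_SIGMAS

    def points(self):
        xs = np.arange(self.x_min, self.x_max + 1e-9, self.step)
        ys = np.arange(self.y_min, self.y_max + 1e-9, self.step)
        X, Y, S = np.meshgrid(xs, ys, np.asarray(self.sigmas),
                              indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), S.ravel()])


def predict_bold(x_deg, y_deg, sigma_deg, movie: StimulusMovie,
                 hrf_peak_s=DEFAULT_PEAK_S,
                 hrf_undershoot_s=DEFAULT_UNDERSHOOT_S,
                 amplitude=1.0, baseline=0.0):
    """Noiseless forward prediction for one parameter set.

    Shares the drive and HRF code with the simulator, so a voxel
    simulated with these parameters is reproduced exactly.
    """
    drive = neural_drive(movie, x_deg, y_deg, sigma_deg)
    pred = convolve_hrf(drive, movie.tr_s, hrf_peak_s, hrf_undershoot_s)
    return amplitude * pred + baseline


def _r2(y, residual_ss):
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0
    return 1.0 - residual_ss / sst


def _profiled_fit(pred, y):
    """Solve y ~ a*pred + b in closed form; return (a, b, SSR)."""
    pc = pred - pred.mean()
    yc = y - y.mean()
    denom = float(pc @ pc)
    if denom == 0.0:
        return 0.0, float(y.mean()), float(yc @ yc)
    a = float(pc @ yc) / denom
    b = float(y.mean() - a * pred.mean())
    ssr = float(yc @ yc) - a * a * denom
    return a, b, max(ssr, 0.0)


def _candidate_predictions(movie: StimulusMovie, params,
                           peak_s=DEFAULT_PEAK_S,
                           undershoot_s=DEFAULT_UNDERSHOOT_S):
    """Unit-amplitude predictions for many (x, y, sigma) candidates."""
    frames = movie.frames.reshape(movie.n_frames, -1)
    xs, ys = movie.xs, movie.ys
    preds = np.empty((len(params), movie.n_frames))
    for i, (x, y, s) in enumerate(params):
        g = gaussian_rf(xs, ys, x, y, s)
        gs = g.sum()
        preds[i] = 0.0 if gs == 0.0 else frames @ (g / gs).ravel()
    return convolve_hrf(preds, movie.tr_s, peak_s, undershoot_s)


def coarse_grid_fit(ts, movie_downsampled: StimulusMovie, grid=None):
    """Sparse grid search stage; returns per-voxel seed PRFFit objects.

    ``ts`` is (n_voxels, n_TR) or (n_TR,). At each grid point the
    amplitude/baseline subproblem is linear, so the best grid point is
    found from centered correlations in one matrix product.
    """
    grid = grid or GridSpec(x_min=-movie_downsampled.extent_deg,
                            x_max=movie_downsampled.extent_deg,
                            y_min=-movie_downsampled.extent_deg,
                            y_max=movie_downsampled.extent_deg)
    params = grid.points()
    if len(params) == 0:
        raise ValueError("empty search grid")
    single = np.asarray(ts).ndim == 1
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if ts.shape[1] != movie_downsampled.n_frames:
        raise ValueError("time series length does not match movie frames")

    preds = _candidate_predictions(movie_downsampled, params)
    pc = preds - preds.mean(axis=1, keepdims=True)
    pnorm2 = np.einsum("ij,ij->i", pc, pc)
    ok = pnorm2 > 0
    yc = ts - ts.mean(axis=1, keepdims=True)
    ynorm2 = np.einsum("ij,ij->i", yc, yc)
    # r^2 at the profiled optimum = (p.y)^2 / (|p|^2 |y|^2)
    scores = (pc[ok] @ yc.T) ** 2 / pnorm2[ok, None]
    best = np.argmax(scores, axis=0)
    idx = np.flatnonzero(ok)[best]

    fits = []
    for v in range(ts.shape[0]):
        x, y, s = params[idx[v]]
        a, b, ssr = _profiled_fit(preds[idx[v]], ts[v])
        r2 = 0.0 if ynorm2[v] == 0 else 1.0 - ssr / ynorm2[v]
        fits.append(PRFFit(x_deg=x, y_deg=y, sigma_deg=s, baseline=b,
                           amplitude=a, r2=r2))
    return fits[0] if single else fits


def fit_hrf_delays(ts, coarse_fit: PRFFit, movie: StimulusMovie,
                   peak_bounds=PEAK_BOUNDS,
                   undershoot_bounds=UNDERSHOOT_BOUNDS,
                   peak_step=0.5, undershoot_step=1.0,
                   min_identifiable_r2=1e-3):
    """Grid-search the HRF delay pair holding spatial parameters fixed.

    Returns a PRFFit with updated delays, amplitude, baseline and r2.
    Flat or unfittable series keep the default delays and are flagged
    ``hrf_identifiable=False``.
    """
    if peak_bounds[0] >= peak_bounds[1] or \
            undershoot_bounds[0] >= undershoot_bounds[1]:
        raise ValueError("delay bounds must be (low, high) with low < high")
    ts = np.asarray(ts, dtype=float)
    drive = neural_drive(movie, coarse_fit.x_deg, coarse_fit.y_deg,
                         coarse_fit.sigma_deg)
    peaks = np.arange(peak_bounds[0], peak_bounds[1] + 1e-9, peak_step)
    unders = np.arange(undershoot_bounds[0], undershoot_bounds[1] + 1e-9,
                       undershoot_step)
    best = None
    for p in peaks:
        for u in unders:
            pred = convolve_hrf(drive, movie.tr_s, p, u)
            a, b, ssr = _profiled_fit(pred, ts)
            r2 = _r2(ts, ssr)
            if best is None or r2 > best[0]:
                best = (r2, p, u, a, b)
    r2, p, u, a, b = best
    if r2 < min_identifiable_r2:
        return replace(coarse_fit, hrf_peak_s=DEFAULT_PEAK_S,
                       hrf_undershoot_s=DEFAULT_UNDERSHOOT_S,
                       hrf_identifiable=False)
    return replace(coarse_fit, hrf_peak_s=float(p), hrf_undershoot_s=float(u),
                   amplitude=a, baseline=b, r2=r2, hrf_identifiable=True)


def refine_fit(ts, movie: StimulusMovie, seed_fit: PRFFit,
               sigma_bounds=(0.05, 16.0), max_iter=500, tol=1e-10):
    """Quasi-Newton refinement on the full-resolution movie.

    Optimizes (x, y, log sigma, peak delay, undershoot delay) with
    amplitude and baseline profiled out at every evaluation. Never
    returns an r^2 below the seed's; non-convergence keeps the seed-stage
    parameters and is flagged.
    """
    ts = np.asarray(ts, dtype=float)
    frames = movie.frames.reshape(movie.n_frames, -1)
    xs, ys = movie.xs, movie.ys
    sst = float(np.sum((ts - ts.mean()) ** 2))
    if sst == 0.0:
        return replace(seed_fit, converged=False)

    def objective(theta):
        x, y, logsig, p, u = theta
        g = gaussian_rf(xs, ys, x, y, np.exp(logsig))
        gs = g.sum()
        if gs == 0.0:
            return 1.0
        drive = frames @ (g / gs).ravel()
        pred = convolve_hrf(drive, movie.tr_s, p, u)
        _, _, ssr = _profiled_fit(pred, ts)
        return ssr / sst

    ext = movie.extent_deg
    x0 = np.array([seed_fit.x_deg, seed_fit.y_deg,
                   np.log(seed_fit.sigma_deg), seed_fit.hrf_peak_s,
                   seed_fit.hrf_undershoot_s])
    bounds = [(-1.5 * ext, 1.5 * ext), (-1.5 * ext, 1.5 * ext),
              (np.log(sigma_bounds[0]), np.log(sigma_bounds[1])),
              PEAK_BOUNDS, UNDERSHOOT_BOUNDS]
    res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                            options=dict(maxiter=max_iter, ftol=tol,
                                         gtol=1e-10))
    x, y, logsig, p, u = res.x
    g = gaussian_rf(xs, ys, x, y, np.exp(logsig))
    gs = g.sum()
    if gs == 0.0:
        return replace(seed_fit, converged=False)
    drive = frames @ (g / gs).ravel()
    pred = convolve_hrf(drive, movie.tr_s, p, u)
    a, b, ssr = _profiled_fit(pred, ts)
    r2 = 1.0 - ssr / sst
    if r2 < seed_fit.r2:
        return replace(seed_fit, converged=False)
    return PRFFit(x_deg=float(x), y_deg=float(y),
                  sigma_deg=float(np.exp(logsig)), hrf_peak_s=float(p),
                  hrf_undershoot_s=float(u), baseline=b, amplitude=a, r2=r2,
                  converged=bool(res.success),
                  hrf_identifiable=seed_fit.hrf_identifiable)


def fit_prf(bold, movie: StimulusMovie, grid=None, fit_hrf=True,
            refine=True, downsample_fraction=0.05, min_pixels=16):
    """Full three-stage pRF fit for a (n_voxels, n_TR) BOLD matrix."""
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    movie_ds = downsample_movie(movie, downsample_fraction, min_pixels)
    seeds = coarse_grid_fit(bold, movie_ds, grid)
    if isinstance(seeds, PRFFit):
        seeds = [seeds]
    fits = []
    for v, seed_fit in enumerate(seeds):
        f = seed_fit
        if fit_hrf:
            f = fit_hrf_delays(bold[v], f, movie)
        if refine:
            f = refine_fit(bold[v], movie, f)
        fits.append(f)
    return fits


def select_roi(fits, r2_threshold=0.1):
    """Indices of voxels passing the model threshold (inclusive)."""
    return np.array([i for i, f in enumerate(fits)
                     if f.r2 >= r2_threshold], dtype=int)


@dataclass
class FieldCoverageMap:
    """Pointwise maximum of unit-height pRF Gaussians over the field."""

    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray = field(repr=False)


def aggregate_fov(fits, extent_deg=16.0, grid_size=101):
    """Field-of-view coverage: max over voxels of unit pRF Gaussians.

    Each grid coordinate maps to the maximum pRF value across voxels, so
    the map is 1 at every fitted center and in [0, 1] everywhere.
    """
    if len(fits) == 0:
        raise ValueError("aggregate_fov requires at least one fit")
    xs = np.linspace(-extent_deg, extent_deg, grid_size)
    ys = np.linspace(-extent_deg, extent_deg, grid_size)
    values = np.zeros((grid_size, grid_size))
    for f in fits:
        np.maximum(values, gaussian_rf(xs, ys, f.x_deg, f.y_deg,
                                       f.sigma_deg), out=values)
    return FieldCoverageMap(xs=xs, ys=ys, values=values)


def polar_angle_histogram(fits, n_bins=16):
    """Fractional volume per polar-angle bin; fractions sum to 1.

    Returns (bin_edges_deg, fractions) with edges spanning [0, 360].
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(fits) == 0:
        raise ValueError("no fits to histogram")
    angles = np.array([f.polar_angle_deg for f in fits])
    counts, edges = np.histogram(angles, bins=n_bins, range=(0.0, 360.0))
    return edges, counts / counts.sum()


@dataclass
class SizeEccentricityStats:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    slope_stderr: float

    def slope_ci(self, n, level=0.95):
        """Confidence interval for the slope from the OLS standard error."""
        tcrit = sps.t.ppf(0.5 + level / 2.0, df=n - 2)
        return (self.slope - tcrit * self.slope_stderr,
                self.slope + tcrit * self.slope_stderr)


def size_eccentricity_stats(sizes, eccentricities=None):
    """OLS line of pRF size on eccentricity plus Pearson correlation.

    Accepts either a list of PRFFit/voxel objects with ``sigma_deg`` and
    ``eccentricity_deg`` attributes, or two arrays (sizes, eccs).
    """
    if eccentricities is None:
        eccentricities = np.array([f.eccentricity_deg for f in sizes])
        sizes = np.array([f.sigma_deg for f in sizes])
    sizes = np.asarray(sizes, dtype=float)
    eccentricities = np.asarray(eccentricities, dtype=float)
    if sizes.size < 3:
        raise ValueError("need at least 3 voxels")
    if np.ptp(eccentricities) == 0:
        raise ValueError("zero variance in eccentricity")
    res = sps.linregress(eccentricities, sizes)
    return SizeEccentricityStats(slope=res.slope, intercept=res.intercept,
                                 pearson_r=res.rvalue, p_value=res.pvalue,
                                 slope_stderr=res.stderr)
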