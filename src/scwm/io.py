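"""Readers and writers for the package's standard formats.

Tables (trial schedules, fit summaries, fidelity draws) are
tab-separated values with a header; matrices (BOLD, weights, aperture
movies) are written either as TSV or as NIfTI via nibabel, with voxels
along the first spatial axis and TRs along the fourth dimension.
Floats are serialized with 17 significant digits, which round-trips
float64 values exactly and keeps reruns byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.17g"


def write_table(df: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(mat, path):
    """Write a 2D matrix as headerless TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.atleast_2d(mat), delimiter="\t", fmt=FLOAT_FORMAT)


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_bold_nifti(bold, path, tr_s=1.5):
    """Write a (n_voxels, n_TR) matrix as a 4D NIfTI (voxels x 1 x 1 x TR)."""
    bold = np.asarray(bold, dtype=np.float64)
    img = nib.Nifti1Image(bold[:, None, None, :], affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr_s))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def read_bold_nifti(path) -> np.ndarray:
    data = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return data.reshape(-1, data.shape[-1])


def write_movie_nifti(movie, path):
    """Write aperture frames as (H x W x 1 x TR) NIfTI."""
    frames = np.moveaxis(np.asarray(movie.frames, dtype=np.float64), 0, -1)
    img = nib.Nifti1Image(frames[:, :, None, :], affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, movie.tr_s))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def fits_to_table(fits) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(fits):
        rows.append(dict(
            voxel=i, x_deg=f.x_deg, y_deg=f.y_deg, sigma_deg=f.sigma_deg,
            polar_angle_deg=f.polar_angle_deg,
            eccentricity_deg=f.eccentricity_deg,
            hrf_peak_s=f.hrf_peak_s, hrf_undershoot_s=f.hrf_undershoot_s,
            baseline=f.baseline, amplitude=f.amplitude, r2=f.r2,
            converged=f.converged, hrf_identifiable=f.hrf_identifiable))
    return pd.DataFrame(rows)


def table_to_fits(df: pd.DataFrame):
    from .prf import PRFFit

    return [PRFFit(x_deg=r.x_deg, y_deg=r.y_deg, sigma_deg=r.sigma_deg,
                   hrf_peak_s=r.hrf_peak_s,
                   hrf_undershoot_s=r.hrf_undershoot_s, baseline=r.baseline,
                   amplitude=r.amplitude, r2=r.r2, converged=bool(r.converged),
                   hrf_identifiable=bool(r.hrf_identifiable))
            for r in df.itertuples()]
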