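"""Temporal filtering, voxelwise normalization, spatial smoothing.

The preprocessing chain mirrors a standard block-design fMRI stream:
removal of low frequencies up to a few cycles per scan (mean, linear
trend, and sine/cosine pairs projected out by regression), z-score
normalization of each voxel's time course, and 3-D Gaussian spatial
smoothing specified by its FWHM in millimetres.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import BOLDRun

__all__ = [
    "lowfreq_basis",
    "highpass_detrend",
    "zscore_voxelwise",
    "smooth_gaussian",
    "fwhm_to_sigma",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm * FWHM_TO_SIGMA


def lowfreq_basis(n_vols: int, n_cycles: int) -> np.ndarray:
    """Regressor basis spanning mean, linear trend, and slow sinusoids.

    Columns: constant, centered linear ramp, then sin/cos pairs at
    1..n_cycles cycles per run. Shape (n_vols, 2 + 2*n_cycles).
    """
    if n_vols < 2:
        raise ValueError("need at least 2 time points")
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    t = np.arange(n_vols, dtype=float)
    cols = [np.ones(n_vols), t - t.mean()]
    for k in range(1, n_cycles + 1):
        arg = 2.0 * np.pi * k * t / n_vols
        cols.append(np.sin(arg))
        cols.append(np.cos(arg))
    return np.column_stack(cols)


def _residual_projector(basis: np.ndarray) -> np.ndarray:
    """Orthonormal Q of the basis; residual = y - Q (Q^T y)."""
    q, _ = np.linalg.qr(basis)
    return q


def project_out(arr: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project the column space of ``basis`` out of time series.

    ``arr`` has time on its last axis, matching basis rows.
    """
    if arr.shape[-1] != basis.shape[0]:
        raise ValueError("time axis length must match basis rows")
    q = _residual_projector(basis)
    return arr - (arr @ q) @ q.T


def highpass_detrend(run: BOLDRun, n_cycles: int = 3) -> BOLDRun:
    """Remove mean, linear trend and slow sinusoids up to n_cycles/run.

    Realized as regression rather than FFT masking: the output is, per
    voxel, exactly orthogonal to each removed regressor, and a second
    application is a no-op.
    """
    if run.n_vols <= 2 * n_cycles + 2:
        raise ValueError(
            f"run of {run.n_vols} volumes too short to remove "
            f"{2 * n_cycles + 2} low-frequency regressors"
        )
    basis = lowfreq_basis(run.n_vols, n_cycles)
    return run.copy_with(project_out(run.data, basis))


def zscore_voxelwise(run: BOLDRun, qc: dict | None = None) -> BOLDRun:
    """Normalize each voxel's time course to mean 0, SD 1.

    Constant voxels (temporal SD of 0) would divide by zero; they are
    set to all-zero output and their indices recorded under
    ``qc['constant_voxels']`` and in the returned run's own qc dict.
    """
    data = run.data
    mean = data.mean(axis=-1, keepdims=True)
    sd = data.std(axis=-1, keepdims=True)
    constant = sd[..., 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (data - mean) / safe_sd
    out[constant, :] = 0.0
    flagged = np.argwhere(constant)
    if qc is not None:
        qc["constant_voxels"] = flagged
    result = run.copy_with(out)
    result.qc["constant_voxels"] = flagged
    return result


def smooth_gaussian(
    vol: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm,
    renormalize_edges: bool = True,
) -> np.ndarray:
    """Spatial Gaussian smoothing of a 3-D volume or 4-D (x,y,z,t) array.

    sigma (voxels) = fwhm_mm / (2 sqrt(2 ln 2)) / voxel_size per axis.
    fwhm_mm = 0 is the identity. With ``renormalize_edges`` the kernel
    is renormalized where it overhangs the volume border, so constants
    pass through unchanged even at edges (no darkening on small grids).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    vol = np.asarray(vol, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_size_mm
    if vol.ndim == 3:
        sigma = tuple(sigma_vox)
    elif vol.ndim == 4:
        sigma = (*sigma_vox, 0.0)
    else:
        raise ValueError("expected a 3-D volume or 4-D (x,y,z,t) array")
    out = gaussian_filter(vol, sigma=sigma, mode="constant", cval=0.0)
    if renormalize_edges:
        norm = gaussian_filter(np.ones(vol.shape[:3]), sigma=tuple(sigma_vox), mode="constant", cval=0.0)
        out = out / (norm if vol.ndim == 3 else norm[..., None])
    return out


def smooth_run(run: BOLDRun, fwhm_mm: float) -> BOLDRun:
    """Apply spatial smoothing to every volume of a run."""
    return run.copy_with(smooth_gaussian(run.data, fwhm_mm, run.voxel_size_mm))
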