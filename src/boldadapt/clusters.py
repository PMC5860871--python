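"""Cluster-extent correction for voxelwise group maps.

Family-wise error is controlled by requiring supra-threshold voxels to
form connected clusters of at least k voxels, with k calibrated by
Monte-Carlo simulation: smooth Gaussian null fields are generated on
the analysis mask, thresholded voxelwise, and the distribution of the
maximum cluster extent determines the smallest k whose exceedance
probability is at or below the chosen family-wise alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .preprocess import smooth_gaussian
from .stats import StatMap

__all__ = [
    "ClusterTable",
    "label_clusters",
    "monte_carlo_cluster_threshold",
    "cluster_corrected_map",
]

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _CONNECTIVITY_STRUCTS[int(connectivity)]
    except KeyError:
        raise ValueError(
            f"connectivity must be one of {sorted(_CONNECTIVITY_STRUCTS)}, got {connectivity}"
        ) from None


@dataclass
class ClusterTable:
    """Connected supra-threshold clusters and their extents.

    ``table`` has one row per cluster: cluster_id, extent, peak_z,
    peak_ijk, corrected_pass. ``labels`` is the cluster-id volume
    (0 = background). Clusters are disjoint by construction and
    partition the supra-threshold voxels exactly.
    """

    table: pd.DataFrame
    labels: np.ndarray
    connectivity: int
    extent_threshold: int = 1

    @property
    def n_clusters(self) -> int:
        return int(len(self.table))

    @property
    def passing(self) -> pd.DataFrame:
        return self.table[self.table["corrected_pass"]]

    def voxels(self, cluster_id: int) -> np.ndarray:
        return np.argwhere(self.labels == cluster_id)


def label_clusters(
    binary_map: np.ndarray,
    connectivity: int = 26,
    z_map: np.ndarray | None = None,
    extent_threshold: int = 1,
) -> ClusterTable:
    """Connected components of a supra-threshold binary volume.

    Peak location is the member voxel with largest |z| when a z volume
    is supplied, else the first member in scan order.
    """
    if extent_threshold < 1:
        raise ValueError("extent_threshold must be >= 1")
    binary = np.asarray(binary_map, dtype=bool)
    labels, n = ndimage.label(binary, structure=_structure(connectivity))
    rows = []
    for cid in range(1, n + 1):
        members = np.argwhere(labels == cid)
        if z_map is not None:
            zvals = z_map[tuple(members.T)]
            peak = members[int(np.nanargmax(np.abs(zvals)))]
            peak_z = float(z_map[tuple(peak)])
        else:
            peak = members[0]
            peak_z = np.nan
        rows.append(
            {
                "cluster_id": cid,
                "extent": int(members.shape[0]),
                "peak_z": peak_z,
                "peak_ijk": tuple(int(v) for v in peak),
                "corrected_pass": members.shape[0] >= extent_threshold,
            }
        )
    table = pd.DataFrame(
        rows, columns=["cluster_id", "extent", "peak_z", "peak_ijk", "corrected_pass"]
    )
    return ClusterTable(
        table=table,
        labels=labels,
        connectivity=int(connectivity),
        extent_threshold=int(extent_threshold),
    )


def null_max_extents(
    mask: np.ndarray,
    smoothness_fwhm_mm: float,
    voxel_size_mm,
    voxel_alpha: float,
    n_iter: int,
    seed: int,
    connectivity: int = 26,
) -> np.ndarray:
    """Maximum cluster extents of simulated null fields.

    Each iteration draws one white Gaussian field, smooths it to the
    target FWHM, standardizes it to unit variance within the mask,
    thresholds two-sidedly at the voxel alpha, and records the largest
    cluster. To keep the smoothed null field stationary on small
    grids, the white field is drawn on a grid padded by ~3 kernel
    sigmas per side and cropped back after smoothing (no padding when
    FWHM is 0, so unsmoothed draws are exactly rng.standard_normal of
    the mask shape).
    """
    from .preprocess import fwhm_to_sigma

    mask = np.asarray(mask, dtype=bool)
    struct = _structure(connectivity)
    z_crit = sps.norm.isf(voxel_alpha / 2.0)
    rng = np.random.default_rng(seed)
    voxel_sizes = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_to_sigma(smoothness_fwhm_mm) / voxel_sizes
    pad = np.ceil(3.0 * sigma_vox).astype(int) if smoothness_fwhm_mm > 0 else np.zeros(3, int)
    shape = tuple(s + 2 * p for s, p in zip(mask.shape, pad))
    crop = tuple(slice(p, p + s) for s, p in zip(mask.shape, pad))
    out = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        field = rng.standard_normal(shape)
        if smoothness_fwhm_mm > 0:
            field = smooth_gaussian(
                field, smoothness_fwhm_mm, voxel_sizes, renormalize_edges=False
            )
        field = field[crop]
        vals = field[mask]
        field = (field - vals.mean()) / vals.std()
        supra = (np.abs(field) >= z_crit) & mask
        labels, n = ndimage.label(supra, structure=struct)
        if n == 0:
            out[i] = 0
        else:
            out[i] = int(np.bincount(labels.ravel())[1:].max())
    return out


def monte_carlo_cluster_threshold(
    mask: np.ndarray,
    smoothness_fwhm_mm: float,
    voxel_size_mm,
    voxel_alpha: float = 0.05,
    fwe_alpha: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
    return_extents: bool = False,
):
    """Cluster extent threshold k from Monte-Carlo null simulation.

    k is the smallest extent whose exceedance by the null maximum
    cluster is empirically at most ``fwe_alpha``: with extents sorted
    descending, k = extents[ceil(fwe_alpha * n_iter)] + 1 (the
    empirical (1 - fwe_alpha) quantile + 1 convention, resolved at the
    Monte-Carlo precision of 1/n_iter), and at least 1 — so as
    fwe_alpha approaches 1 any cluster passes.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    if not (0 < voxel_alpha < 1 and 0 < fwe_alpha < 1):
        raise ValueError("alphas must lie in (0, 1)")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    extents = null_max_extents(
        mask, smoothness_fwhm_mm, voxel_size_mm, voxel_alpha, n_iter, seed, connectivity
    )
    desc = np.sort(extents)[::-1]
    cut = int(np.ceil(fwe_alpha * n_iter))
    k = 1 if cut >= n_iter else int(desc[cut]) + 1
    k = max(k, 1)
    if return_extents:
        return k, extents
    return k


def cluster_corrected_map(
    stat_map: StatMap,
    voxel_alpha: float = 0.05,
    k: int = 1,
    connectivity: int = 26,
) -> ClusterTable:
    """Threshold a StatMap voxelwise and keep clusters of extent >= k."""
    if k < 1:
        raise ValueError("extent threshold k must be >= 1")
    with np.errstate(invalid="ignore"):
        supra = (stat_map.p < voxel_alpha) & stat_map.mask & np.isfinite(stat_map.p)
    return label_clusters(
        supra, connectivity=connectivity, z_map=stat_map.z, extent_threshold=k
    )
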