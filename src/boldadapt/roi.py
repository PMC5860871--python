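"""ROI-level adaptation analysis.

Betas are averaged across the ROI's voxels per TOA condition, the
decay model is fitted to the four averaged betas per subject, and the
per-subject time constants are compared between groups with a
Mann-Whitney test. Averaging betas over voxels is equivalent, for OLS
with a design shared across voxels, to averaging the time series first
and re-fitting the GLM (the GLM is linear in the data); the unit tests
verify this rather than assume it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import DecayParams, fit_decay
from .glm import BetaMap
from .stats import DEFAULT_EXACT_LIMIT, effect_size_r, mann_whitney_z
from .types import ROIMask

__all__ = ["roi_mean_betas", "roi_fit_decay", "ROIGroupResult", "roi_group_compare"]

log = logging.getLogger(__name__)


def roi_mean_betas(beta_map: BetaMap, roi: ROIMask) -> dict:
    """Per-TOA arithmetic mean of betas over the ROI's voxels.

    Missing-valued (NaN) voxels are excluded from the mean; an ROI with
    no finite voxel at all is rejected.
    """
    if roi.mask.shape != beta_map.grid_shape:
        raise ValueError("ROI mask is not on the beta map grid")
    vals = beta_map.betas[roi.mask]  # (n_roi_voxels, n_toa)
    finite = np.isfinite(vals).all(axis=1)
    if not finite.any():
        raise ValueError(f"ROI '{roi.name}' contains no finite-valued voxels")
    n_missing = int((~finite).sum())
    if n_missing:
        log.info("ROI %s: excluded %d missing-valued voxels", roi.name, n_missing)
    means = vals[finite].mean(axis=0)
    return {float(t): float(m) for t, m in zip(beta_map.toas_s, means)}


def roi_fit_decay(beta_map: BetaMap, roi: ROIMask, **fit_kwargs) -> DecayParams:
    """Decay fit on the ROI-averaged betas."""
    return fit_decay(roi_mean_betas(beta_map, roi), **fit_kwargs)


@dataclass
class ROIGroupResult:
    """Group comparison of ROI-level adaptation time constants."""

    roi_name: str
    table: pd.DataFrame  # subject, group, a, b, tau_s, sse, valid, reason
    u: float
    z: float
    p: float
    r: float
    n1: int
    n2: int
    median_tau: dict  # group label -> median fitted tau

    def summary_row(self) -> dict:
        groups = list(self.median_tau)
        return {
            "roi": self.roi_name,
            "n1": self.n1,
            "n2": self.n2,
            "U": self.u,
            "z": self.z,
            "p": self.p,
            "r": self.r,
            **{f"median_tau_{g}": self.median_tau[g] for g in groups},
        }


def roi_group_compare(
    subject_beta_maps,
    roi: ROIMask,
    group_labels,
    groups: tuple | None = None,
    exact_limit: int | None = DEFAULT_EXACT_LIMIT,
    **fit_kwargs,
) -> ROIGroupResult:
    """ROI decay fit per subject, then Mann-Whitney on the fitted taus.

    ``group_labels`` aligns with ``subject_beta_maps``; ``groups``
    optionally fixes the (first, second) group order (z is signed
    first - second). Subjects whose ROI fit is invalid are excluded
    and logged; each group must retain >= 2 subjects.
    """
    labels = list(group_labels)
    maps = list(subject_beta_maps)
    if len(labels) != len(maps):
        raise ValueError("one group label per subject beta map required")
    if groups is None:
        groups = tuple(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for i, (bm, grp) in enumerate(zip(maps, labels)):
        fit = roi_fit_decay(bm, roi, **fit_kwargs)
        rows.append(
            {
                "subject": i,
                "group": grp,
                "a": fit.a,
                "b": fit.b,
                "tau_s": fit.tau_s,
                "sse": fit.sse,
                "valid": fit.valid,
                "reason": fit.reason,
            }
        )
    table = pd.DataFrame(rows)
    dropped = table[~table["valid"]]
    if len(dropped):
        log.warning(
            "ROI %s: excluded %d subjects with invalid fits (%s)",
            roi.name,
            len(dropped),
            ", ".join(dropped["reason"].unique()),
        )
    kept = table[table["valid"]]
    x = kept.loc[kept["group"] == groups[0], "tau_s"].to_numpy()
    y = kept.loc[kept["group"] == groups[1], "tau_s"].to_numpy()
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"fewer than 2 valid subjects remain in a group for ROI '{roi.name}'"
        )
    u, z, p = mann_whitney_z(x, y, exact_limit=exact_limit)
    r = effect_size_r(z, x.size + y.size)
    return ROIGroupResult(
        roi_name=roi.name,
        table=table,
        u=u,
        z=z,
        p=p,
        r=r,
        n1=int(x.size),
        n2=int(y.size),
        median_tau={groups[0]: float(np.median(x)), groups[1]: float(np.median(y))},
    )
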