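"""Nonparametric group comparison: Mann-Whitney U, z, p and effect size.

Rank tests are used for comparing the per-subject adaptation time
constants because tau estimates are noisy and right-skewed; ranks keep
extreme values from being over-weighted. Conventions:

* U counts pairs where the first sample exceeds the second (ties count
  one half), so U = R1 - n1(n1+1)/2 with R1 the first sample's rank sum.
* z uses the normal approximation with tie-corrected variance and a
  0.5 continuity correction shrunk toward zero.
* For small samples (n1+n2 <= exact_limit) the p-value comes from
  exhaustive enumeration of all C(n, n1) group labelings.
* Effect size r = z / sqrt(n1+n2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "mann_whitney_z",
    "effect_size_r",
    "exact_mw_distribution",
    "StatMap",
    "voxelwise_group_map",
]

DEFAULT_EXACT_LIMIT = 12


def _rank_stats(x: np.ndarray, y: np.ndarray):
    """Vectorized U / z / p for column-stacked samples.

    x: (n1, m), y: (n2, m). Returns (u, z, p) of length m, NaN where
    any input value is non-finite.
    """
    n1, m = x.shape
    n2 = y.shape[0]
    n = n1 + n2
    w = np.concatenate([x, y], axis=0)
    finite = np.all(np.isfinite(w), axis=0)
    ranks = sps.rankdata(w, axis=0, method="average")
    r1 = ranks[:n1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0

    # tie correction: sum over tie groups of (t^3 - t), computed from
    # within-run positions of the sorted values (element at 1-based
    # position p of its run contributes 3 p (p-1)).
    s = np.sort(w, axis=0)
    idx = np.arange(n)[:, None]
    new_run = np.ones((n, m), dtype=bool)
    new_run[1:] = s[1:] != s[:-1]
    run_start = np.maximum.accumulate(np.where(new_run, idx, 0), axis=0)
    pos = idx - run_start
    tie_sum = (3.0 * (pos + 1) * pos).sum(axis=0)

    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    d = u - mu
    d_cc = np.sign(d) * np.maximum(np.abs(d) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, d_cc / np.where(sd > 0, sd, 1.0), 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    u = np.where(finite, u, np.nan)
    z = np.where(finite, z, np.nan)
    p = np.where(finite, p, np.nan)
    return u, z, p


def exact_mw_distribution(values: np.ndarray, n1: int) -> np.ndarray:
    """U statistics of every C(n, n1) assignment of ``values`` to group 1.

    Exhaustive-enumeration null distribution given the observed pooled
    values (so ties are conditioned on).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = sps.rankdata(values)
    offset = n1 * (n1 + 1) / 2.0
    out = np.empty(comb(n, n1))
    for i, c in enumerate(combinations(range(n), n1)):
        out[i] = ranks[list(c)].sum() - offset
    return out


def mann_whitney_z(x, y, exact_limit: int | None = DEFAULT_EXACT_LIMIT):
    """Two-sample Mann-Whitney comparison.

    Returns (U, z, p_two_sided). When n1+n2 <= exact_limit the p-value
    is the exact two-sided tail probability P(|U' - mu| >= |U - mu|)
    under exhaustive enumeration; otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    u, z, p = _rank_stats(x[:, None], y[:, None])
    u, z, p = float(u[0]), float(z[0]), float(p[0])
    n = x.size + y.size
    if exact_limit is not None and n <= exact_limit:
        dist = exact_mw_distribution(np.concatenate([x, y]), x.size)
        mu = x.size * y.size / 2.0
        p = float(np.mean(np.abs(dist - mu) >= np.abs(u - mu) - 1e-12))
    return u, z, p


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-test effect size r = z / sqrt(N)."""
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    return float(z) / np.sqrt(n_total)


@dataclass
class StatMap:
    """Voxelwise group-difference statistics inside a mask.

    Volumes are NaN outside the mask (and in masked voxels where any
    subject's value was non-finite, e.g. a non-identifiable tau).
    """

    u: np.ndarray
    z: np.ndarray
    p: np.ndarray
    r: np.ndarray
    mask: np.ndarray
    n1: int
    n2: int


def _stack_subject_maps(maps) -> np.ndarray:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected a sequence of 3-D subject maps")
    return arr


def voxelwise_group_map(
    tau_maps_group1,
    tau_maps_group2,
    mask: np.ndarray,
    exact_limit: int | None = None,
) -> StatMap:
    """Mann-Whitney comparison of per-subject tau at every masked voxel.

    ``tau_maps_group*`` are sequences of 3-D volumes (one per subject)
    on a common grid. z is signed group1 - group2. The normal
    approximation is used by default (set ``exact_limit`` to switch the
    p-values to exhaustive enumeration per voxel for small cohorts).
    """
    g1 = _stack_subject_maps(tau_maps_group1)
    g2 = _stack_subject_maps(tau_maps_group2)
    if g1.shape[1:] != g2.shape[1:]:
        raise ValueError("group maps are on different grids")
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 subjects per group")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != g1.shape[1:]:
        raise ValueError("mask does not match map grid")
    x = g1[:, mask]
    y = g2[:, mask]
    u, z, p = _rank_stats(x, y)
    if exact_limit is not None and n1 + n2 <= exact_limit:
        for j in range(x.shape[1]):
            if np.all(np.isfinite(x[:, j])) and np.all(np.isfinite(y[:, j])):
                _, _, p[j] = mann_whitney_z(x[:, j], y[:, j], exact_limit)
    r = z / np.sqrt(n1 + n2)
    grid = g1.shape[1:]
    vols = []
    for vals in (u, z, p, r):
        vol = np.full(grid, np.nan)
        vol[mask] = vals
        vols.append(vol)
    return StatMap(u=vols[0], z=vols[1], p=vols[2], r=vols[3], mask=mask, n1=n1, n2=n2)
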