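"""Exponential decay model of BOLD adaptation.

The per-block GLM amplitude is modeled as a function of the block's
trial onset asynchrony (TOA):

    beta(TOA) = a + b * exp(-TOA / tau)

where ``a`` is the asymptotic BOLD level, ``b`` the magnitude of
adaptation, and ``tau`` the time constant of its decay — the quantity
compared between groups. With the four TOA points of the study design
this is a 3-parameter least-squares problem.

It is solved by variable projection: for any fixed tau the model is
linear in (a, b), so (a, b) come from a 2x2 linear solve and the
problem reduces to a 1-D search over tau. A log-spaced tau grid
locates the basin and golden-section refinement on log(tau) polishes
it. The same vectorized path serves a single fit and whole-volume
maps, so scalar and map results agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import BetaMap

__all__ = [
    "DecayParams",
    "DecayMaps",
    "fit_decay",
    "fit_decay_batch",
    "fit_decay_map",
    "REASON_CODES",
]

REASON_CODES = {
    "ok": 0,
    "non_identifiable": 1,
    "tau_at_bound": 2,
    "negative_b": 3,
}
_REASON_NAMES = {v: k for k, v in REASON_CODES.items()}

DEFAULT_TAU_BOUNDS = (0.1, 60.0)
DEFAULT_TAU_GRID = 50


@dataclass(frozen=True)
class DecayParams:
    """One decay fit: (a, b, tau) with fit quality and validity.

    ``valid`` is False for non-identifiable fits (all betas equal) and
    for fits that ran into a tau bound; negative-b fits are kept valid
    but carry the 'negative_b' reason code.
    """

    a: float
    b: float
    tau_s: float
    sse: float
    valid: bool
    reason: str = "ok"

    def predict(self, toa_s) -> np.ndarray:
        toa_s = np.asarray(toa_s, dtype=float)
        if np.isnan(self.tau_s):
            return np.full_like(toa_s, self.a, dtype=float)
        return self.a + self.b * np.exp(-toa_s / self.tau_s)


def _linear_coeffs(toas: np.ndarray, b_mat: np.ndarray, tau: np.ndarray):
    """Best (a, b) and SSE for each column of b_mat at per-column tau.

    toas: (k,), b_mat: (k, n), tau: (n,). Degenerate designs (tau so
    small or large that exp(-TOA/tau) is numerically collinear with the
    constant) fall back to the constant-only fit so they cannot win the
    tau search.
    """
    x = np.exp(-toas[:, None] / tau[None, :])  # (k, n)
    k = toas.size
    sx = x.sum(axis=0)
    sxx = np.einsum("ij,ij->j", x, x)
    sy = b_mat.sum(axis=0)
    sxy = np.einsum("ij,ij->j", x, b_mat)
    det = k * sxx - sx * sx
    # variance of the regressor column; zero means collinear with constant
    degenerate = det <= 1e-12 * k * np.maximum(sxx, 1e-300)
    safe_det = np.where(degenerate, 1.0, det)
    a = (sxx * sy - sx * sxy) / safe_det
    b = (k * sxy - sx * sy) / safe_det
    mean = sy / k
    a = np.where(degenerate, mean, a)
    b = np.where(degenerate, 0.0, b)
    # residual form (not the normal-equation shortcut): immune to the
    # catastrophic cancellation that would flatten the SSE landscape
    # near perfect fits and stall the 1-D tau refinement
    resid = b_mat - a[None, :] - b[None, :] * x
    sse = np.einsum("ij,ij->j", resid, resid)
    return a, b, sse


def fit_decay_batch(
    toas_s,
    betas,
    tau_bounds: tuple = DEFAULT_TAU_BOUNDS,
    n_grid: int = DEFAULT_TAU_GRID,
    n_refine: int = 80,
):
    """Vectorized decay fits for beta matrix of shape (n_toa, n_series).

    Returns arrays (a, b, tau, sse, valid, reason_code), each of length
    n_series. tau is NaN where the fit is non-identifiable.
    """
    toas = np.asarray(toas_s, dtype=float)
    if np.unique(toas).size < 3:
        raise ValueError("need >= 3 distinct TOA values to fit (a, b, tau)")
    b_mat = np.asarray(betas, dtype=float)
    if b_mat.ndim == 1:
        b_mat = b_mat[:, None]
    if b_mat.shape[0] != toas.size:
        raise ValueError("betas must have one row per TOA")
    lo, hi = tau_bounds
    if not (0 < lo < hi):
        raise ValueError("tau bounds must satisfy 0 < lo < hi")
    n = b_mat.shape[1]

    # tau grid search (log-spaced), vectorized over series
    grid = np.geomspace(lo, hi, n_grid)
    sse_grid = np.empty((n_grid, n))
    for i, tau in enumerate(grid):
        _, _, sse_grid[i] = _linear_coeffs(toas, b_mat, np.full(n, tau))
    best = np.argmin(sse_grid, axis=0)

    # golden-section refinement on log(tau) within the bracketing cell
    log_grid = np.log(grid)
    left = log_grid[np.maximum(best - 1, 0)]
    right = log_grid[np.minimum(best + 1, n_grid - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(n_refine):
        span = right - left
        c = right - invphi * span
        d = left + invphi * span
        _, _, fc = _linear_coeffs(toas, b_mat, np.exp(c))
        _, _, fd = _linear_coeffs(toas, b_mat, np.exp(d))
        go_left = fc < fd
        right = np.where(go_left, d, right)
        left = np.where(go_left, left, c)
    tau = np.exp(0.5 * (left + right))
    a, b, sse = _linear_coeffs(toas, b_mat, tau)

    # keep the grid point if refinement did not improve on it (flat SSE)
    grid_best_sse = sse_grid[best, np.arange(n)]
    worse = sse > grid_best_sse
    if np.any(worse):
        tau = np.where(worse, grid[best], tau)
        a2, b2, sse2 = _linear_coeffs(toas, b_mat, tau)
        a, b, sse = (
            np.where(worse, a2, a),
            np.where(worse, b2, b),
            np.where(worse, sse2, sse),
        )

    reason = np.zeros(n, dtype=np.int8)
    valid = np.ones(n, dtype=bool)

    neg_b = b < 0
    reason[neg_b] = REASON_CODES["negative_b"]

    # a bound-constrained minimum has a flat basin at the edge; snap the
    # estimate to the bound so it is deterministic, and flag it censored
    at_lo = tau <= lo * (1 + 1e-3)
    at_hi = tau >= hi * (1 - 1e-3)
    at_bound = at_lo | at_hi
    if np.any(at_bound):
        tau = np.where(at_lo, lo, np.where(at_hi, hi, tau))
        a2, b2, sse2 = _linear_coeffs(toas, b_mat, tau)
        a = np.where(at_bound, a2, a)
        b = np.where(at_bound, b2, b)
        sse = np.where(at_bound, sse2, sse)
    valid[at_bound] = False
    reason[at_bound] = REASON_CODES["tau_at_bound"]

    scale = np.max(np.abs(b_mat), axis=0)
    flat = np.ptp(b_mat, axis=0) <= 1e-12 * np.maximum(scale, 1.0)
    a[flat] = b_mat.mean(axis=0)[flat]
    b[flat] = 0.0
    tau = np.where(flat, np.nan, tau)
    sse[flat] = 0.0
    valid[flat] = False
    reason[flat] = REASON_CODES["non_identifiable"]

    return a, b, tau, sse, valid, reason


def fit_decay(
    betas_by_toa,
    tau_bounds: tuple = DEFAULT_TAU_BOUNDS,
    n_grid: int = DEFAULT_TAU_GRID,
) -> DecayParams:
    """Fit the decay model to one set of per-TOA betas.

    ``betas_by_toa`` maps TOA (seconds) to beta, or is a pair
    (toas, betas) of equal-length sequences.
    """
    if isinstance(betas_by_toa, dict):
        toas = np.array(sorted(betas_by_toa), dtype=float)
        betas = np.array([betas_by_toa[t] for t in toas], dtype=float)
    else:
        toas, betas = betas_by_toa
        toas = np.asarray(toas, dtype=float)
        betas = np.asarray(betas, dtype=float)
    a, b, tau, sse, valid, reason = fit_decay_batch(
        toas, betas[:, None], tau_bounds=tau_bounds, n_grid=n_grid
    )
    return DecayParams(
        a=float(a[0]),
        b=float(b[0]),
        tau_s=float(tau[0]),
        sse=float(sse[0]),
        valid=bool(valid[0]),
        reason=_REASON_NAMES[int(reason[0])],
    )


@dataclass
class DecayMaps:
    """Voxelwise decay fits: parameter volumes plus validity/reason."""

    a: np.ndarray
    b: np.ndarray
    tau_s: np.ndarray
    sse: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    mask: np.ndarray

    def tau_values(self, include_invalid: bool = True) -> np.ndarray:
        """Finite tau values inside the mask (optionally only valid fits)."""
        sel = self.mask & np.isfinite(self.tau_s)
        if not include_invalid:
            sel &= self.valid
        return self.tau_s[sel]


def fit_decay_map(
    beta_map: BetaMap,
    mask: np.ndarray | None = None,
    tau_bounds: tuple = DEFAULT_TAU_BOUNDS,
    n_grid: int = DEFAULT_TAU_GRID,
) -> DecayMaps:
    """Fit the decay model in every masked voxel of a BetaMap.

    Unmasked voxels are NaN in the parameter volumes; the reason volume
    holds REASON_CODES (-1 outside the mask).
    """
    grid_shape = beta_map.grid_shape
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid_shape:
        raise ValueError("mask must share the beta map grid")
    if not mask.any():
        raise ValueError("mask is empty")
    b_mat = beta_map.betas[mask].T  # (n_toa, n_masked)
    a, b, tau, sse, valid, reason = fit_decay_batch(
        beta_map.toas_s, b_mat, tau_bounds=tau_bounds, n_grid=n_grid
    )
    out = {}
    for name, vals in (("a", a), ("b", b), ("tau_s", tau), ("sse", sse)):
        vol = np.full(grid_shape, np.nan)
        vol[mask] = vals
        out[name] = vol
    valid_vol = np.zeros(grid_shape, dtype=bool)
    valid_vol[mask] = valid
    reason_vol = np.full(grid_shape, -1, dtype=np.int8)
    reason_vol[mask] = reason
    return DecayMaps(mask=mask, valid=valid_vol, reason=reason_vol, **out)
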