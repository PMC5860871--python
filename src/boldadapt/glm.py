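"""Block-design GLM: per-TOA predictors by HRF convolution, OLS betas.

Each constant-TOA block contributes an event train which, convolved with
the two-gamma HRF and sampled at the volume acquisition times, forms one
predictor per TOA condition (blocks of the same TOA across runs share a
column). Ordinary least squares per voxel yields one beta per TOA —
the block's event-evoked amplitude in signal units, because the HRF
kernel is max-normalized to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .hrf import TwoGammaHRF
from .types import BOLDRun, EventSchedule

__all__ = [
    "DesignMatrix",
    "BetaMap",
    "event_regressor",
    "build_design_matrix",
    "fit_glm",
    "bh_fdr",
    "select_task_responsive",
    "pooled_task_f",
]


def event_regressor(
    schedule: EventSchedule,
    hrf: TwoGammaHRF,
    frame_times_s: np.ndarray,
) -> np.ndarray:
    """Predicted response of a unit-amplitude event train at frame times.

    For impulse events (duration 0) the regressor is the exact
    superposition of HRF copies shifted to each onset. Boxcar events are
    convolved on an oversampled grid (step = HRF dt) and resampled.
    """
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    if schedule.duration_s == 0:
        lags = frame_times_s[:, None] - schedule.onsets_s[None, :]
        return hrf(lags).sum(axis=1)
    dt = hrf.params.dt_s
    t_end = frame_times_s[-1] + dt
    fine_t = np.arange(0.0, t_end + hrf.params.length_s, dt)
    neural = np.zeros_like(fine_t)
    for onset in schedule.onsets_s:
        on = (fine_t >= onset) & (fine_t < onset + schedule.duration_s)
        neural[on] += 1.0
    kernel = hrf.sample(dt)
    resp = np.convolve(neural, kernel * dt)[: fine_t.size] / schedule.duration_s
    return np.interp(frame_times_s, fine_t, resp)


@dataclass
class DesignMatrix:
    """GLM design: one column per TOA condition plus confounds.

    matrix
        (n_timepoints, n_columns) array; task columns first.
    toas_s
        TOA value of each task column, ascending.
    labels
        Column labels, e.g. 'toa_3' ... 'constant'.
    """

    matrix: np.ndarray
    toas_s: np.ndarray
    labels: list
    tr_s: float

    @property
    def n_timepoints(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_task(self) -> int:
        return int(self.toas_s.size)

    @property
    def task_matrix(self) -> np.ndarray:
        return self.matrix[:, : self.n_task]

    @property
    def confound_matrix(self) -> np.ndarray:
        return self.matrix[:, self.n_task :]

    def with_projection(self, basis: np.ndarray) -> "DesignMatrix":
        """Project a temporal basis out of the task columns.

        Used when the data were high-pass filtered: filtering the task
        predictors with the same projector keeps the per-TOA betas
        unbiased (equivalent to adding the basis as confound columns).
        """
        from .preprocess import project_out

        task = project_out(self.matrix[:, : self.n_task].T, basis).T
        mat = np.column_stack([task, self.matrix[:, self.n_task :]])
        return DesignMatrix(matrix=mat, toas_s=self.toas_s, labels=list(self.labels), tr_s=self.tr_s)


def build_design_matrix(
    schedules,
    tr_s: float,
    n_vols: int,
    hrf: TwoGammaHRF | None = None,
    add_constant: bool = True,
) -> DesignMatrix:
    """Build per-TOA predictors from block schedules.

    ``schedules`` is an iterable of EventSchedule; blocks with the same
    TOA are summed into a shared column. A constant confound column is
    appended by default (slow drift is assumed handled upstream).
    """
    hrf = hrf or TwoGammaHRF()
    schedules = list(schedules)
    if not schedules:
        raise ValueError("need at least one block schedule")
    run_end = n_vols * tr_s
    for sch in schedules:
        beyond = sch.onsets_s[sch.onsets_s >= run_end]
        if beyond.size:
            raise ValueError(
                f"onset {beyond[0]:g} s falls beyond run end ({run_end:g} s)"
            )
    frame_times = np.arange(n_vols) * tr_s
    toas = np.unique([sch.toa_s for sch in schedules])
    cols = []
    for toa in toas:
        col = np.zeros(n_vols)
        for sch in schedules:
            if sch.toa_s == toa:
                col += event_regressor(sch, hrf, frame_times)
        cols.append(col)
    labels = [f"toa_{toa:g}" for toa in toas]
    if add_constant:
        cols.append(np.ones(n_vols))
        labels.append("constant")
    return DesignMatrix(
        matrix=np.column_stack(cols), toas_s=toas, labels=labels, tr_s=tr_s
    )


@dataclass
class BetaMap:
    """Per-voxel GLM amplitudes, one per TOA condition, plus diagnostics.

    betas
        (x, y, z, n_toa) array of per-TOA amplitudes.
    resid_var
        Residual variance per voxel (RSS / df).
    df
        Residual degrees of freedom: n_timepoints - rank(design).
    rss_full / rss_reduced
        Residual sums of squares of the full model and of the
        confound-only model; their difference feeds the omnibus
        task-vs-baseline F test.
    """

    betas: np.ndarray
    toas_s: np.ndarray
    resid_var: np.ndarray
    df: int
    rss_full: np.ndarray
    rss_reduced: np.ndarray
    n_task: int
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.array([3.0, 3.0, 3.0]))

    @property
    def grid_shape(self) -> tuple:
        return self.betas.shape[:-1]

    def betas_by_toa(self) -> dict:
        return {float(t): self.betas[..., i] for i, t in enumerate(self.toas_s)}


def _check_full_rank(design: DesignMatrix) -> None:
    x = design.matrix
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [design.labels[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_glm(run: BOLDRun, design: DesignMatrix) -> BetaMap:
    """Ordinary least squares per voxel.

    Returns one beta per TOA condition per voxel, the residual variance,
    and the residual sums of squares of the full and confound-only
    models (for the omnibus task test).
    """
    if run.n_vols != design.n_timepoints:
        raise ValueError(
            f"run has {run.n_vols} volumes but design has {design.n_timepoints} rows"
        )
    _check_full_rank(design)
    x = design.matrix
    grid = run.grid_shape
    y = run.data.reshape(-1, run.n_vols).T  # (t, voxels)
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    rss_full = np.einsum("ij,ij->j", resid, resid)
    df = run.n_vols - x.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    xc = design.confound_matrix
    if xc.shape[1]:
        coef0, _, _, _ = np.linalg.lstsq(xc, y, rcond=None)
        resid0 = y - xc @ coef0
    else:
        resid0 = y
    rss_reduced = np.einsum("ij,ij->j", resid0, resid0)
    betas = coef[: design.n_task].T.reshape(*grid, design.n_task)
    return BetaMap(
        betas=betas,
        toas_s=design.toas_s.copy(),
        resid_var=(rss_full / df).reshape(grid),
        df=df,
        rss_full=rss_full.reshape(grid),
        rss_reduced=rss_reduced.reshape(grid),
        n_task=design.n_task,
        voxel_size_mm=run.voxel_size_mm.copy(),
    )


def average_beta_maps(maps) -> BetaMap:
    """Average per-TOA betas over runs; pool F-test inputs additively."""
    maps = list(maps)
    first = maps[0]
    for m in maps[1:]:
        if m.grid_shape != first.grid_shape or not np.array_equal(m.toas_s, first.toas_s):
            raise ValueError("beta maps do not share grid/TOA layout")
    return BetaMap(
        betas=np.mean([m.betas for m in maps], axis=0),
        toas_s=first.toas_s.copy(),
        resid_var=np.mean([m.resid_var for m in maps], axis=0),
        df=int(sum(m.df for m in maps)),
        rss_full=np.sum([m.rss_full for m in maps], axis=0),
        rss_reduced=np.sum([m.rss_reduced for m in maps], axis=0),
        n_task=int(sum(m.n_task for m in maps)),
        voxel_size_mm=first.voxel_size_mm.copy(),
    )


def bh_fdr(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection set.

    Rejects all p <= p_(k) where k = max{i : p_(i) <= i q / m}. Returns
    a boolean array of the same shape as ``pvals``.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order]
    passing = np.where(ranked <= (np.arange(1, m + 1) * q / m))[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject.reshape(p.shape)


def pooled_task_f(beta_maps) -> tuple:
    """Fixed-effects omnibus F of the TOA predictors, pooled over subjects.

    Numerator and denominator sums of squares are summed across the
    supplied per-subject BetaMaps; F = (sum dRSS / sum q) / (sum RSS /
    sum df) with q the number of task columns per subject. Returns
    (f_map, p_map, df_num, df_den).
    """
    beta_maps = list(beta_maps)
    num_ss = np.sum([m.rss_reduced - m.rss_full for m in beta_maps], axis=0)
    den_ss = np.sum([m.rss_full for m in beta_maps], axis=0)
    df_num = int(sum(m.n_task for m in beta_maps))
    df_den = int(sum(m.df for m in beta_maps))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (num_ss / df_num) / (den_ss / df_den)
    f = np.where(den_ss > 0, f, np.inf)
    p = sps.f.sf(f, df_num, df_den)
    return f, p, df_num, df_den


def select_task_responsive(beta_maps, q: float = 0.001) -> tuple:
    """Mask of voxels whose pooled task-vs-baseline F survives BH-FDR at q.

    Returns (mask, p_map). Warns if no voxel survives (downstream
    voxelwise stages should then halt).
    """
    _, p, _, _ = pooled_task_f(beta_maps)
    mask = bh_fdr(p, q)
    if not mask.any():
        warnings.warn(
            "no task-responsive voxels at FDR q=%g; voxelwise stages have "
            "nothing to analyze" % q,
            stacklevel=2,
        )
    return mask, p
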