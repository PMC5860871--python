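"""End-to-end orchestration: simulate -> preprocess -> GLM -> decay fit
-> group inference -> ROI analysis, with seeding and provenance.

Each stage is a pure function of (inputs, config, seed); a single
master seed expands deterministically into per-subject streams, so the
same config and seed reproduce every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clusters import ClusterTable, cluster_corrected_map, monte_carlo_cluster_threshold
from .decay import fit_decay_map
from .glm import (
    BetaMap,
    average_beta_maps,
    build_design_matrix,
    fit_glm,
    select_task_responsive,
)
from .hrf import HRFParams, TwoGammaHRF
from .preprocess import highpass_detrend, lowfreq_basis, smooth_run, zscore_voxelwise
from .roi import ROIGroupResult, roi_group_compare
from .stats import StatMap, voxelwise_group_map
from .synth import Cohort, CohortDesign, NoiseSpec, make_group_cohort
from .types import box_roi

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "subject_beta_map", "cohort_beta_maps"]

log = logging.getLogger(__name__)


def _asdict(obj):
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, np.generic):
            return v.item()
        return v

    return clean(d)


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the synthetic end-to-end analysis.

    Serializes round-trip through JSON so a provenance record suffices
    to regenerate any output.
    """

    # cohort
    n_control: int = 19
    n_dyslexic: int = 20
    tau_control_s: float = 10.0
    tau_dyslexic_s: float = 5.0
    between_subject_sd: float = 0.2
    design: CohortDesign = field(default_factory=CohortDesign)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    # preprocessing
    do_detrend: bool = True
    detrend_cycles: int = 3
    do_zscore: bool = True
    do_smooth: bool = True
    smooth_fwhm_mm: float = 4.0
    # GLM / selection
    fdr_q: float = 0.001
    # decay fit
    tau_bounds: tuple = (0.1, 60.0)
    tau_grid: int = 50
    # group inference
    voxel_alpha: float = 0.05
    fwe_alpha: float = 0.05
    mc_iters: int = 1000
    connectivity: int = 26
    # ROI geometry: an axis-aligned box (99 voxels by default)
    roi_corner: tuple = (0, 4, 4)
    roi_size: tuple = (11, 3, 3)
    # seeding
    seed: int = 0

    def to_json(self, **kwargs) -> str:
        return json.dumps(_asdict(self), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        raw["design"] = CohortDesign(
            **{
                **{k: v for k, v in raw["design"].items() if k != "hrf_params"},
                "toas_s": tuple(raw["design"]["toas_s"]),
                "grid_shape": tuple(raw["design"]["grid_shape"]),
                "hrf_params": HRFParams(**raw["design"]["hrf_params"]),
            }
        )
        raw["noise"] = NoiseSpec(**raw["noise"])
        for key in ("tau_bounds", "roi_corner", "roi_size"):
            raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def subject_beta_map(runs, schedules_per_run, config: PipelineConfig, hrf: TwoGammaHRF) -> BetaMap:
    """Preprocess one subject's runs and average per-run GLM betas.

    When high-pass filtering is on, the same low-frequency projection
    is applied to the task predictors so the per-TOA betas stay
    unbiased (equivalent to adding the basis as confounds).
    """
    per_run = []
    for run, schedules in zip(runs, schedules_per_run):
        if config.do_detrend:
            run = highpass_detrend(run, config.detrend_cycles)
        if config.do_zscore:
            run = zscore_voxelwise(run)
        if config.do_smooth and config.smooth_fwhm_mm > 0:
            run = smooth_run(run, config.smooth_fwhm_mm)
        design = build_design_matrix(schedules, run.tr_s, run.n_vols, hrf)
        if config.do_detrend:
            design = design.with_projection(lowfreq_basis(run.n_vols, config.detrend_cycles))
        per_run.append(fit_glm(run, design))
    return average_beta_maps(per_run)


def cohort_beta_maps(cohort: Cohort, config: PipelineConfig) -> list:
    """Per-subject BetaMaps: simulate, preprocess, GLM, average runs."""
    maps = []
    for i in range(cohort.n_subjects):
        runs = cohort.simulate_subject(i)
        schedules = [cohort.run_schedules(i, r) for r in range(cohort.design.n_runs)]
        maps.append(subject_beta_map(runs, schedules, config, cohort.hrf))
    return maps


@dataclass
class PipelineResult:
    """Everything the end-to-end analysis produces."""

    config: PipelineConfig
    cohort: Cohort
    beta_maps: list
    group_labels: list
    task_mask: np.ndarray
    decay_maps: list
    stat_map: StatMap | None
    extent_threshold: int | None
    cluster_table: ClusterTable | None
    group_mean_tau: dict
    roi_result: ROIGroupResult | None
    provenance: dict


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> PipelineResult:
    """Run the full synthetic analysis described by ``config``.

    Stages: cohort simulation; per-subject preprocessing and GLM;
    pooled task-responsive voxel selection (FDR); per-subject voxelwise
    decay fits; voxelwise Mann-Whitney group map with Monte-Carlo
    cluster-extent correction; group-mean-beta tau maps (the map-making
    path); ROI group comparison (the inference path).
    """
    config = config or PipelineConfig()
    t0 = time.time()
    timings = {}
    counts = {}

    cohort = make_group_cohort(
        n_control=config.n_control,
        n_dyslexic=config.n_dyslexic,
        tau_control_s=config.tau_control_s,
        tau_dyslexic_s=config.tau_dyslexic_s,
        between_subject_sd=config.between_subject_sd,
        noise=config.noise,
        design=config.design,
        seed=config.seed,
    )
    timings["simulate_setup"] = time.time() - t0

    t1 = time.time()
    beta_maps = cohort_beta_maps(cohort, config)
    group_labels = [s.group for s in cohort.subjects]
    timings["glm"] = time.time() - t1

    t1 = time.time()
    task_mask, _ = select_task_responsive(beta_maps, q=config.fdr_q)
    counts["task_responsive_voxels"] = int(task_mask.sum())
    timings["selection"] = time.time() - t1

    stat_map = None
    extent_threshold = None
    cluster_table = None
    decay_maps = []
    group_mean_tau = {}
    if task_mask.any():
        t1 = time.time()
        decay_maps = [
            fit_decay_map(bm, task_mask, tau_bounds=config.tau_bounds, n_grid=config.tau_grid)
            for bm in beta_maps
        ]
        counts["valid_fit_voxels"] = int(np.sum([dm.valid.sum() for dm in decay_maps]))
        # map-making path: fit the decay model to group-mean betas
        for grp in cohort.groups:
            idx = cohort.group_indices(grp)
            mean_bm = average_beta_maps([beta_maps[i] for i in idx])
            group_mean_tau[grp] = fit_decay_map(
                mean_bm, task_mask, tau_bounds=config.tau_bounds, n_grid=config.tau_grid
            )
        timings["decay_fit"] = time.time() - t1

        t1 = time.time()
        g1, g2 = cohort.groups
        stat_map = voxelwise_group_map(
            [decay_maps[i].tau_s for i in cohort.group_indices(g1)],
            [decay_maps[i].tau_s for i in cohort.group_indices(g2)],
            task_mask,
        )
        smoothness = config.smooth_fwhm_mm if config.do_smooth else config.noise.spatial_fwhm_mm
        extent_threshold = monte_carlo_cluster_threshold(
            task_mask,
            smoothness,
            np.broadcast_to(np.asarray(config.design.voxel_size_mm, float), (3,)),
            voxel_alpha=config.voxel_alpha,
            fwe_alpha=config.fwe_alpha,
            n_iter=config.mc_iters,
            seed=np.random.SeedSequence([config.seed, 0xC1]).generate_state(1)[0] % (2**31),
            connectivity=config.connectivity,
        )
        cluster_table = cluster_corrected_map(
            stat_map, config.voxel_alpha, extent_threshold, config.connectivity
        )
        counts["suprathreshold_voxels"] = int(
            np.nansum(stat_map.p[task_mask] < config.voxel_alpha)
        )
        counts["surviving_clusters"] = int(cluster_table.passing.shape[0])
        timings["group_inference"] = time.time() - t1
    else:
        log.warning("empty task-responsive mask; voxelwise stages skipped")

    t1 = time.time()
    roi_result = None
    try:
        roi = box_roi(
            config.design.grid_shape, config.roi_corner, config.roi_size, name="roi_box"
        )
        roi_result = roi_group_compare(
            beta_maps,
            roi,
            group_labels,
            groups=tuple(cohort.groups),
            tau_bounds=config.tau_bounds,
            n_grid=config.tau_grid,
        )
    except ValueError as exc:
        log.warning("ROI stage skipped: %s", exc)
    timings["roi"] = time.time() - t1

    provenance = {
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "counts": counts,
    }
    result = PipelineResult(
        config=config,
        cohort=cohort,
        beta_maps=beta_maps,
        group_labels=group_labels,
        task_mask=task_mask,
        decay_maps=decay_maps,
        stat_map=stat_map,
        extent_threshold=extent_threshold,
        cluster_table=cluster_table,
        group_mean_tau=group_mean_tau,
        roi_result=roi_result,
        provenance=provenance,
    )
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def write_results(result: PipelineResult, out_dir) -> None:
    """Write maps (NIfTI), tables (TSV) and provenance (JSON)."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = np.broadcast_to(np.asarray(result.config.design.voxel_size_mm, float), (3,))
    affine = np.diag([*vs, 1.0])

    def save_vol(arr, name, dtype=np.float32):
        nib.save(nib.Nifti1Image(np.asarray(arr).astype(dtype), affine), str(out / name))

    save_vol(result.task_mask, "task_mask.nii", np.uint8)
    if result.stat_map is not None:
        for nm in ("u", "z", "p", "r"):
            save_vol(getattr(result.stat_map, nm), f"group_{nm}.nii")
    for grp, dm in result.group_mean_tau.items():
        save_vol(dm.tau_s, f"tau_mean_{grp}.nii")
    if result.cluster_table is not None:
        tbl = result.cluster_table.table.copy()
        tbl["peak_ijk"] = tbl["peak_ijk"].map(lambda t: ",".join(map(str, t)))
        tbl.to_csv(out / "clusters.tsv", sep="\t", index=False)
    if result.roi_result is not None:
        result.roi_result.table.to_csv(out / "roi_fits.tsv", sep="\t", index=False)
        pd.DataFrame([result.roi_result.summary_row()]).to_csv(
            out / "roi_summary.tsv", sep="\t", index=False
        )
    prov = dict(result.provenance)
    prov["extent_threshold"] = result.extent_threshold
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
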