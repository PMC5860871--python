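"""Seeded synthetic BOLD cohorts with known adaptation ground truth.

The generator emulates the study design this package analyzes: two
groups of listeners (controls and dyslexic readers), each subject
scanned in 3 runs of 4 constant-TOA blocks (TOA in {3, 6, 9, 15} s,
16 trials per block, TR = 1 s). Every voxel's event-evoked amplitude
in a block follows the adaptation decay law

    amp(TOA) = a + b * exp(-TOA / tau)

with subject-level (a, b, tau) drawn around group centers (tau on the
log scale so it stays positive), so the full forward model is

    signal = sum_blocks amp(TOA) * (event train * HRF) + drift + noise.

With an all-zero NoiseSpec the run is the exact noiseless forward
model, which downstream stages must invert to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from .hrf import HRFParams, TwoGammaHRF
from .glm import event_regressor
from .preprocess import smooth_gaussian
from .types import BOLDRun, EventSchedule, make_event_schedule

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "CohortDesign",
    "SubjectSpec",
    "Cohort",
    "simulate_run",
    "make_group_cohort",
    "build_run_schedules",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive disturbances of a simulated run.

    sigma
        SD of the additive Gaussian noise, signal units. The default is
        calibrated so that voxelwise fitted-tau scatter is moderate
        (SD around 30% of the generating tau) under the default cohort.
    drift_amp
        Maximum amplitude of the slow cosine drift (uniform per-voxel
        amplitude in [0, drift_amp], one random phase per run).
    spatial_fwhm_mm
        Smoothness of the noise field; 0 means white noise (smoothed
        noise is rescaled back to per-voxel SD sigma).
    """

    sigma: float = 0.3
    drift_amp: float = 0.3
    spatial_fwhm_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.drift_amp < 0 or self.spatial_fwhm_mm < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def silent(self) -> bool:
        return self.sigma == 0 and self.drift_amp == 0


@dataclass
class GroundTruth:
    """Per-voxel generating parameters of one subject."""

    a_map: np.ndarray
    b_map: np.ndarray
    tau_map: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        self.a_map = np.asarray(self.a_map, dtype=float)
        self.b_map = np.asarray(self.b_map, dtype=float)
        self.tau_map = np.asarray(self.tau_map, dtype=float)
        if not (self.a_map.shape == self.b_map.shape == self.tau_map.shape):
            raise ValueError("ground-truth maps must share one grid")
        active = self.b_map != 0
        if np.any(~(self.tau_map[active] > 0)):
            raise ValueError("tau_map must be positive wherever b_map != 0")

    @property
    def grid_shape(self) -> tuple:
        return self.a_map.shape

    def block_amplitude(self, toa_s: float) -> np.ndarray:
        """Per-voxel event amplitude in a block of the given TOA."""
        amp = self.a_map.copy()
        active = self.b_map != 0
        amp[active] += self.b_map[active] * np.exp(-toa_s / self.tau_map[active])
        return amp


def _spans_overlap(schedules) -> bool:
    iv = sorted((s.start_s, s.end_s) for s in schedules)
    return any(iv[i + 1][0] < iv[i][1] for i in range(len(iv) - 1))


def simulate_run(
    ground_truth: GroundTruth,
    schedules,
    tr_s: float = 1.0,
    hrf: TwoGammaHRF | None = None,
    noise: NoiseSpec | None = None,
    n_vols: int | None = None,
    voxel_size_mm=3.0,
    rng: np.random.Generator | int | None = None,
) -> BOLDRun:
    """Forward-simulate one run from ground truth and block schedules.

    Per voxel: signal = sum over blocks of the block amplitude
    (a + b exp(-TOA/tau)) times the unit event train convolved with the
    HRF, plus drift and noise per the NoiseSpec.
    """
    hrf = hrf or TwoGammaHRF()
    noise = noise or NoiseSpec(0.0, 0.0, 0.0)
    schedules = list(schedules)
    if not schedules:
        raise ValueError("need at least one block schedule")
    if _spans_overlap(schedules):
        raise ValueError("block schedules have overlapping time spans")
    if n_vols is None:
        run_end = max(s.end_s for s in schedules) + hrf.params.length_s
        n_vols = int(np.ceil(run_end / tr_s)) + 1
    frame_times = np.arange(n_vols) * tr_s
    grid = ground_truth.grid_shape
    data = np.zeros((*grid, n_vols))
    for sch in schedules:
        reg = event_regressor(sch, hrf, frame_times)
        amp = ground_truth.block_amplitude(sch.toa_s)
        data += amp[..., None] * reg
    if not noise.silent:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        voxel_sizes = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
        if noise.drift_amp > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            amp = rng.uniform(0.0, noise.drift_amp, size=grid)
            drift = np.cos(2.0 * np.pi * frame_times / (n_vols * tr_s) + phase)
            data += amp[..., None] * drift
        if noise.sigma > 0:
            eps = rng.standard_normal((*grid, n_vols))
            if noise.spatial_fwhm_mm > 0:
                eps = smooth_gaussian(eps, noise.spatial_fwhm_mm, voxel_sizes)
                eps /= eps.std()
            data += noise.sigma * eps
    return BOLDRun(data=data, tr_s=tr_s, voxel_size_mm=np.broadcast_to(
        np.asarray(voxel_size_mm, dtype=float), (3,)).copy())


@dataclass(frozen=True)
class CohortDesign:
    """Scan/design layout of a synthetic cohort.

    Defaults mirror the study conditions: blocks of 16 trials at TOAs
    3/6/9/15 s, 3 runs of 4 blocks, TR 1 s, 12^3 grid of 3 mm voxels.
    The inter-block rest gap (20 s) keeps block responses from
    overlapping after HRF convolution; block order and the gap are
    exposed because the original scan protocol does not pin them down.
    """

    toas_s: tuple = (3.0, 6.0, 9.0, 15.0)
    n_trials: int = 16
    n_runs: int = 3
    tr_s: float = 1.0
    gap_s: float = 20.0
    lead_in_s: float = 10.0
    tail_s: float = 25.0
    duration_s: float = 0.0
    block_order: str = "fixed"  # 'fixed' | 'shuffled'
    grid_shape: tuple = (12, 12, 12)
    voxel_size_mm: float = 3.0
    a_center: float = 0.5
    a_sd: float = 0.05
    b_center: float = 1.0
    b_sd: float = 0.1
    hrf_params: HRFParams = field(default_factory=HRFParams)

    def __post_init__(self) -> None:
        if len(self.toas_s) < 3:
            raise ValueError("need >= 3 TOA conditions for the decay fit")
        if self.n_trials < 1 or self.n_runs < 1:
            raise ValueError("n_trials and n_runs must be >= 1")
        if self.block_order not in ("fixed", "shuffled"):
            raise ValueError("block_order must be 'fixed' or 'shuffled'")

    @property
    def n_vols(self) -> int:
        """Run length in volumes (independent of block order)."""
        t = self.lead_in_s
        for toa in self.toas_s:
            span = (self.n_trials - 1) * toa + self.duration_s
            t += span + self.gap_s
        t = t - self.gap_s + self.tail_s
        return int(np.ceil(t / self.tr_s))


def build_run_schedules(design: CohortDesign, order=None) -> list:
    """Block schedules of one run, in the given TOA order."""
    toas = list(design.toas_s if order is None else order)
    schedules = []
    t = design.lead_in_s
    for toa in toas:
        sch = make_event_schedule(toa, design.n_trials, start_s=t, duration_s=design.duration_s)
        schedules.append(sch)
        t = sch.end_s + design.gap_s
    return schedules


@dataclass
class SubjectSpec:
    """Generating parameters and RNG streams of one synthetic subject."""

    subject_id: str
    group: str
    a: float
    b: float
    tau_s: float
    run_seeds: list
    run_orders: list  # list of TOA tuples, one per run


@dataclass
class Cohort:
    """A lazily simulated two-group cohort.

    Holds per-subject ground-truth parameters and seeded RNG streams;
    4-D runs are materialized on demand with ``simulate_subject`` so
    that large cohorts never need to reside in memory at once.
    """

    design: CohortDesign
    noise: NoiseSpec
    subjects: list
    seed: int

    def __post_init__(self) -> None:
        self._hrf = TwoGammaHRF(self.design.hrf_params)

    @property
    def hrf(self) -> TwoGammaHRF:
        return self._hrf

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def group_indices(self, group: str) -> list:
        return [i for i, s in enumerate(self.subjects) if s.group == group]

    @property
    def groups(self) -> list:
        seen = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def ground_truth(self, idx: int) -> GroundTruth:
        s = self.subjects[idx]
        shape = self.design.grid_shape
        return GroundTruth(
            a_map=np.full(shape, s.a),
            b_map=np.full(shape, s.b),
            tau_map=np.full(shape, s.tau_s),
            group_label=s.group,
        )

    def run_schedules(self, idx: int, run: int) -> list:
        return build_run_schedules(self.design, self.subjects[idx].run_orders[run])

    def simulate_subject(self, idx: int) -> list:
        """All runs of one subject as BOLDRun objects."""
        s = self.subjects[idx]
        gt = self.ground_truth(idx)
        runs = []
        for r in range(self.design.n_runs):
            runs.append(
                simulate_run(
                    gt,
                    self.run_schedules(idx, r),
                    tr_s=self.design.tr_s,
                    hrf=self._hrf,
                    noise=self.noise,
                    n_vols=self.design.n_vols,
                    voxel_size_mm=self.design.voxel_size_mm,
                    rng=np.random.default_rng(s.run_seeds[r]),
                )
            )
        return runs

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "a": s.a,
                    "b": s.b,
                    "tau_s": s.tau_s,
                }
                for s in self.subjects
            ]
        )

    def write(self, out_dir) -> None:
        """Write runs (NIfTI), events (TSV), truth (NIfTI+JSON), manifest."""
        from pathlib import Path
        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, s in enumerate(self.subjects):
            sdir = out / s.subject_id
            sdir.mkdir(exist_ok=True)
            gt = self.ground_truth(i)
            affine = np.diag([self.design.voxel_size_mm] * 3 + [1.0])
            for name, vol in (("a", gt.a_map), ("b", gt.b_map), ("tau", gt.tau_map)):
                nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(sdir / f"truth_{name}.nii"))
            (sdir / "truth.json").write_text(
                json.dumps({"a": s.a, "b": s.b, "tau_s": s.tau_s, "group": s.group})
            )
            events = []
            for r, run in enumerate(self.simulate_subject(i)):
                run_path = sdir / f"run-{r + 1}_bold.nii"
                run.save(run_path)
                for blk, sch in enumerate(self.run_schedules(i, r)):
                    for onset in sch.onsets_s:
                        events.append(
                            {
                                "onset": onset,
                                "duration": sch.duration_s,
                                "toa": sch.toa_s,
                                "block": blk,
                                "run": r + 1,
                            }
                        )
                rows.append({"subject_id": s.subject_id, "group": s.group, "path": str(run_path)})
            pd.DataFrame(events).to_csv(sdir / "events.tsv", sep="\t", index=False)
        pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)


def make_group_cohort(
    n_control: int = 19,
    n_dyslexic: int = 20,
    tau_control_s: float = 10.0,
    tau_dyslexic_s: float = 5.0,
    between_subject_sd: float = 0.2,
    noise: NoiseSpec | None = None,
    design: CohortDesign | None = None,
    seed: int = 0,
) -> Cohort:
    """Two-group synthetic cohort with group-specific adaptation tau.

    Subject-level tau is lognormal around the group center:
    tau_i = center * exp(N(0, between_subject_sd)), keeping tau > 0
    with the right skew typical of time constants; a and b are normal
    around the design's centers. Group sizes and the shorter dyslexic
    tau default to the study conditions (19 controls vs 20 dyslexics,
    10 s vs 5 s).
    """
    if n_control < 1 or n_dyslexic < 1:
        raise ValueError("group sizes must be >= 1")
    if tau_control_s <= 0 or tau_dyslexic_s <= 0:
        raise ValueError("tau centers must be positive")
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be >= 0")
    noise = noise if noise is not None else NoiseSpec()
    design = design or CohortDesign()
    root = np.random.SeedSequence(seed)
    subjects = []
    specs = [("control", tau_control_s)] * n_control + [
        ("dyslexic", tau_dyslexic_s)
    ] * n_dyslexic
    children = root.spawn(len(specs))
    for i, ((group, tau_center), child) in enumerate(zip(specs, children)):
        param_ss, *run_ss = child.spawn(design.n_runs + 1)
        rng = np.random.default_rng(param_ss)
        tau = tau_center * np.exp(rng.normal(0.0, between_subject_sd))
        a = rng.normal(design.a_center, design.a_sd)
        b = rng.normal(design.b_center, design.b_sd)
        orders = []
        for _ in range(design.n_runs):
            if design.block_order == "shuffled":
                orders.append(tuple(rng.permutation(design.toas_s)))
            else:
                orders.append(tuple(design.toas_s))
        subjects.append(
            SubjectSpec(
                subject_id=f"sub-{i + 1:03d}",
                group=group,
                a=float(a),
                b=float(b),
                tau_s=float(tau),
                run_seeds=run_ss,
                run_orders=orders,
            )
        )
    return Cohort(design=design, noise=noise, subjects=subjects, seed=seed)
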