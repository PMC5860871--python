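"""ROI averaging, decay fitting and group comparison."""

import numpy as np
import pytest

import boldadapt as ba
from boldadapt.pipeline import PipelineConfig, cohort_beta_maps

TOAS = np.array([3.0, 6.0, 9.0, 15.0])


def beta_map_from_grid(grid):
    shape = grid.shape
    return ba.BetaMap(
        betas=grid,
        toas_s=TOAS.copy(),
        resid_var=np.zeros(shape[:3]),
        df=10,
        rss_full=np.zeros(shape[:3]),
        rss_reduced=np.zeros(shape[:3]),
        n_task=4,
    )


class TestRoiMeanBetas:
    def test_single_voxel_roi_returns_that_voxel(self, rng):
        grid = rng.normal(size=(3, 3, 3, 4))
        roi = ba.box_roi((3, 3, 3), (1, 1, 1), (1, 1, 1), name="one")
        out = ba.roi_mean_betas(beta_map_from_grid(grid), roi)
        np.testing.assert_allclose(list(out.values()), grid[1, 1, 1])

    def test_two_voxel_mean(self):
        grid = np.zeros((2, 1, 1, 4))
        grid[0, 0, 0] = 1.0
        grid[1, 0, 0] = 3.0
        roi = ba.box_roi((2, 1, 1), (0, 0, 0), (2, 1, 1), name="pair")
        out = ba.roi_mean_betas(beta_map_from_grid(grid), roi)
        np.testing.assert_allclose(list(out.values()), 2.0)

    def test_missing_voxels_excluded(self):
        grid = np.ones((2, 1, 1, 4))
        grid[1, 0, 0] = np.nan
        roi = ba.box_roi((2, 1, 1), (0, 0, 0), (2, 1, 1))
        out = ba.roi_mean_betas(beta_map_from_grid(grid), roi)
        np.testing.assert_allclose(list(out.values()), 1.0)

    def test_fully_missing_roi_rejected(self):
        grid = np.full((2, 1, 1, 4), np.nan)
        roi = ba.box_roi((2, 1, 1), (0, 0, 0), (2, 1, 1))
        with pytest.raises(ValueError, match="no finite"):
            ba.roi_mean_betas(beta_map_from_grid(grid), roi)

    def test_off_grid_roi_rejected(self, rng):
        grid = rng.normal(size=(3, 3, 3, 4))
        roi = ba.box_roi((4, 4, 4), (0, 0, 0), (2, 2, 2))
        with pytest.raises(ValueError, match="grid"):
            ba.roi_mean_betas(beta_map_from_grid(grid), roi)


class TestRoiDecayFit:
    def test_homogeneous_roi_recovers_generating_tau(self):
        betas = 0.5 + 1.0 * np.exp(-TOAS / 7.0)
        grid = np.broadcast_to(betas, (3, 3, 3, 4)).copy()
        roi = ba.box_roi((3, 3, 3), (0, 0, 0), (3, 3, 3))
        fit = ba.roi_fit_decay(beta_map_from_grid(grid), roi)
        assert abs(fit.tau_s - 7.0) / 7.0 <= 1e-6

    def test_roi_average_then_fit_equals_voxel_fit_homogeneous(self):
        betas = 0.2 + 0.8 * np.exp(-TOAS / 5.0)
        grid = np.broadcast_to(betas, (2, 2, 2, 4)).copy()
        bm = beta_map_from_grid(grid)
        roi = ba.box_roi((2, 2, 2), (0, 0, 0), (2, 2, 2))
        roi_fit = ba.roi_fit_decay(bm, roi)
        vox_fit = ba.fit_decay(dict(zip(TOAS, grid[0, 0, 0])))
        assert roi_fit.tau_s == pytest.approx(vox_fit.tau_s, rel=1e-9)

    def test_beta_averaging_equals_timeseries_averaging(self, hrf, noiseless):
        """With one shared design, averaging betas over voxels equals
        averaging the time series first and re-fitting the GLM."""
        shape = (3, 1, 1)
        rng = np.random.default_rng(5)
        gt = ba.GroundTruth(
            a_map=rng.uniform(0.2, 0.8, shape),
            b_map=rng.uniform(0.5, 1.5, shape),
            tau_map=rng.uniform(3, 12, shape),
        )
        design = ba.CohortDesign(grid_shape=shape, n_trials=4, gap_s=10.0)
        sch = ba.build_run_schedules(design)
        run = ba.simulate_run(gt, sch, noise=noiseless, n_vols=design.n_vols)
        dm = ba.build_design_matrix(sch, 1.0, run.n_vols, hrf)
        bm = ba.fit_glm(run, dm)
        roi = ba.box_roi(shape, (0, 0, 0), shape)
        beta_avg = np.array(list(ba.roi_mean_betas(bm, roi).values()))
        mean_ts = run.data.reshape(-1, run.n_vols).mean(axis=0)
        bm_ts = ba.fit_glm(
            ba.BOLDRun(data=mean_ts.reshape(1, 1, 1, -1), tr_s=1.0), dm
        )
        np.testing.assert_allclose(beta_avg, bm_ts.betas[0, 0, 0], atol=1e-10)

    def test_roi_tau_variance_shrinks_with_roi_size(self, hrf):
        """Homogeneous ROI, fixed noise: larger ROIs give steadier tau."""
        rng = np.random.default_rng(0)
        sizes = [1, 8, 27, 99]
        spread = []
        for n_vox in sizes:
            taus = []
            for _ in range(40):
                betas = 0.5 + 1.0 * np.exp(-TOAS / 8.0)
                noisy = betas[None, :] + 0.3 * rng.standard_normal((n_vox, 4))
                fit = ba.fit_decay(dict(zip(TOAS, noisy.mean(axis=0))))
                taus.append(fit.tau_s if np.isfinite(fit.tau_s) else 60.0)
            spread.append(np.std(taus))
        assert spread[-1] < spread[0]
        assert np.argmin(spread) >= 2


class TestRoiGroupCompare:
    def _cohort_maps(self, tau_c, tau_d, seed, n=6):
        design = ba.CohortDesign(grid_shape=(3, 3, 3), n_trials=8, gap_s=10.0, tail_s=20.0)
        cfg = PipelineConfig(design=design, do_smooth=False)
        cohort = ba.make_group_cohort(
            n, n, tau_control_s=tau_c, tau_dyslexic_s=tau_d,
            between_subject_sd=0.1, noise=cfg.noise, design=design, seed=seed,
        )
        return cohort_beta_maps(cohort, cfg), [s.group for s in cohort.subjects]

    def test_group_difference_detected(self):
        maps, labels = self._cohort_maps(12.0, 4.0, seed=3, n=8)
        roi = ba.box_roi((3, 3, 3), (0, 0, 0), (3, 3, 3))
        res = ba.roi_group_compare(maps, roi, labels, groups=("control", "dyslexic"))
        assert res.p < 0.05
        assert res.z > 0  # controls have larger tau
        assert res.median_tau["control"] > res.median_tau["dyslexic"]

    def test_r_is_z_over_sqrt_n(self):
        maps, labels = self._cohort_maps(10.0, 5.0, seed=4)
        roi = ba.box_roi((3, 3, 3), (0, 0, 0), (3, 3, 3))
        res = ba.roi_group_compare(maps, roi, labels)
        assert res.r == pytest.approx(res.z / np.sqrt(res.n1 + res.n2))

    def test_table_has_all_subjects(self):
        maps, labels = self._cohort_maps(8.0, 8.0, seed=5)
        roi = ba.box_roi((3, 3, 3), (1, 1, 1), (2, 2, 2))
        res = ba.roi_group_compare(maps, roi, labels)
        assert len(res.table) == len(labels)
        assert set(res.table["group"]) == {"control", "dyslexic"}

    def test_invalid_fits_excluded_and_small_group_rejected(self):
        grid_flat = np.ones((2, 2, 2, 4))  # constant betas: non-identifiable
        flat_map = beta_map_from_grid(grid_flat)
        maps, labels = self._cohort_maps(10.0, 5.0, seed=6)
        roi = ba.box_roi((2, 2, 2), (0, 0, 0), (2, 2, 2))
        small = [beta_map_from_grid(m.betas[:2, :2, :2]) for m in maps]
        res = ba.roi_group_compare(small, roi, labels)
        assert res.n1 + res.n2 <= len(labels)
        # all-but-one control invalid -> group below 2 -> rejected
        all_flat = [flat_map if lbl == "control" else beta_map_from_grid(m.betas[:2, :2, :2])
                    for m, lbl in zip(maps, labels)]
        with pytest.raises(ValueError, match="fewer than 2"):
            ba.roi_group_compare(all_flat, roi, labels)

    def test_wrong_label_count_rejected(self):
        maps, labels = self._cohort_maps(10.0, 5.0, seed=7)
        roi = ba.box_roi((3, 3, 3), (0, 0, 0), (2, 2, 2))
        with pytest.raises(ValueError):
            ba.roi_group_compare(maps, roi, labels[:-1])
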