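"""HRF, design construction, OLS fitting, FDR selection."""

import numpy as np
import pytest

import boldadapt as ba
from boldadapt.glm import average_beta_maps, pooled_task_f


class TestTwoGammaHRF:
    def test_zero_at_onset(self, hrf):
        assert hrf(0.0) == 0.0

    def test_peak_near_five_seconds(self):
        # dense-grid oracle: evaluate the unnormalized shape on a 1 ms grid
        hrf = ba.TwoGammaHRF()
        t = np.arange(0, 32, 0.001)
        assert t[np.argmax(hrf(t))] == pytest.approx(5.0, abs=0.01)
        assert hrf.peak_time_s == pytest.approx(5.0, abs=0.01)

    def test_max_normalized_to_one(self, hrf):
        assert np.max(hrf.sample(0.001)) == pytest.approx(1.0, abs=1e-9)

    def test_no_undershoot_is_nonnegative(self):
        hrf = ba.TwoGammaHRF(ba.HRFParams(undershoot_ratio=0.0))
        assert np.all(hrf.sample(0.01) >= 0)

    def test_zero_outside_support(self, hrf):
        assert hrf(-1.0) == 0.0
        assert hrf(100.0) == 0.0

    @pytest.mark.parametrize(
        "bad", [dict(peak_shape=0), dict(undershoot_rate=-1), dict(dt_s=0)]
    )
    def test_rejects_invalid_params(self, bad):
        with pytest.raises(ValueError):
            ba.HRFParams(**bad)


class TestDesignMatrix:
    def test_single_event_column_is_sampled_hrf(self, hrf):
        sch = ba.make_event_schedule(3, 1, start_s=0)
        dm = ba.build_design_matrix([sch], tr_s=1.0, n_vols=30, hrf=hrf)
        np.testing.assert_allclose(dm.task_matrix[:, 0], hrf(np.arange(30.0)))

    def test_two_events_superpose(self, hrf):
        # explicit-summation oracle
        sch = ba.make_event_schedule(3, 2, start_s=0)
        dm = ba.build_design_matrix([sch], tr_s=1.0, n_vols=40, hrf=hrf)
        t = np.arange(40.0)
        expected = hrf(t) + hrf(t - 3.0)
        np.testing.assert_allclose(dm.task_matrix[:, 0], expected, atol=1e-12)

    def test_same_toa_blocks_share_column(self, hrf):
        a = ba.make_event_schedule(3, 2, start_s=0)
        b = ba.make_event_schedule(3, 2, start_s=50)
        dm = ba.build_design_matrix([a, b], 1.0, 100, hrf)
        assert dm.n_task == 1
        assert dm.labels == ["toa_3", "constant"]

    def test_onset_beyond_run_rejected(self, hrf):
        sch = ba.make_event_schedule(10, 3, start_s=0)
        with pytest.raises(ValueError, match="20"):
            ba.build_design_matrix([sch], 1.0, 15, hrf)

    def test_boxcar_duration_regressor_close_to_impulse_for_short_events(self, hrf):
        imp = ba.make_event_schedule(5, 2, start_s=2, duration_s=0.0)
        box = ba.make_event_schedule(5, 2, start_s=2, duration_s=0.1)
        t = np.arange(40.0)
        ri = ba.event_regressor(imp, hrf, t)
        rb = ba.event_regressor(box, hrf, t)
        assert np.max(np.abs(ri - rb)) < 0.05


class TestFitGLM:
    def _design(self, hrf, n_vols=60):
        schedules = [
            ba.make_event_schedule(3, 3, start_s=2),
            ba.make_event_schedule(6, 3, start_s=30),
        ]
        return ba.build_design_matrix(schedules, 1.0, n_vols, hrf)

    def test_noiseless_recovery(self, hrf):
        dm = self._design(hrf)
        true_beta = np.array([1.5, 0.7, 0.2])  # two TOAs + constant
        y = (dm.matrix @ true_beta).reshape(1, 1, 1, -1)
        run = ba.BOLDRun(data=y, tr_s=1.0)
        bm = ba.fit_glm(run, dm)
        np.testing.assert_allclose(bm.betas[0, 0, 0], true_beta[:2], rtol=1e-10)
        assert bm.resid_var[0, 0, 0] == pytest.approx(0.0, abs=1e-16)

    def test_orthonormal_design_betas_are_inner_products(self):
        # hand-checkable 4-timepoint toy with orthonormal columns
        x = np.array([[1, 0], [0, 1], [0, 0], [0, 0]], dtype=float)
        dm = ba.DesignMatrix(matrix=x, toas_s=np.array([3.0, 6.0]), labels=["toa_3", "toa_6"], tr_s=1.0)
        y = np.array([2.0, -1.0, 5.0, 0.0]).reshape(1, 1, 1, 4)
        bm = ba.fit_glm(ba.BOLDRun(data=y, tr_s=1.0), dm)
        np.testing.assert_allclose(bm.betas[0, 0, 0], [2.0, -1.0])

    def test_pure_noise_betas_shrink_with_run_length(self, hrf, rng):
        mags = []
        for n_vols in (60, 480):
            vals = []
            for _ in range(60):
                dm = self._design(hrf, n_vols)
                run = ba.BOLDRun(data=rng.standard_normal((1, 1, 1, n_vols)), tr_s=1.0)
                vals.append(np.abs(ba.fit_glm(run, dm).betas).mean())
            mags.append(np.mean(vals))
        assert mags[1] < mags[0]
        assert mags[1] < 0.5  # centered near zero

    def test_residuals_orthogonal_to_design(self, hrf, rng):
        dm = self._design(hrf)
        run = ba.BOLDRun(data=rng.standard_normal((2, 2, 2, 60)), tr_s=1.0)
        bm = ba.fit_glm(run, dm)
        y = run.data.reshape(-1, 60).T
        coef, *_ = np.linalg.lstsq(dm.matrix, y, rcond=None)
        resid = y - dm.matrix @ coef
        assert np.max(np.abs(dm.matrix.T @ resid)) < 1e-8

    def test_scaling_kernel_inversely_scales_betas(self, hrf):
        """Kernel amplitude trades off against beta: max-normalization matters."""
        dm = self._design(hrf)
        y = (dm.matrix @ np.array([1.0, 2.0, 0.5])).reshape(1, 1, 1, -1)
        run = ba.BOLDRun(data=y, tr_s=1.0)
        scaled = ba.DesignMatrix(
            matrix=np.column_stack([dm.task_matrix * 4.0, dm.confound_matrix]),
            toas_s=dm.toas_s, labels=dm.labels, tr_s=dm.tr_s,
        )
        b1 = ba.fit_glm(run, dm).betas[0, 0, 0]
        b4 = ba.fit_glm(run, scaled).betas[0, 0, 0]
        np.testing.assert_allclose(b4, b1 / 4.0, rtol=1e-9)

    def test_rank_deficient_design_names_columns(self, hrf):
        col = ba.event_regressor(ba.make_event_schedule(3, 2), hrf, np.arange(30.0))
        dm = ba.DesignMatrix(
            matrix=np.column_stack([col, col]),
            toas_s=np.array([3.0, 6.0]),
            labels=["toa_3", "toa_6"],
            tr_s=1.0,
        )
        run = ba.BOLDRun(data=np.zeros((1, 1, 1, 30)), tr_s=1.0)
        with pytest.raises(ValueError, match="toa_6"):
            ba.fit_glm(run, dm)

    def test_length_mismatch_rejected(self, hrf):
        dm = self._design(hrf, 60)
        run = ba.BOLDRun(data=np.zeros((1, 1, 1, 61)), tr_s=1.0)
        with pytest.raises(ValueError, match="61"):
            ba.fit_glm(run, dm)


class TestBHFDR:
    def test_stepup_worked_example(self):
        # by hand: p_(4)=0.041 <= 4*0.05/4, so all four rejected
        p = np.array([0.001, 0.008, 0.039, 0.041])
        assert ba.bh_fdr(p, 0.05).all()

    def test_all_ones_rejects_nothing(self):
        assert not ba.bh_fdr(np.ones(10), 0.05).any()

    def test_single_pvalue_reduces_to_threshold(self):
        assert ba.bh_fdr(np.array([0.04]), 0.05).all()
        assert not ba.bh_fdr(np.array([0.06]), 0.05).any()

    def test_matches_bruteforce_stepup_scan(self, rng):
        # oracle: scan all m candidate thresholds p_(i), pick the largest
        # i with p_(i) <= i q / m, reject everything at or below it
        for _ in range(200):
            m = rng.integers(1, 13)
            p = np.round(rng.uniform(size=m), 3)
            q = rng.uniform(0.01, 0.2)
            srt = np.sort(p)
            k = 0
            for i in range(1, m + 1):
                if srt[i - 1] <= i * q / m:
                    k = i
            expected = p <= (srt[k - 1] if k else -1)
            np.testing.assert_array_equal(ba.bh_fdr(p, q), expected)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)
        ours = ba.bh_fdr(p, 0.1)
        theirs = multipletests(p, alpha=0.1, method="fdr_bh")[0]
        np.testing.assert_array_equal(ours, theirs)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            ba.bh_fdr(np.array([1.2]), 0.05)
        with pytest.raises(ValueError):
            ba.bh_fdr(np.array([0.5]), 1.5)


class TestTaskResponsiveSelection:
    def _beta_maps(self, cohort, config):
        from boldadapt.pipeline import cohort_beta_maps

        return cohort_beta_maps(cohort, config)

    def test_strong_signal_selects_everything(self, raw_config, tiny_design, noiseless):
        cohort = ba.make_group_cohort(
            2, 2, noise=noiseless, design=tiny_design, seed=0
        )
        maps = self._beta_maps(cohort, raw_config)
        mask, _ = ba.select_task_responsive(maps, q=0.001)
        assert mask.all()

    def test_pure_noise_selects_almost_nothing(self, tiny_design, raw_config):
        n_sel = 0
        n_tot = 0
        for seed in range(25):
            design = tiny_design
            cohort = ba.make_group_cohort(
                2, 2, noise=ba.NoiseSpec(sigma=0.5, drift_amp=0.0),
                design=design, seed=seed,
            )
            # zero out the signal: a = b = 0 for every subject
            for s in cohort.subjects:
                s.a = 0.0
                s.b = 0.0
            maps = self._beta_maps(cohort, raw_config)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mask, _ = ba.select_task_responsive(maps, q=0.001)
            n_sel += mask.sum()
            n_tot += mask.size
        assert n_sel / n_tot <= 0.001 + 0.002  # empirical FDR at the null

    def test_mixed_cohort_selection_contains_driven_voxels(self, tiny_design, raw_config):
        cohort = ba.make_group_cohort(
            3, 3, noise=ba.NoiseSpec(sigma=0.05, drift_amp=0.0),
            design=tiny_design, seed=7,
        )
        maps = self._beta_maps(cohort, raw_config)
        # silence half the voxels by zeroing their betas post hoc
        driven = np.zeros(tiny_design.grid_shape, dtype=bool)
        driven[:2] = True
        for m in maps:
            m.betas[~driven] = 0.0
            m.rss_reduced[~driven] = m.rss_full[~driven]
        mask, _ = ba.select_task_responsive(maps, q=0.001)
        assert (mask & driven).sum() == driven.sum()
        assert (mask & ~driven).sum() <= 0.01 * (~driven).sum() + 1

    def test_pooled_f_df_accumulate(self, raw_config, tiny_design, noiseless):
        cohort = ba.make_group_cohort(2, 2, noise=noiseless, design=tiny_design, seed=0)
        maps = self._beta_maps(cohort, raw_config)
        _, _, df_num, df_den = pooled_task_f(maps)
        assert df_num == sum(m.n_task for m in maps)
        assert df_den == sum(m.df for m in maps)


def test_average_beta_maps_means_betas(raw_config, tiny_design, noiseless):
    cohort = ba.make_group_cohort(1, 1, noise=noiseless, design=tiny_design, seed=0)
    runs = cohort.simulate_subject(0)
    from boldadapt.pipeline import subject_beta_map

    schedules = [cohort.run_schedules(0, r) for r in range(tiny_design.n_runs)]
    bm = subject_beta_map(runs, schedules, raw_config, cohort.hrf)
    dm = ba.build_design_matrix(schedules[0], 1.0, runs[0].n_vols, cohort.hrf)
    singles = [ba.fit_glm(r, dm) for r in runs]
    np.testing.assert_allclose(
        bm.betas, np.mean([s.betas for s in singles], axis=0), atol=1e-12
    )
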