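"""Phantom geometry, ground-truth volumes and signal-model checks."""

import numpy as np
import pytest
from scipy import ndimage, special

import rflesion as rf
from rflesion.phantom import LESION, EDEMA, MYOCARDIUM, BLOOD

TES = (3.0, 25.0, 75.0, 184.0)


class TestLabelVolume:
    def test_edema_region_volume_matches_configured_baseline(self):
        # static region (growth 0) holds its 0.77 mL baseline at any time
        cfg = rf.PhantomConfig(
            snr=np.inf, edema=rf.EdemaSpec(volume0_mL=0.77, growth_rate=0.0))
        lab = rf.build_label_volume(cfg, 120.0)
        voxvol_mL = cfg.voxel_volume_mm3 / 1000.0
        assert abs(lab.true_volumes_mL["edema_region"] - 0.77) <= voxvol_mL
        assert abs(lab.class_volume_mL(LESION, EDEMA) - 0.77) <= voxvol_mL

    def test_baseline_region_equals_v0(self):
        cfg = rf.PhantomConfig(snr=np.inf)
        lab = rf.build_label_volume(cfg, 0.0)
        voxvol_mL = cfg.voxel_volume_mm3 / 1000.0
        assert abs(lab.class_volume_mL(LESION, EDEMA)
                   - cfg.edema.volume0_mL) <= voxvol_mL

    def test_linear_growth_within_one_voxel(self):
        cfg = rf.PhantomConfig(snr=np.inf)
        voxvol_mL = cfg.voxel_volume_mm3 / 1000.0
        for t in (0.0, 30.0, 90.0, 180.0):
            lab = rf.build_label_volume(cfg, t)
            expect = cfg.edema.volume0_mL * (1 + cfg.edema.growth_rate * t)
            assert abs(lab.class_volume_mL(LESION, EDEMA) - expect) <= voxvol_mL

    def test_volume_conservation_in_annulus(self):
        cfg = rf.PhantomConfig(snr=np.inf)
        annulus_expected = None
        for t in (0.0, 60.0, 180.0):
            lab = rf.build_label_volume(cfg, t)
            total = lab.class_volume_mL(MYOCARDIUM, LESION, EDEMA)
            if annulus_expected is None:
                annulus_expected = total
            assert total == pytest.approx(annulus_expected, abs=1e-12)

    def test_monotone_growth_constant_core(self):
        cfg = rf.PhantomConfig(snr=np.inf)
        prev = -1.0
        core = None
        for t in np.linspace(0, 200, 9):
            lab = rf.build_label_volume(cfg, float(t))
            v = lab.class_volume_mL(LESION, EDEMA)
            assert v >= prev
            prev = v
            if core is None:
                core = lab.class_volume_mL(LESION)
            assert lab.class_volume_mL(LESION) == pytest.approx(core)

    def test_region_connected_and_inside_annulus(self, noiseless_label):
        region = noiseless_label.edema_region_mask
        n_comp = ndimage.label(region, structure=np.ones((3, 3, 3)))[1]
        assert n_comp == 1
        assert not (region & noiseless_label.mask(BLOOD)).any()
        assert not (region & (noiseless_label.labels == 0)).any()
        # core and rim are disjoint by labelling
        assert not (noiseless_label.mask(LESION) & noiseless_label.mask(EDEMA)).any()

    def test_capacity_error(self):
        cfg = rf.PhantomConfig(snr=np.inf, edema=rf.EdemaSpec(volume0_mL=50.0))
        with pytest.raises(rf.CapacityError):
            rf.build_label_volume(cfg, 0.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rf.build_label_volume(rf.PhantomConfig(), -1.0)

    def test_annulus_volume_matches_analytic(self):
        cfg = rf.PhantomConfig(snr=np.inf)
        lab = rf.build_label_volume(cfg, 0.0)
        analytic = (np.pi * (cfg.r_epi_mm ** 2 - cfg.r_endo_mm ** 2)
                    * cfg.slice_thickness_mm * cfg.n_slices / 1000.0)
        raster = lab.class_volume_mL(MYOCARDIUM, LESION, EDEMA)
        assert raster == pytest.approx(analytic, rel=0.05)

    def test_annular_sector_rasterisation_matches_closed_form(self):
        # independent check of the grid conventions: rasterise a 60-degree
        # sector of the annulus directly and compare to the sector formula
        cfg = rf.PhantomConfig(snr=np.inf)
        nx, ny = cfg.matrix
        cx, cy = cfg.center
        x = (np.arange(nx) - cx) * cfg.spacing_mm[0]
        y = (np.arange(ny) - cy) * cfg.spacing_mm[1]
        X, Y = np.meshgrid(x, y, indexing="ij")
        R = np.hypot(X, Y)
        TH = np.arctan2(Y, X)
        sector = ((R >= cfg.r_endo_mm) & (R <= cfg.r_epi_mm)
                  & (TH >= 0.0) & (TH <= np.pi / 3))
        raster_mm3 = sector.sum() * np.prod(cfg.spacing_mm)
        analytic_mm3 = (np.pi / 6) * (cfg.r_epi_mm ** 2 - cfg.r_endo_mm ** 2)
        assert raster_mm3 == pytest.approx(analytic_mm3, rel=0.05)

    def test_lesion_width_solver_hits_target(self):
        cfg = rf.PhantomConfig(snr=np.inf)
        for target in (0.3, 0.48, 0.7):
            w = rf.lesion_width_for_volume(cfg, target)
            from dataclasses import replace
            scale = w / cfg.lesion.width_mm
            spec = replace(cfg.lesion, width_mm=w,
                           length_mm=cfg.lesion.length_mm * scale,
                           target_volume_mL=None)
            lab = rf.build_label_volume(replace(cfg, lesion=spec), 0.0)
            assert lab.class_volume_mL(LESION) == pytest.approx(target, rel=0.10)


class TestSignalModels:
    def test_t2prep_short_te_returns_pd(self, noiseless_label, noiseless_config):
        series = rf.simulate_t2prep_series(noiseless_label, noiseless_config,
                                           TEs=(1e-6, 3.0, 25.0))
        pd_healthy = noiseless_config.tissues[MYOCARDIUM].pd
        healthy = noiseless_label.mask(MYOCARDIUM)
        assert np.allclose(series.frames[0][healthy], pd_healthy, rtol=1e-4)

    def test_t2prep_one_time_constant(self, noiseless_label, noiseless_config):
        series = rf.simulate_t2prep_series(noiseless_label, noiseless_config,
                                           TEs=(39.0, 78.0, 117.0))
        healthy = noiseless_label.mask(MYOCARDIUM)
        pd_healthy = noiseless_config.tissues[MYOCARDIUM].pd
        assert np.allclose(series.frames[0][healthy], pd_healthy / np.e)

    def test_rician_roi_mean_matches_analytic(self, noisy_config):
        # Monte-Carlo ROI mean per echo vs the exact Rician expectation
        lab = rf.build_label_volume(noisy_config, 10.0)
        series = rf.simulate_t2prep_series(lab, noisy_config, TEs=TES, seed=5)
        healthy = lab.mask(MYOCARDIUM)
        n = int(healthy.sum())
        assert n >= 500
        tissue = noisy_config.tissues[MYOCARDIUM]
        sigma = tissue.pd / noisy_config.snr

        def rician_mean(nu, sig):
            # E[M] = sig*sqrt(pi/2) * L_{1/2}(-nu^2/(2 sig^2)); the scaled
            # Bessel functions ive already carry the exp(x/2) factor
            x = -nu ** 2 / (2 * sig ** 2)
            l_half = ((1 - x) * special.ive(0, -x / 2)
                      - x * special.ive(1, -x / 2))
            return sig * np.sqrt(np.pi / 2) * l_half

        for i, te in enumerate(TES):
            nu = tissue.pd * np.exp(-te / tissue.t2)
            expect = rician_mean(nu, sigma)
            observed = series.frames[i][healthy]
            se = observed.std(ddof=1) / np.sqrt(n)
            assert abs(observed.mean() - expect) < 3 * se

    def test_ir_null_point_every_class(self, noiseless_label, noiseless_config):
        for cls in (BLOOD, MYOCARDIUM, LESION, EDEMA):
            t1 = noiseless_config.tissues[cls].t1
            series = rf.simulate_ir_series(noiseless_label, noiseless_config,
                                           TIs=(t1 * np.log(2), 2000.0, 4000.0))
            vals = series.frames[0][noiseless_label.mask(cls)]
            assert np.allclose(vals, 0.0, atol=1e-9)

    def test_ir_full_recovery_long_ti(self, noiseless_label, noiseless_config):
        series = rf.simulate_ir_series(noiseless_label, noiseless_config,
                                       TIs=(500.0, 1000.0, 50000.0))
        for cls in (MYOCARDIUM, LESION, EDEMA):
            pd_cls = noiseless_config.tissues[cls].pd
            vals = series.frames[-1][noiseless_label.mask(cls)]
            assert np.allclose(vals, pd_cls, rtol=1e-3)

    def test_ir_lesion_hyperenhanced_at_831ms(self, noiseless_label, noiseless_config):
        series = rf.simulate_ir_series(noiseless_label, noiseless_config,
                                       TIs=(300.0, 550.0, 831.0))
        frame = series.frames[-1]
        lesion_si = frame[noiseless_label.mask(LESION)].mean()
        healthy_si = frame[noiseless_label.mask(MYOCARDIUM)].mean()
        assert lesion_si / healthy_si > 1.0
        # direct evaluation of the magnitude inversion-recovery formula
        for cls, si in ((LESION, lesion_si), (MYOCARDIUM, healthy_si)):
            tis = noiseless_config.tissues[cls]
            expect = tis.pd * abs(1 - 2 * np.exp(-831.0 / tis.t1))
            assert si == pytest.approx(expect, rel=1e-6)

    def test_ir_requires_shorter_lesion_t1(self, noiseless_label, noiseless_config):
        from dataclasses import replace
        bad = dict(noiseless_config.tissues)
        bad[LESION] = rf.Tissue(t1=1200.0, t2=53.0, pd=100.0)
        cfg = replace(noiseless_config, tissues=bad)
        with pytest.raises(ValueError):
            rf.simulate_ir_series(noiseless_label, cfg)

    def test_scheduled_t2_applies_per_interval(self):
        cfg = rf.PhantomConfig(t2_schedule=tuple(rf.default_t2_schedule()))
        assert cfg.tissue_table_at(70.0)[LESION].t2 == 55.0
        assert cfg.tissue_table_at(70.0)[EDEMA].t2 == 58.0
        assert cfg.tissue_table_at(10.0)[EDEMA].t2 == 53.0
        assert cfg.tissue_table_at(120.0)[EDEMA].t2 == 56.0
        # outside any interval the base table applies
        assert cfg.tissue_table_at(40.0)[EDEMA].t2 == 58.0


class TestDeterminism:
    def test_identical_seed_identical_voxels(self, noisy_config):
        lab = rf.build_label_volume(noisy_config, 10.0)
        s1 = rf.simulate_t2prep_series(lab, noisy_config, seed=3)
        s2 = rf.simulate_t2prep_series(lab, noisy_config, seed=3)
        assert np.array_equal(s1.frames, s2.frames)
        s3 = rf.simulate_t2prep_series(lab, noisy_config, seed=4)
        assert not np.array_equal(s1.frames, s3.frames)

    def test_study_truth_tables_bit_identical(self):
        a = rf.generate_study(n_lesions=5, n_animals=4, seed=9).truth_table()
        b = rf.generate_study(n_lesions=5, n_animals=4, seed=9).truth_table()
        assert a.equals(b)


class TestStudyGeneration:
    def test_study_shape_and_truth_records(self):
        study = rf.generate_study(n_lesions=13, n_animals=11,
                                  times_min=(10, 45, 70, 120, 180), seed=1)
        assert len(study.lesions) == 13
        assert len({l.lesion_id for l in study.lesions}) == 13
        assert len({l.animal_id for l in study.lesions}) == 11
        tt = study.truth_table()
        assert len(tt) == 65

    def test_sample_moments_match_targets(self):
        study = rf.generate_study(n_lesions=13, n_animals=11,
                                  times_min=(10.0,), seed=3)
        v0 = np.array([l.config.edema.volume0_mL for l in study.lesions])
        cores = np.array([l.core_volume_mL for l in study.lesions])
        assert v0.mean() == pytest.approx(0.77, rel=0.02)
        assert cores.mean() == pytest.approx(0.48, rel=0.05)

    def test_fixed_ratio_study(self):
        study = rf.generate_study(n_lesions=6, n_animals=6, times_min=(10.0,),
                                  seed=4, edema_lesion_ratio=2.1)
        for les in study.lesions:
            assert les.config.edema.volume0_mL == pytest.approx(
                2.1 * les.core_volume_mL)

    def test_out_of_range_times_rejected(self):
        with pytest.raises(ValueError):
            rf.generate_study(n_lesions=3, n_animals=3, times_min=(10.0, 400.0),
                              seed=0)

    def test_invalid_animal_count_rejected(self):
        with pytest.raises(ValueError):
            rf.generate_study(n_lesions=3, n_animals=5, seed=0)

    def test_single_lesion_single_time_still_simulates(self):
        study = rf.generate_study(n_lesions=1, n_animals=1, times_min=(10.0,),
                                  seed=0)
        label, series = study.lesions[0].t2prep_series(10.0)
        assert series.frames.shape[0] == 4
        assert label.lesion_mask.any()


class TestImageSeriesContracts:
    def test_non_increasing_contrast_times_rejected(self, noiseless_label):
        with pytest.raises(ValueError):
            rf.ImageSeries(frames=np.zeros((2, 4, 4, 1)), times_ms=(5.0, 5.0),
                           contrast="t2prep", acq_time_min=0.0,
                           voxel_dims_mm=(1, 1, 1))

    def test_negative_magnitudes_rejected(self):
        with pytest.raises(ValueError):
            rf.ImageSeries(frames=-np.ones((2, 4, 4, 1)), times_ms=(5.0, 10.0),
                           contrast="t2prep", acq_time_min=0.0,
                           voxel_dims_mm=(1, 1, 1))
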