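# rflesion

Quantitative analysis of acute radiofrequency (RF) ablation lesions in
native-contrast cardiac MR, built around a digital left-ventricular phantom.

RF ablation of ventricular tachycardia creates two distinct injury zones that
native (non-contrast) CMR can separate: a **T1-derived lesion core** —
thermally coagulated tissue that hyper-enhances on long-TI inversion-recovery
(IR-SSFP-style) images because its T1 is shortened — and a surrounding
**T2-derived edematous region** of elevated T2 reflecting transient
interstitial fluid. The core is stable over the first hours; the edema grows.
Telling the two apart intra-procedurally matters because edema can mimic a
successful ablation and later resorb, leading to arrhythmia recurrence.

`rflesion` is aimed at researchers developing or validating such lesion
assessment pipelines. Because no public in-vivo datasets exist for this
setting, the package ships a first-class synthetic-data generator and
reproduces the whole analysis chain end to end:

1. **Phantom** (`rflesion.phantom`) — short-axis LV slices (annular
   myocardium, blood pool) with a teardrop (half-ellipsoid) lesion core
   seated on the endocardium and a growing edema rim,
   V(t) = V0·(1 + g·t); T2-prepared (S = PD·e^(−TE/T2)) and
   inversion-recovery magnitude (S = PD·|1 − 2e^(−TI/T1)|) series with
   Rician noise; multi-animal study generation.
2. **Relaxometry** (`rflesion.relaxometry`) — per-voxel 3-parameter
   T2 fit S(TE) = A·e^(−TE/T2) + C from 4 echoes (3–184 ms), with a
   vectorised solver for whole maps, validity flags, a dense grid-search
   oracle, and 256×256 interpolation.
3. **Segmentation** (`rflesion.segmentation`) — edema at
   *mean + 3 SD* of healthy T2, lesion at *mean + 2 SD* of healthy IR signal,
   per-slice connected components, cavity-aware hole filling and
   morphological cleanup; volumes, transmurality (depth / wall thickness),
   wall thickness, diameters.
4. **Longitudinal statistics** (`rflesion.longitudinal`) — baseline
   normalization, random-intercept linear mixed model
   y_it = β0 + β1·t + b_i + ε_it (REML, grouped by animal),
   edema/lesion volume ratios per time interval with Welch ANOVA and
   one-sided tests, ROI T2 time courses, Bland-Altman agreement and
   Pearson/Spearman correlation.
5. **Workflow** (`rflesion.workflow`, `rflesion.cli`) — a seeded,
   deterministic simulate → fit → segment → analyze pipeline with NIfTI +
   JSON sidecar IO, CSV tables and a consolidated JSON report.

## Worked example

```python
import numpy as np
import rflesion as rf

cfg = rf.PhantomConfig(snr=30.0, seed=7,
                       lesion=rf.LesionSpec(target_volume_mL=0.48))
label = rf.build_label_volume(cfg, 10.0)          # 10 min post-ablation
series = rf.simulate_t2prep_series(label, cfg)
t2map = rf.fit_t2_map(series, label.myocardium_region)
print(f"healthy T2: {t2map.roi_mean_t2(label.mask(rf.MYOCARDIUM)):.1f} ms")

seg = rf.segment_edema(t2map, label.myocardium_region,
                       rf.reference_sector_mask(label))
print(f"edema volume: {seg.volume_mL:.2f} mL "
      f"(true {label.true_volumes_mL['edema_region']:.2f} mL)")

ir = rf.simulate_ir_series(label, cfg)
seg_l = rf.segment_lesion(ir, label.myocardium_region,
                          rf.reference_sector_mask(label))
tm = rf.measure_transmurality(seg_l.mask, label.endo_disk, label.epi_disk,
                              cfg.spacing_mm)
print(f"lesion volume: {seg_l.volume_mL:.2f} mL, "
      f"transmurality {100*tm['max']:.0f}%")

fit = rf.fit_lmm(rf.simulate_lmm_study(np.random.default_rng(7)))
print(f"LMM slope {fit.slope:.4f}/min, "
      f"180-min prediction {rf.predict_fixed(fit, 180.0):.2f}")
```

prints

```
healthy T2: 39.2 ms
edema volume: 0.79 mL (true 0.79 mL)
lesion volume: 0.46 mL, transmurality 50%
LMM slope 0.0032/min, 180-min prediction 1.72
```

Read: the fitted healthy myocardial T2 recovers the configured 39 ms; the
3-SD threshold segmentation recovers the 0.79 mL edematous region; the 2-SD
IR segmentation recovers the 0.46 mL core reaching halfway through the wall;
and a simulated 13-lesion longitudinal study fitted with the mixed model
estimates ~0.003/min normalized edema growth, i.e. ~1.7× baseline volume by
180 min while lesion cores stay near 1.0×.

The same pipeline is available from the shell:

```bash
rflesion simulate --out run/ --seed 3
rflesion fit-t2 --series run/t2prep.nii.gz --out run/t2map.nii.gz
rflesion pipeline --out study/ --seed 1
```

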