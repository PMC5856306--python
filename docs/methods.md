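# Methods

## The phantom and what it emulates

The synthetic data generator produces short-axis left-ventricular geometry as
concentric circles per slice: a blood-pool disk (endocardial radius 25 mm), a
myocardial annulus (epicardial radius 33 mm, i.e. an 8 mm wall), and air
background. Default grids are 128×128 at 1.3×1.3 mm in-plane with three
6 mm slices, matching the effective resolution and slice thickness of the
T2-prepared and IR acquisitions the analysis is designed for.

**Injury model.** The lesion core is a half-ellipsoid seated on the
endocardial border with its axis along the local radial direction — the
characteristic teardrop cross-section of an RF lesion — parameterised by
angular position, surface width, through-plane length and depth as a
fraction of wall thickness (default 0.52). The edematous region (core plus
rim) evolves as V(t) = V0·(1 + g·t) with V0 = 0.77 mL and g = 0.003/min by
default; the rim is realised *geometrically* by adding the myocardial voxels
nearest to the core (3D Euclidean distance transform with physical sampling,
ties broken by voxel index) until the region's voxel count matches the
target, so the region volume is exact to one voxel at every time point and
segmentation accuracy can be judged independently of any intensity model.
Requests exceeding the annulus capacity raise `CapacityError` rather than
truncating silently.

**Tissue table.** Defaults (T1 ms / T2 ms / PD a.u.): blood 1600/250/110,
healthy myocardium 1100/39/100, lesion core 800/53/100, edema rim
1150/58/100. The healthy T2 (39 ms), lesion T2 (53 ms) and edema T2 (58 ms)
are the region statistics the thresholds are anchored to; the lesion T1 is
set below healthy T1 so the core hyper-enhances at long inversion times —
only this *ordering* is constrained by the measurements the phantom mirrors,
the absolute T1 values are plausible 1.5 T choices. An optional interval
schedule (lesion 53 → 55 → 53 ms, edema 53 → 58 → 56 ms over (0–25],
(60–80], (80–185] min) reproduces the measured ROI T2 time courses.

**Signal models.** T2-prep: S = PD·exp(−TE/T2) at 4 TEs {3, 25, 75, 184} ms.
Inversion recovery: S = PD·|1 − 2·exp(−TI/T1)| — the simplified IR magnitude
without the bSSFP steady-state readout, which preserves the two features the
analysis uses (the null point TI = T1·ln 2 and long-TI lesion contrast).
Noise is Rician — the magnitude of the complex signal after adding
independent Gaussian noise of standard deviation σ = PD(healthy)/SNR to both
channels — because all inputs are magnitude images and this gives the
correct noise floor at long TE. SNR defaults to 30; `np.inf` disables noise.

**Study generation.** Multi-animal studies assign the first
(n_lesions − n_animals) animals two lesions each. Per-lesion true core
volumes are drawn from N(0.48, 0.23²) mL and baseline edematous volumes from
N(0.77, 0.55²) mL, then the finite sample is standardised to those moments
exactly (floor 0.15 mL, with the mean restored on unfloored entries); this
makes a 13-lesion study reproduce the population statistics it is configured
to rather than fluctuating by the ±15% a free 13-draw sample would. Each
target volume is resolved once to a concrete rasterised geometry (bisection
on the teardrop width; voxel counts are a step function of width, so the
closest achievable count is used and recorded as the ground truth).
Per-animal baseline offsets b_i ~ N(0, 0.1²) shift whole volume curves on
the normalized scale. Everything derives from one master seed.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: cardiac and respiratory motion, spiral k-space
artifacts, bSSFP banding, catheter artifacts, partial-volume mixing at
tissue borders (labels are crisp), spatial T2 heterogeneity within a tissue
class (in vivo edema shows ±13–15 ms spread; the phantom's spread is noise
only), wall swelling after ablation (documented in vivo, off here), and
gadolinium kinetics.

## T2 reconstruction

The model is the standard 3-parameter magnitude decay
S(TE) = A·exp(−TE/T2) + C with bounds A > 0, T2 ∈ [1, 500] ms and an
unconstrained offset. `fit_t2_voxel` is a trust-region bounded least-squares
fit (scipy TRF, parameter tolerance 1e-10, ≤200 evaluations) initialised
from a log-linear fit of signal − min(signal). Voxels whose samples are
non-decreasing, or whose relative residual exceeds 0.5, carry an explicit
invalid flag — never a silent default.

`fit_t2_map` applies the same model over all masked voxels with a vectorised
projected Levenberg-Marquardt solver (batched 3×3 normal equations), chosen
so that study-scale map reconstruction takes milliseconds rather than
minutes; a standing test verifies it against the per-voxel scipy route.

**Noise-floor handling.** Plain magnitude-domain fitting is biased low by
5–7% at SNR 30 with this 4-echo scheme (the offset couples to the Rician
floor and the long-TE samples). The map-level default therefore fits squared
magnitudes, M² = A²·exp(−2·TE/T2) + B with B ≥ 0: E[M²] = ν² + 2σ² holds
exactly for Rician data, and measured ROI-mean bias is below 0.5% for
T2 ∈ [30, 70] ms at SNR ≥ 20. The reported offset is √(B/2), the implied
noise σ. Magnitude-domain fitting remains available (`mode="magnitude"`)
and the two agree to better than 0.05 ms on noiseless data.

An independent brute-force oracle (`grid_search_t2`) scans T2 on a 0.1 ms
grid solving A and C linearly per grid point; the iterative fit agrees with
it within 1 ms on ≥95/100 random noisy decays, as a standing test.

Images can be resampled to a 256×256 matrix (bilinear for images, nearest
for masks) with the in-plane spacing rescaled so physical extent and
volumes are preserved; the default workflow operates on the acquired grid,
where threshold volumes measured unbiased, and exposes interpolation as an
option.

## Segmentation

Edema is segmented on the T2 map at *mean + 3 SD* of a healthy reference
ROI; the lesion core on the first IR frame with TI ≥ 700 ms at *mean + 2 SD*
of healthy signal intensity. The reference ROI replaces operator placement
with a 60°-wide annulus sector diametrically opposite the configured lesion
angle; its mean and sample SD use valid-fit voxels only and require ≥30
voxels.

Cleanup runs per 2D slice: 8-connected components, removal of components
under 5 voxels, retention of components intersecting the myocardium, hole
filling, and an optional binary opening. Two choices differ from the most
obvious recipe and are deliberate:

* **Cavity-aware filling.** The lesion cavity enclosed by a supra-threshold
  edema rim is not a topological hole — its endocardial side borders the
  blood pool. Filling operates on mask ∪ interior-cavity (the region
  enclosed by the annulus that is not annulus) and clips back to the
  myocardium, which closes exactly these cavities while preserving borders.
* **Opening off by default (radius config-exposed).** At the configured
  volumes (core 0.48 mL ≈ 45 voxels, rim 1–2 voxels thin) erosion by even a
  radius-1 disk removes 30–60% of true volume; the minimum-component-size
  rule already removes isolated noise. When enabled, the opening runs after
  filling so it cannot sever the thin rim before the fill.

For noisy maps the workflow denoises the T2 map before thresholding with a
masked in-plane Gaussian (normalised convolution restricted to the
myocardium and valid voxels, σ = 0.6 voxels). Rationale: the homogeneous
phantom puts the rim (58 ms) within one noise SD of the mean+3 SD threshold
(~54 ms at SNR 30), so unsmoothed thresholding detects only ~80% of the rim
and ring gaps defeat the fill; the masked smooth lowers the per-voxel SD and
the threshold *consistently* (both computed on the same smoothed map) and
restores segmented/true volume ratios of 0.94–1.05. Masking prevents the
250 ms blood-pool T2 from bleeding across the endocardium. Noiseless runs
keep the raw map and may inject an explicit reference SD (e.g. 5 ms) so the
printed thresholds remain meaningful when the measured SD degenerates to 0.

Volumes are voxel count × voxel volume, exactly, with no partial-volume
weighting. Transmurality is measured along the radial ray through the
mask's in-plane centroid: depth is the mask's extent beyond the endocardial
border and thickness the endo-to-epi distance on the same ray, both
localised sub-voxel via half-level crossings of bilinear profiles; reported
per slice and as the maximum. Diameter is the farthest in-plane pair of
mask voxel centres plus one voxel.

## Longitudinal statistics

Volumes are normalized per (lesion, contrast) to the earliest measurement
(ties broken by row order and logged; zero baselines are an error). The
temporal trend is a linear mixed model y_it = β0 + β1·t + b_i + ε_it with a
random per-animal intercept, REML estimation (statsmodels MixedLM; BFGS with
Powell/Nelder-Mead fallback). A random slope is not included: baseline
normalization already anchors per-lesion levels, and the per-animal
intercept captures the clustering. Grouping by a single animal is refused;
non-convergence raises with diagnostics. Exactly linear noise-free input
drives the residual variance to zero where REML is undefined; such input
short-circuits to the OLS solution with zero variance components (the fixed
effects are identical there). Population predictions are β0 + β1·t with
random effects at zero, e.g. 1.20 + 0.003·180 = 1.74 ≈ 1.7× baseline for
edema and 1.01 − 0.0006·180 = 0.90× for lesion cores.

Edema/lesion ratios are formed from nearest-in-time matched pairs inside the
non-contiguous intervals (0–25], (60–80], (80–185] min; the 25–60 min gap is
respected, not bridged. Per interval: mean, SD, 95% t-CI and a one-sided
one-sample t-test against 1; across intervals Welch's ANOVA (robust to the
visibly unequal interval variances). Intervals with fewer than two pairs are
excluded and reported. ROI T2 time courses summarise per-lesion ROI means
(healthy and lesion masks fixed over time; edema from the largest segmented
region so far, frozen to examine a consistent tissue region) per interval,
with paired t-tests between consecutive intervals and against healthy
tissue. Bland-Altman agreement is bias ± 1.96·SD of paired differences;
correlation is Pearson (with regression line) or Spearman, flagging
zero-variance input as undefined.

The analysis stage excludes series whose baseline segmented volume is below
0.15 mL (config-exposed): such lesions sit in the partial-volume regime
where the baseline is dominated by segmentation noise and a normalized time
course is meaningless — the in-vivo counterpart is a lesion recorded as not
clearly apparent and left out of that contrast's analysis.

## Determinism and problem sizes

Every stochastic step is driven by numpy Generators seeded from explicit
integers; studies derive per-lesion, per-time, per-contrast seeds from a
master seed via SeedSequence, so a pipeline run is bit-reproducible (the
consolidated JSON report is byte-identical across runs at a fixed seed).
The test suite and the acceptance script use 3-slice 128×128 phantoms,
13-lesion (11-animal) single-time-point studies for volume recovery,
200 replicate table-level studies for slope recovery, and a 256×256
0.65 mm phantom for the transmurality measurement, where rasterisation of
the lesion boundary would otherwise dominate the radial measurement; these
sizes were chosen as the smallest at which the quantities of interest are
measured at the precision the checks require.

## Known limitations

* The phantom's crisp labels and homogeneous tissue classes make
  segmentation easier than in vivo; Dice scores here are upper bounds.
* The IR model omits the bSSFP readout, so absolute IR signal levels are
  not comparable to scanner data — only contrast orderings are.
* Edema growth is purely geometric; T2 elevation and extent are decoupled,
  whereas in vivo they co-evolve.
* Wall swelling (8 → 11 mm post-ablation) is not modelled; wall thickness
  is stationary unless configured otherwise.
* The squared-magnitude fit assumes spatially uniform noise; parallel
  imaging with spatially varying g-factor would violate this.
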