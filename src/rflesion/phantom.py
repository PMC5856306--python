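"""Digital short-axis left-ventricular phantom with an evolving ablation injury.

The phantom realises a three-class anatomy (blood pool, myocardial annulus,
background) plus a two-compartment ablation injury: a teardrop-shaped lesion
core attached to the endocardial border and a surrounding edema rim.  The
edematous region (lesion core plus rim) grows linearly in time; the lesion
core is constant.  Weighted image series are simulated with simplified signal
models — mono-exponential T2-prepared decay and inversion-recovery magnitude —
and Rician noise, providing ground truth for T2 mapping, segmentation and
longitudinal statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger("rflesion")

# Tissue class labels used throughout the package.
BACKGROUND, BLOOD, MYOCARDIUM, LESION, EDEMA = 0, 1, 2, 3, 4

__all__ = [
    "BACKGROUND", "BLOOD", "MYOCARDIUM", "LESION", "EDEMA",
    "Tissue", "LesionSpec", "EdemaSpec", "PhantomConfig", "LabelVolume",
    "ImageSeries", "CapacityError", "DEFAULT_TISSUES", "DEFAULT_TES",
    "DEFAULT_TIS", "default_t2_schedule", "build_label_volume",
    "simulate_t2prep_series", "simulate_ir_series", "lesion_width_for_volume",
    "Study", "StudyLesion", "generate_study", "reference_sector_mask",
]


class CapacityError(ValueError):
    """Requested injury volume exceeds the capacity of the myocardial annulus."""


@dataclass(frozen=True)
class Tissue:
    """Relaxometric description of one tissue class.

    T1 and T2 in ms, proton density (PD) in arbitrary units.
    """

    t1: float
    t2: float
    pd: float

    def __post_init__(self):
        if self.pd > 0 and (self.t1 <= 0 or self.t2 <= 0):
            raise ValueError("T1 and T2 must be positive for visible tissue")
        if self.pd < 0:
            raise ValueError("proton density must be non-negative")


# Healthy myocardial T2 of 39 ms matches the in-vivo reference statistic the
# segmentation thresholds are anchored to; lesion-core/edema T2 of 53/58 ms are
# the early-interval region values.  Lesion T1 is set below healthy T1 so the
# lesion hyper-enhances on long-TI inversion-recovery images; the remaining T1s
# are plausible 1.5 T values (unconstrained by the reference statistics).
DEFAULT_TISSUES: dict[int, Tissue] = {
    BACKGROUND: Tissue(t1=1.0, t2=1.0, pd=0.0),
    BLOOD: Tissue(t1=1600.0, t2=250.0, pd=110.0),
    MYOCARDIUM: Tissue(t1=1100.0, t2=39.0, pd=100.0),
    LESION: Tissue(t1=800.0, t2=53.0, pd=100.0),
    EDEMA: Tissue(t1=1150.0, t2=58.0, pd=100.0),
}

DEFAULT_TES = (3.0, 25.0, 75.0, 184.0)   # ms, 4-echo T2-prep acquisition
DEFAULT_TIS = (300.0, 550.0, 831.0)      # ms, long-TI image used for lesions


def default_t2_schedule() -> list[tuple[float, float, dict[int, float]]]:
    """Interval-wise T2 schedule for the injury classes.

    Emulates the measured ROI time courses: lesion core 53 -> 55 -> 53 ms and
    edema 53 -> 58 -> 56 ms over the intervals (0-25], (60-80], (80-185] min.
    Outside the listed intervals the base tissue table applies.
    """
    return [
        (0.0, 25.0, {LESION: 53.0, EDEMA: 53.0}),
        (60.0, 80.0, {LESION: 55.0, EDEMA: 58.0}),
        (80.0, 185.0, {LESION: 53.0, EDEMA: 56.0}),
    ]


@dataclass(frozen=True)
class LesionSpec:
    """Teardrop lesion geometry: a half-ellipsoid seated on the endocardium.

    angle_deg        angular position of the contact point on the endocardium
    width_mm         in-plane (tangential) full width at the endocardial surface
    length_mm        through-plane full length at the endocardial surface
    depth_frac       lesion depth as a fraction of local wall thickness (0, 1]
    target_volume_mL optional; when set, ``width_mm`` is rescaled at build time
                     so the rasterised core matches this volume within a voxel
    """

    angle_deg: float = 90.0
    width_mm: float = 11.0
    length_mm: float = 16.0
    depth_frac: float = 0.52
    target_volume_mL: float | None = None

    def __post_init__(self):
        if not (0.0 < self.depth_frac <= 1.0):
            raise ValueError("depth_frac must be in (0, 1]")
        if self.width_mm <= 0 or self.length_mm <= 0:
            raise ValueError("lesion width/length must be positive")


@dataclass(frozen=True)
class EdemaSpec:
    """Time evolution of the edematous region (lesion core + rim).

    volume0_mL   ground-truth edematous-region volume at ``t = start_min``
    growth_rate  fractional growth per minute g: V(t) = V0 * (1 + g * t)
    start_min    time offset before which the region stays at V0
    """

    volume0_mL: float = 0.77
    growth_rate: float = 0.003
    start_min: float = 0.0

    def __post_init__(self):
        if self.volume0_mL <= 0:
            raise ValueError("baseline edema volume must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    """Full parametric description of the phantom.

    Geometry is in mm with 0-based voxel indices; the slice axis is last.
    ``snr`` is the healthy-myocardium signal at TE=0 divided by the Gaussian
    noise standard deviation of each complex channel (``np.inf`` = noiseless).
    """

    matrix: tuple[int, int] = (128, 128)
    spacing_mm: tuple[float, float] = (1.3, 1.3)
    slice_thickness_mm: float = 6.0
    n_slices: int = 3
    center_vox: tuple[float, float] | None = None
    r_endo_mm: float = 25.0
    r_epi_mm: float = 33.0
    lesion: LesionSpec = field(default_factory=LesionSpec)
    edema: EdemaSpec = field(default_factory=EdemaSpec)
    tissues: dict[int, Tissue] = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    t2_schedule: tuple[tuple[float, float, dict[int, float]], ...] | None = None
    snr: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not (self.r_epi_mm > self.r_endo_mm > 0):
            raise ValueError("need epicardial radius > endocardial radius > 0")
        if self.snr <= 0:
            raise ValueError("SNR must be positive (np.inf for noiseless)")
        if self.n_slices < 1 or min(self.matrix) < 8:
            raise ValueError("degenerate grid")

    @property
    def voxel_dims_mm(self) -> tuple[float, float, float]:
        return (*self.spacing_mm, self.slice_thickness_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims_mm
        return dx * dy * dz

    @property
    def center(self) -> tuple[float, float]:
        if self.center_vox is not None:
            return self.center_vox
        return ((self.matrix[0] - 1) / 2.0, (self.matrix[1] - 1) / 2.0)

    def tissue_table_at(self, t_min: float) -> dict[int, Tissue]:
        """Tissue table with any scheduled T2 overrides applied at time ``t_min``."""
        table = dict(self.tissues)
        if self.t2_schedule:
            for lo, hi, overrides in self.t2_schedule:
                if lo < t_min <= hi:
                    for cls, t2 in overrides.items():
                        table[cls] = replace(table[cls], t2=t2)
        return table


@dataclass
class LabelVolume:
    """Voxel-wise tissue classes plus ground truth for one time point."""

    labels: np.ndarray                       # (nx, ny, nz) int8
    voxel_dims_mm: tuple[float, float, float]
    t_min: float
    true_volumes_mL: dict[str, float]
    center_vox: tuple[float, float]
    r_endo_mm: float
    r_epi_mm: float
    lesion_angle_deg: float

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims_mm
        return dx * dy * dz

    def mask(self, *classes: int) -> np.ndarray:
        return np.isin(self.labels, classes)

    @property
    def myocardium_region(self) -> np.ndarray:
        """Annulus analysis region: healthy myocardium plus any injury."""
        return self.mask(MYOCARDIUM, LESION, EDEMA)

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.mask(LESION)

    @property
    def edema_region_mask(self) -> np.ndarray:
        """Ground-truth edematous region = lesion core plus edema rim."""
        return self.mask(LESION, EDEMA)

    @property
    def endo_disk(self) -> np.ndarray:
        """Filled endocardial contour (blood-pool disk), per slice."""
        return _radial_disk(self.labels.shape, self.center_vox,
                            self.voxel_dims_mm, self.r_endo_mm)

    @property
    def epi_disk(self) -> np.ndarray:
        """Filled epicardial contour, per slice."""
        return _radial_disk(self.labels.shape, self.center_vox,
                            self.voxel_dims_mm, self.r_epi_mm)

    def class_volume_mL(self, *classes: int) -> float:
        return int(self.mask(*classes).sum()) * self.voxel_volume_mm3 / 1000.0


@dataclass
class ImageSeries:
    """Ordered stack of magnitude images sharing one contrast mechanism.

    ``contrast`` is ``"t2prep"`` (``times_ms`` are echo times TE) or ``"ir"``
    (``times_ms`` are inversion times TI).
    """

    frames: np.ndarray                        # (n_images, nx, ny, nz)
    times_ms: tuple[float, ...]
    contrast: str
    acq_time_min: float
    voxel_dims_mm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times_ms, dtype=float)
        if t.ndim != 1 or len(t) != self.frames.shape[0]:
            raise ValueError("one contrast time per frame required")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("contrast times must be positive and strictly increasing")
        if self.contrast not in ("t2prep", "ir"):
            raise ValueError("contrast must be 't2prep' or 'ir'")
        if np.any(self.frames < 0):
            raise ValueError("magnitude images must be non-negative")


# ---------------------------------------------------------------------------
# geometry helpers


def _coordinate_grids(config: PhantomConfig):
    nx, ny = config.matrix
    dx, dy = config.spacing_mm
    cx, cy = config.center
    x = (np.arange(nx) - cx) * dx
    y = (np.arange(ny) - cy) * dy
    X, Y = np.meshgrid(x, y, indexing="ij")
    return X, Y


def _slice_offsets_mm(config: PhantomConfig) -> np.ndarray:
    nz = config.n_slices
    return (np.arange(nz) - (nz - 1) / 2.0) * config.slice_thickness_mm


def _radial_disk(shape, center_vox, voxel_dims, radius_mm) -> np.ndarray:
    nx, ny, nz = shape
    dx, dy, _ = voxel_dims
    x = (np.arange(nx) - center_vox[0]) * dx
    y = (np.arange(ny) - center_vox[1]) * dy
    X, Y = np.meshgrid(x, y, indexing="ij")
    disk2d = np.hypot(X, Y) <= radius_mm
    return np.repeat(disk2d[:, :, None], nz, axis=2)


def _rasterize_lesion(config: PhantomConfig, width_mm: float) -> np.ndarray:
    """Half-ellipsoid core seated on the endocardial border, axis radial."""
    X, Y = _coordinate_grids(config)
    R = np.hypot(X, Y)
    annulus2d = (R >= config.r_endo_mm) & (R <= config.r_epi_mm)

    theta = np.deg2rad(config.lesion.angle_deg)
    u = np.array([np.cos(theta), np.sin(theta)])   # radial unit vector
    v = np.array([-np.sin(theta), np.cos(theta)])  # tangential unit vector
    depth = config.lesion.depth_frac * (config.r_epi_mm - config.r_endo_mm)
    a_t = width_mm / 2.0
    a_z = config.lesion.length_mm / 2.0

    xi_r = X * u[0] + Y * u[1] - config.r_endo_mm   # depth into the wall
    xi_t = X * v[0] + Y * v[1]

    nz = config.n_slices
    lesion = np.zeros((*config.matrix, nz), dtype=bool)
    for k, z in enumerate(_slice_offsets_mm(config)):
        if abs(z) >= a_z:
            continue
        q = (xi_r / depth) ** 2 + (xi_t / a_t) ** 2 + (z / a_z) ** 2
        lesion[:, :, k] = (q <= 1.0) & (xi_r >= 0.0) & annulus2d
    return lesion


def lesion_width_for_volume(config: PhantomConfig, target_mL: float,
                            tol_voxels: int = 1) -> float:
    """Surface width (mm) whose rasterised core volume matches ``target_mL``.

    Monotone bisection on the width; the through-plane length is scaled with
    the width to preserve the teardrop aspect.  Accepts the first width whose
    voxel count is within ``tol_voxels`` of the target count.
    """
    target_n = target_mL * 1000.0 / config.voxel_volume_mm3
    base = config.lesion

    def count(scale: float) -> int:
        cfg = replace(config, lesion=replace(
            base, width_mm=base.width_mm * scale,
            length_mm=base.length_mm * scale, target_volume_mL=None))
        return int(_rasterize_lesion(cfg, base.width_mm * scale).sum())

    lo, hi = 0.05, 8.0
    if count(hi) < target_n:
        raise CapacityError("target lesion volume exceeds annulus capacity")
    # Voxel counts are a step function of the scale (whole columns/slices
    # enter at once), so an exact hit may not exist; keep the closest-count
    # candidate seen during the bisection.
    best = (np.inf, 0.5 * (lo + hi))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        n = count(mid)
        err = abs(n - target_n)
        if n > 0 and err < best[0]:
            best = (err, mid)
        if err <= tol_voxels:
            return base.width_mm * mid
        if n < target_n:
            lo = mid
        else:
            hi = mid
    return base.width_mm * best[1]


# ---------------------------------------------------------------------------
# label volume construction


def build_label_volume(config: PhantomConfig, t_min: float) -> LabelVolume:
    """Rasterise anatomy and injury at ``t_min`` minutes post-ablation.

    The lesion core is constant in time.  The ground-truth edematous region
    (core + rim) has volume ``V0 * (1 + g * max(t - start, 0))``, realised by
    selecting the myocardial voxels nearest to the core (Euclidean distance
    with physical sampling) until the target voxel count is reached, which
    thickens the rim geometrically without touching intensities.

    Raises
    ------
    CapacityError
        If the requested edematous volume exceeds the annulus capacity.
    """
    if t_min < 0:
        raise ValueError("t_min must be non-negative")

    X, Y = _coordinate_grids(config)
    R = np.hypot(X, Y)
    nz = config.n_slices
    blood2d = R < config.r_endo_mm
    annulus2d = (R >= config.r_endo_mm) & (R <= config.r_epi_mm)

    labels = np.zeros((*config.matrix, nz), dtype=np.int8)
    labels[np.repeat(blood2d[:, :, None], nz, axis=2)] = BLOOD
    annulus = np.repeat(annulus2d[:, :, None], nz, axis=2)
    labels[annulus] = MYOCARDIUM

    width = config.lesion.width_mm
    if config.lesion.target_volume_mL is not None:
        width = lesion_width_for_volume(config, config.lesion.target_volume_mL)
    lesion = _rasterize_lesion(config, width)
    if not lesion.any():
        raise ValueError("lesion rasterised to zero voxels; check geometry")

    voxvol = config.voxel_volume_mm3
    dt = max(t_min - config.edema.start_min, 0.0)
    target_mL = config.edema.volume0_mL * (1.0 + config.edema.growth_rate * dt)
    target_n = int(round(target_mL * 1000.0 / voxvol))
    n_lesion = int(lesion.sum())
    n_annulus = int(annulus.sum())
    if target_n > n_annulus:
        raise CapacityError(
            f"edematous region of {target_mL:.2f} mL needs {target_n} voxels; "
            f"annulus holds only {n_annulus}")
    if target_n < n_lesion:
        raise ValueError(
            "edematous-region volume smaller than the lesion core; the region "
            "must contain the core")

    # Thicken the rim: myocardial voxels nearest to the core, ties broken by
    # flat index for determinism.
    dist = ndimage.distance_transform_edt(~lesion, sampling=config.voxel_dims_mm)
    candidates = np.flatnonzero(annulus & ~lesion)
    order = np.lexsort((candidates, dist.ravel()[candidates]))
    rim_idx = candidates[order[: target_n - n_lesion]]

    edema_region = lesion.copy()
    edema_region.ravel()[rim_idx] = True
    labels[edema_region] = EDEMA
    labels[lesion] = LESION

    true_volumes = {
        "lesion": n_lesion * voxvol / 1000.0,
        "edema_region": target_n * voxvol / 1000.0,
        "myocardium_annulus": n_annulus * voxvol / 1000.0,
    }
    return LabelVolume(
        labels=labels, voxel_dims_mm=config.voxel_dims_mm, t_min=t_min,
        true_volumes_mL=true_volumes, center_vox=config.center,
        r_endo_mm=config.r_endo_mm, r_epi_mm=config.r_epi_mm,
        lesion_angle_deg=config.lesion.angle_deg)


# ---------------------------------------------------------------------------
# signal simulation


def _lookup(table: dict[int, Tissue], labels: np.ndarray, attr: str) -> np.ndarray:
    lut = np.zeros(max(table) + 1)
    for cls, tissue in table.items():
        lut[cls] = getattr(tissue, attr)
    return lut[labels]


def _add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator):
    """Magnitude of the complex signal after additive Gaussian channel noise."""
    if sigma == 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def simulate_t2prep_series(label: LabelVolume, config: PhantomConfig,
                           TEs=DEFAULT_TES, seed: int | None = None) -> ImageSeries:
    """T2-prepared series: S(TE) = PD * exp(-TE / T2) per class, Rician noise.

    Noise sigma is healthy-myocardium PD divided by the configured SNR and is
    applied independently per echo image.  Deterministic for a fixed seed.
    """
    TEs = tuple(float(te) for te in TEs)
    if len(TEs) == 0 or min(TEs) <= 0:
        raise ValueError("TEs must be non-empty and positive")
    table = config.tissue_table_at(label.t_min)
    pd_map = _lookup(table, label.labels, "pd")
    t2_map = _lookup(table, label.labels, "t2")
    sigma = 0.0 if np.isinf(config.snr) else table[MYOCARDIUM].pd / config.snr
    rng = np.random.default_rng(config.seed if seed is None else seed)

    frames = np.empty((len(TEs), *label.labels.shape))
    for i, te in enumerate(TEs):
        with np.errstate(divide="ignore"):
            s = pd_map * np.exp(-te / np.maximum(t2_map, 1e-9))
        s[pd_map == 0] = 0.0
        frames[i] = _add_rician_noise(s, sigma, rng)
    return ImageSeries(frames=frames, times_ms=TEs, contrast="t2prep",
                       acq_time_min=label.t_min,
                       voxel_dims_mm=label.voxel_dims_mm,
                       meta={"snr": config.snr})


def simulate_ir_series(label: LabelVolume, config: PhantomConfig,
                       TIs=DEFAULT_TIS, seed: int | None = None) -> ImageSeries:
    """Inversion-recovery magnitude series: S(TI) = PD * |1 - 2 exp(-TI/T1)|.

    The balanced-SSFP steady-state readout is deliberately not modelled; the
    simplified magnitude expression reproduces the two features the analysis
    relies on — the per-class null point at TI = T1 ln 2 and hyper-enhancement
    of the short-T1 lesion core at long TI.
    """
    TIs = tuple(float(ti) for ti in TIs)
    if len(TIs) == 0 or min(TIs) <= 0:
        raise ValueError("TIs must be non-empty and positive")
    table = config.tissue_table_at(label.t_min)
    if table[LESION].t1 >= table[MYOCARDIUM].t1:
        raise ValueError("lesion T1 must be shorter than healthy T1 for "
                         "long-TI hyper-enhancement")
    pd_map = _lookup(table, label.labels, "pd")
    t1_map = _lookup(table, label.labels, "t1")
    sigma = 0.0 if np.isinf(config.snr) else table[MYOCARDIUM].pd / config.snr
    rng = np.random.default_rng(config.seed if seed is None else seed)

    frames = np.empty((len(TIs), *label.labels.shape))
    for i, ti in enumerate(TIs):
        s = pd_map * np.abs(1.0 - 2.0 * np.exp(-ti / np.maximum(t1_map, 1e-9)))
        s[pd_map == 0] = 0.0
        frames[i] = _add_rician_noise(s, sigma, rng)
    return ImageSeries(frames=frames, times_ms=TIs, contrast="ir",
                       acq_time_min=label.t_min,
                       voxel_dims_mm=label.voxel_dims_mm,
                       meta={"snr": config.snr})


def reference_sector_mask(label: LabelVolume, half_width_deg: float = 30.0) -> np.ndarray:
    """Healthy reference ROI: annulus sector diametrically opposite the lesion.

    Replaces the operator's manual placement of a remote healthy ROI; the
    sector is centred 180 degrees from the configured lesion angle and clipped
    to voxels that are healthy myocardium at this time point.
    """
    nx, ny, nz = label.labels.shape
    dx, dy, _ = label.voxel_dims_mm
    x = (np.arange(nx) - label.center_vox[0]) * dx
    y = (np.arange(ny) - label.center_vox[1]) * dy
    X, Y = np.meshgrid(x, y, indexing="ij")
    ang = np.rad2deg(np.arctan2(Y, X))
    target = (label.lesion_angle_deg + 180.0 + 180.0) % 360.0 - 180.0
    dang = np.abs((ang - target + 180.0) % 360.0 - 180.0)
    sector2d = dang <= half_width_deg
    sector = np.repeat(sector2d[:, :, None], nz, axis=2)
    return sector & label.mask(MYOCARDIUM)


# ---------------------------------------------------------------------------
# multi-lesion study generation


@dataclass
class StudyLesion:
    """One lesion of a simulated study with its acquisition schedule."""

    animal_id: str
    lesion_id: str
    config: PhantomConfig
    times_min: tuple[float, ...]
    animal_offset: float          # random baseline offset b_i on normalized scale
    seed_base: int = 0
    core_volume_mL: float | None = None   # rasterised lesion-core volume

    def true_edema_volume_mL(self, t_min: float) -> float:
        e = self.config.edema
        dt = max(t_min - e.start_min, 0.0)
        return e.volume0_mL * (1.0 + e.growth_rate * dt + self.animal_offset)

    def _config_at(self, t_min: float) -> PhantomConfig:
        # Fold the animal offset into an effective baseline volume so that the
        # rasterised truth matches true_edema_volume_mL at every time point.
        # The region must still contain the lesion core, so a strongly
        # negative offset is floored just above the rasterised core volume.
        e = self.config.edema
        v_eff = e.volume0_mL * (1.0 + self.animal_offset)
        core = self.core_volume_mL or self.config.lesion.target_volume_mL
        if core is not None:
            voxvol_mL = self.config.voxel_volume_mm3 / 1000.0
            v_eff = max(v_eff, 1.08 * core, core + 2.0 * voxvol_mL)
        g_eff = e.growth_rate / max(1.0 + self.animal_offset, 1e-6)
        return replace(self.config,
                       edema=replace(e, volume0_mL=v_eff, growth_rate=g_eff))

    def label_volume(self, t_min: float) -> LabelVolume:
        return build_label_volume(self._config_at(t_min), t_min)

    def _child_seed(self, t_min: float, stream: int) -> int:
        ss = np.random.SeedSequence(
            [self.seed_base, int(round(t_min * 1000)), stream])
        return int(ss.generate_state(1)[0] % (2**31))

    def t2prep_series(self, t_min: float, TEs=DEFAULT_TES) -> tuple[LabelVolume, ImageSeries]:
        label = self.label_volume(t_min)
        return label, simulate_t2prep_series(label, self.config, TEs,
                                             seed=self._child_seed(t_min, 0))

    def ir_series(self, t_min: float, TIs=DEFAULT_TIS) -> tuple[LabelVolume, ImageSeries]:
        label = self.label_volume(t_min)
        return label, simulate_ir_series(label, self.config, TIs,
                                         seed=self._child_seed(t_min, 1))


@dataclass
class Study:
    """Collection of simulated lesions with ground truth."""

    lesions: list[StudyLesion]
    master_seed: int

    def truth_table(self):
        import pandas as pd
        rows = []
        for les in self.lesions:
            for t in les.times_min:
                rows.append({
                    "animal_id": les.animal_id, "lesion_id": les.lesion_id,
                    "t_min": t,
                    "true_edema_mL": les.true_edema_volume_mL(t),
                    "true_lesion_mL": les.core_volume_mL,
                })
        return pd.DataFrame(rows)


def _match_moments(draws: np.ndarray, mean: float, sd: float,
                   floor: float) -> np.ndarray:
    """Standardise a finite sample to the target mean/SD with a floor clip.

    After clipping at ``floor`` the unclipped entries are shifted so the
    sample mean equals ``mean`` again (a few fixed-point iterations).
    """
    x = np.asarray(draws, dtype=float)
    if len(x) > 1 and x.std() > 0:
        x = mean + (x - x.mean()) * (sd / x.std())
    else:
        x = np.full_like(x, mean)
    return _restore_mean_with_floor(x, mean, np.full_like(x, floor))


def _restore_mean_with_floor(x: np.ndarray, mean: float,
                             floors: np.ndarray) -> np.ndarray:
    """Clip to per-element floors, then shift unclipped entries so the sample
    mean equals ``mean`` (fixed-point iteration; feasible when the floors'
    mean is below the target)."""
    x = np.asarray(x, dtype=float).copy()
    for _ in range(20):
        clipped = x <= floors
        x = np.maximum(x, floors)
        free = ~clipped
        if not free.any() or abs(x.mean() - mean) < 1e-12:
            break
        x[free] += (mean - x.mean()) * len(x) / free.sum()
    return np.maximum(x, floors)


def generate_study(base_config: PhantomConfig | None = None, *,
                   n_lesions: int = 13, n_animals: int = 11,
                   times_min=None, seed: int = 0,
                   lesion_volume_mean_mL: float = 0.48,
                   lesion_volume_sd_mL: float = 0.23,
                   edema_volume_mean_mL: float = 0.77,
                   edema_volume_sd_mL: float = 0.55,
                   edema_lesion_ratio: float | None = None,
                   animal_offset_sd: float = 0.1,
                   n_times_range: tuple[int, int] = (3, 7),
                   t_range_min: tuple[float, float] = (5.0, 250.0)) -> Study:
    """Simulate a multi-animal ablation study with per-lesion ground truth.

    Per-lesion true core and baseline edematous volumes are drawn from normal
    distributions and standardised so the finite sample reproduces the target
    mean and SD (floor 0.15 mL).  When ``edema_lesion_ratio`` is given, the
    edematous baseline volume is instead set to exactly ``ratio`` times the
    core volume for every lesion.  Per-animal baseline offsets b_i are drawn
    from N(0, animal_offset_sd^2) and shift each animal's whole volume curve
    on the normalized scale.  Fully reproducible from ``seed``.

    ``times_min`` may be a list of acquisition times applied to every lesion;
    by default each lesion gets a random number of times (uniform in
    ``n_times_range``) with a baseline in 5-20 min and the rest spread over
    ``t_range_min``.
    """
    if base_config is None:
        base_config = PhantomConfig()
    if n_lesions < 1 or n_animals < 1 or n_animals > n_lesions:
        raise ValueError("need 1 <= n_animals <= n_lesions")
    rng = np.random.default_rng(seed)

    # First (n_lesions - n_animals) animals carry two lesions.
    animal_of = []
    extra = n_lesions - n_animals
    for i in range(n_lesions):
        animal_of.append(i if i < n_animals else i - n_animals)
    assert extra >= 0

    lesion_v = _match_moments(
        rng.normal(lesion_volume_mean_mL, lesion_volume_sd_mL, n_lesions),
        lesion_volume_mean_mL, lesion_volume_sd_mL, floor=0.15)

    # Resolve each target volume to a concrete rasterised geometry once; the
    # achieved (voxelised) core volume is the ground truth used downstream.
    base_lesion = base_config.lesion
    voxvol_mL = base_config.voxel_volume_mm3 / 1000.0
    lesion_specs: list[LesionSpec] = []
    achieved_v = np.empty(n_lesions)
    for i in range(n_lesions):
        w = lesion_width_for_volume(base_config, float(lesion_v[i]))
        scale = w / base_lesion.width_mm
        spec = replace(base_lesion, width_mm=w,
                       length_mm=base_lesion.length_mm * scale,
                       target_volume_mL=None)
        n_core = int(_rasterize_lesion(
            replace(base_config, lesion=spec), w).sum())
        lesion_specs.append(spec)
        achieved_v[i] = n_core * voxvol_mL

    if edema_lesion_ratio is not None:
        edema_v = achieved_v * float(edema_lesion_ratio)
    else:
        edema_v = _match_moments(
            rng.normal(edema_volume_mean_mL, edema_volume_sd_mL, n_lesions),
            edema_volume_mean_mL, edema_volume_sd_mL, floor=0.15)
        # the edematous region must contain the core; floor per lesion, then
        # restore the target sample mean on the unfloored entries
        edema_v = _restore_mean_with_floor(
            edema_v, edema_volume_mean_mL,
            np.maximum(achieved_v * 1.15, 0.15))

    offsets = rng.normal(0.0, animal_offset_sd, n_animals)

    lesions: list[StudyLesion] = []
    seen = set()
    for i in range(n_lesions):
        lesion_id = f"L{i + 1:02d}"
        if lesion_id in seen:
            raise ValueError(f"duplicate lesion identifier {lesion_id}")
        seen.add(lesion_id)
        if times_min is not None:
            times = tuple(sorted(float(t) for t in times_min))
        else:
            n_t = int(rng.integers(n_times_range[0], n_times_range[1] + 1))
            t0 = rng.uniform(max(t_range_min[0], 5.0), 20.0)
            later = rng.uniform(t0 + 10.0, t_range_min[1], size=n_t - 1)
            times = tuple(sorted([t0, *later]))
        if not all(0.0 <= t <= 250.0 for t in times):
            raise ValueError("acquisition times must lie within 0-250 min")
        cfg = replace(
            base_config,
            lesion=lesion_specs[i],
            edema=replace(base_config.edema, volume0_mL=float(edema_v[i])),
            seed=int(rng.integers(0, 2**31)))
        lesions.append(StudyLesion(
            animal_id=f"A{animal_of[i] + 1:02d}", lesion_id=lesion_id,
            config=cfg, times_min=times,
            animal_offset=float(offsets[animal_of[i]]),
            seed_base=int(rng.integers(0, 2**31)),
            core_volume_mL=float(achieved_v[i])))
    logger.info("generated study: %d lesions in %d animals, seed=%d",
                n_lesions, n_animals, seed)
    return Study(lesions=lesions, master_seed=seed)
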