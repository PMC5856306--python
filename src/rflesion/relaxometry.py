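"""Per-voxel T2 reconstruction from multi-echo T2-prepared magnitude images.

The signal model is the standard 3-parameter magnitude decay

    S(TE) = A * exp(-TE / T2) + C,

where the constant offset C absorbs the magnitude-noise floor.  Two solvers
share the model, bounds and log-linear initialisation: a per-voxel bounded
trust-region fit (:func:`fit_t2_voxel`, via ``scipy.optimize.least_squares``)
and a vectorised Levenberg-Marquardt engine used for whole maps
(:func:`fit_t2_map`).  A dense grid-search oracle (:func:`grid_search_t2`) is
provided for independent verification and is never used by the map path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from skimage.transform import resize

from .phantom import ImageSeries

logger = logging.getLogger("rflesion")

T2_BOUNDS = (1.0, 500.0)          # ms, configured validity bounds
RESIDUAL_FLAG_THRESHOLD = 0.5     # relative residual above which a fit is invalid

__all__ = ["T2Map", "VoxelFit", "fit_t2_voxel", "fit_t2_map",
           "grid_search_t2", "interpolate_to_matrix", "T2_BOUNDS"]


@dataclass
class VoxelFit:
    amplitude: float
    t2_ms: float
    offset: float
    residual: float        # euclidean norm of model - data
    valid: bool


@dataclass
class T2Map:
    """Fitted T2 map with diagnostics.

    Invalid or unfitted voxels are flagged explicitly; their T2 values must
    not be interpreted.
    """

    t2_ms: np.ndarray
    amplitude: np.ndarray
    offset: np.ndarray
    residual: np.ndarray
    valid: np.ndarray      # bool: fitted and identifiable
    fitted: np.ndarray     # bool: inside the requested mask
    voxel_dims_mm: tuple[float, float, float]
    acq_time_min: float

    def roi_mean_t2(self, mask: np.ndarray) -> float:
        """Mean T2 over valid fitted voxels of ``mask`` (NaN when empty)."""
        sel = mask & self.valid
        return float(self.t2_ms[sel].mean()) if sel.any() else float("nan")


def _loglinear_init(signal: np.ndarray, tes: np.ndarray):
    """Initial (A, T2, C) from a log-linear fit of signal minus its minimum.

    Vectorised over leading axes; ``signal`` has shape (..., n_te).
    """
    s = np.asarray(signal, dtype=float)
    c0 = s.min(axis=-1)
    y = s - c0[..., None]
    eps = np.maximum(1e-6, 1e-3 * s.max(axis=-1))[..., None]
    w = (y > eps).astype(float)
    # guarantee at least two usable points so the slope is defined
    w[..., :2] = np.maximum(w[..., :2], 0.5)
    ylog = np.log(np.maximum(y, eps))
    wsum = w.sum(axis=-1)
    tbar = (w * tes).sum(axis=-1) / wsum
    ybar = (w * ylog).sum(axis=-1) / wsum
    cov = (w * (tes - tbar[..., None]) * (ylog - ybar[..., None])).sum(axis=-1)
    var = (w * (tes - tbar[..., None]) ** 2).sum(axis=-1)
    slope = cov / np.maximum(var, 1e-12)
    t2 = np.where(slope < -1e-12, -1.0 / np.minimum(slope, -1e-12), 50.0)
    t2 = np.clip(t2, *T2_BOUNDS)
    # S(TE_min) - C approximates A for short first echoes; robust against the
    # exponential of a noisy regression intercept.
    a0 = np.maximum(s.max(axis=-1) - c0, 1e-6)
    return a0, t2, np.maximum(c0, 0.0)


def _decay_identifiable(signal: np.ndarray) -> np.ndarray:
    """False where the sampled signal is non-decreasing (no decay to fit)."""
    s = np.asarray(signal, dtype=float)
    return np.any(np.diff(s, axis=-1) < 0, axis=-1) & (s[..., 0] > s[..., -1])


def fit_t2_voxel(signal, tes) -> VoxelFit:
    """Bounded 3-parameter fit of one voxel's multi-echo decay.

    Trust-region least squares with A > 0, T2 in [1, 500] ms and an
    unconstrained offset C (noise can push the best-fit floor slightly
    negative), initialised from a log-linear fit.  The validity flag is
    cleared when the decay is non-identifiable (non-decreasing samples) or
    the relative residual exceeds 0.5.

    Raises
    ------
    ValueError
        On mismatched lengths or fewer than 3 samples.
    """
    s = np.asarray(signal, dtype=float)
    t = np.asarray(tes, dtype=float)
    if s.shape != t.shape:
        raise ValueError("signal and TE arrays must have matching lengths")
    if s.size < 3:
        raise ValueError("at least 3 echo times are required for a 3-parameter fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("TEs must be strictly increasing")

    if not bool(_decay_identifiable(s)):
        return VoxelFit(0.0, T2_BOUNDS[0], float(s.mean()),
                        float(np.linalg.norm(s - s.mean())), False)

    a0, t20, c0 = _loglinear_init(s, t)

    def resid(p):
        return p[0] * np.exp(-t / p[1]) + p[2] - s

    sol = least_squares(
        resid, x0=[float(a0), float(t20), float(c0)],
        bounds=([1e-12, T2_BOUNDS[0], -np.inf], [np.inf, T2_BOUNDS[1], np.inf]),
        method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=200)
    a, t2, c = sol.x
    rnorm = float(np.linalg.norm(sol.fun))
    rel = rnorm / max(float(np.linalg.norm(s)), 1e-12)
    valid = rel <= RESIDUAL_FLAG_THRESHOLD
    return VoxelFit(float(a), float(t2), float(c), rnorm, bool(valid))


def _batched_lm(signal: np.ndarray, tes: np.ndarray, n_iter: int = 60,
                offset_nonneg: bool = False):
    """Projected Levenberg-Marquardt over all voxels simultaneously.

    ``signal`` has shape (n_vox, n_te).  Returns (A, T2, C, residual_norm).
    Parameters are projected onto the bounds after every accepted step; the
    3x3 normal equations are solved batched.  The offset is free by default
    (magnitude domain, matching :func:`fit_t2_voxel`); squared-domain fits
    constrain it non-negative because the noise power it absorbs cannot be
    negative.
    """
    s = signal
    n = s.shape[0]
    a, t2, c = _loglinear_init(s, tes)
    p = np.stack([a, t2, c], axis=1)

    def residuals(p):
        return p[:, 0:1] * np.exp(-tes / p[:, 1:2]) + p[:, 2:3] - s

    r = residuals(p)
    cost = (r ** 2).sum(axis=1)
    lam = np.full(n, 1e-2)
    eye = np.eye(3)

    for _ in range(n_iter):
        e = np.exp(-tes / p[:, 1:2])                       # (n, m)
        j_a = e
        j_t2 = p[:, 0:1] * tes * e / p[:, 1:2] ** 2
        j_c = np.ones_like(e)
        J = np.stack([j_a, j_t2, j_c], axis=2)             # (n, m, 3)
        JtJ = np.einsum("nmi,nmj->nij", J, J)
        Jtr = np.einsum("nmi,nm->ni", J, r)
        diag = np.maximum(np.einsum("nii->ni", JtJ), 1e-12)
        Aug = JtJ + lam[:, None, None] * (eye[None, :, :] * diag[:, None, :])
        try:
            step = np.linalg.solve(Aug, -Jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.zeros_like(p)
        p_new = p + step
        p_new[:, 0] = np.maximum(p_new[:, 0], 1e-12)
        p_new[:, 1] = np.clip(p_new[:, 1], *T2_BOUNDS)
        if offset_nonneg:
            p_new[:, 2] = np.maximum(p_new[:, 2], 0.0)
        r_new = residuals(p_new)
        cost_new = (r_new ** 2).sum(axis=1)
        accept = cost_new <= cost
        p[accept] = p_new[accept]
        r[accept] = r_new[accept]
        cost[accept] = cost_new[accept]
        lam = np.where(accept, lam * 0.3, lam * 4.0)
        lam = np.clip(lam, 1e-10, 1e8)
    return p[:, 0], p[:, 1], p[:, 2], np.sqrt(cost)


def fit_t2_map(series: ImageSeries, mask: np.ndarray | None = None,
               engine: str = "batched", mode: str = "power") -> T2Map:
    """Fit the 3-parameter decay over the masked voxels of a T2-prep series.

    Out-of-mask voxels are flagged not-fitted.

    ``mode="power"`` (default) fits squared magnitudes,

        M(TE)^2 = A^2 exp(-2 TE / T2) + B,   B >= 0,

    where B absorbs the full Rician noise power (E[M^2] = nu^2 + 2 sigma^2 is
    exact for Rician magnitudes), which removes the T2 bias that plain
    magnitude fitting exhibits at moderate SNR.  The reported amplitude is
    sqrt(A^2); the reported offset is sqrt(B/2), i.e. the implied noise-floor
    sigma.  ``mode="magnitude"`` fits ``A exp(-TE/T2) + C`` directly, exactly
    as :func:`fit_t2_voxel`.

    ``engine="batched"`` uses the vectorised Levenberg-Marquardt solver
    (default); ``engine="voxel"`` loops :func:`fit_t2_voxel` (magnitude mode
    only).

    Raises
    ------
    ValueError
        If the series carries inversion-recovery metadata, which would make a
        T2 interpretation meaningless.
    """
    if series.contrast != "t2prep":
        raise ValueError("fit_t2_map requires a T2-prepared series "
                         f"(got contrast={series.contrast!r})")
    if series.frames.shape[0] < 3:
        raise ValueError("at least 3 echoes required")
    if mode not in ("power", "magnitude"):
        raise ValueError(f"unknown mode {mode!r}")
    shape = series.frames.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match image grid")

    tes = np.asarray(series.times_ms, dtype=float)
    t2 = np.zeros(shape)
    amp = np.zeros(shape)
    off = np.zeros(shape)
    res = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)

    idx = np.flatnonzero(mask)
    if idx.size:
        sig = series.frames.reshape(len(tes), -1)[:, idx].T    # (n_vox, n_te)
        identifiable = _decay_identifiable(sig)
        if mode == "power":
            if engine == "voxel":
                raise ValueError("voxel engine implements magnitude mode only")
            a2, t2v, b, rn2 = _batched_lm(sig ** 2, 2.0 * tes, offset_nonneg=True)
            a = np.sqrt(np.maximum(a2, 0.0))
            c = np.sqrt(np.maximum(b, 0.0) / 2.0)
            rel = rn2 / np.maximum(np.linalg.norm(sig ** 2, axis=1), 1e-12)
            rn = rn2
        elif engine == "batched":
            a, t2v, c, rn = _batched_lm(sig, tes)
            rel = rn / np.maximum(np.linalg.norm(sig, axis=1), 1e-12)
        elif engine == "voxel":
            a = np.empty(idx.size); t2v = np.empty(idx.size)
            c = np.empty(idx.size); rn = np.empty(idx.size)
            for k in range(idx.size):
                f = fit_t2_voxel(sig[k], tes)
                a[k], t2v[k], c[k], rn[k] = f.amplitude, f.t2_ms, f.offset, f.residual
            rel = rn / np.maximum(np.linalg.norm(sig, axis=1), 1e-12)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        ok = identifiable & (rel <= RESIDUAL_FLAG_THRESHOLD)
        t2.ravel()[idx] = t2v
        amp.ravel()[idx] = a
        off.ravel()[idx] = c
        res.ravel()[idx] = rn
        valid.ravel()[idx] = ok

    logger.debug("fitted %d voxels (%s engine), %d valid",
                 idx.size, engine, int(valid.sum()))
    return T2Map(t2_ms=t2, amplitude=amp, offset=off, residual=res,
                 valid=valid, fitted=mask.copy(),
                 voxel_dims_mm=series.voxel_dims_mm,
                 acq_time_min=series.acq_time_min)


def grid_search_t2(signal, tes, t2_grid=None):
    """Brute-force oracle: dense T2 grid with linear solves for A and C.

    For every grid T2 the amplitude and offset are obtained by unconstrained
    linear least squares; the grid point with the smallest residual wins.
    Default grid: 1 to 500 ms in steps of 0.1 ms.  Independent of the
    iterative solvers by construction.
    """
    s = np.asarray(signal, dtype=float)
    t = np.asarray(tes, dtype=float)
    if t2_grid is None:
        t2_grid = np.arange(T2_BOUNDS[0], T2_BOUNDS[1] + 1e-9, 0.1)
    t2_grid = np.asarray(t2_grid, dtype=float)

    # closed-form 2-parameter least squares per grid point, vectorised:
    # basis e = exp(-t/T2), model s ~ a*e + c
    e = np.exp(-t[None, :] / t2_grid[:, None])           # (G, m)
    m = float(len(t))
    se = (e * s[None, :]).sum(axis=1)
    s1 = s.sum()
    ee = (e * e).sum(axis=1)
    e1 = e.sum(axis=1)
    det = ee * m - e1 ** 2
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    a = (se * m - s1 * e1) / det
    c = (ee * s1 - e1 * se) / det
    resid = ((a[:, None] * e + c[:, None] - s[None, :]) ** 2).sum(axis=1)
    resid = np.where(np.isnan(resid), np.inf, resid)
    i = int(np.argmin(resid))
    return VoxelFit(float(a[i]), float(t2_grid[i]), float(c[i]),
                    float(np.sqrt(resid[i])), True)


def interpolate_to_matrix(image: np.ndarray, spacing_mm, target=(256, 256),
                          order: int = 1):
    """Resample a 2D slice to ``target`` preserving its physical extent.

    Bilinear by default (``order=1``); use ``order=0`` for label/mask images.
    Returns ``(image, new_spacing)`` with the in-plane spacing rescaled so
    that extent (n * dx) is unchanged and volumes computed afterwards remain
    consistent.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expects a single 2D slice")
    tx, ty = target
    if tx <= 0 or ty <= 0:
        raise ValueError("target matrix must be positive")
    if img.shape == (tx, ty):
        return img.copy(), tuple(spacing_mm)
    out = resize(img.astype(float), (tx, ty), order=order, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    if img.dtype == bool:
        out = out >= 0.5
    new_spacing = (spacing_mm[0] * img.shape[0] / tx,
                   spacing_mm[1] * img.shape[1] / ty)
    return out, new_spacing
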