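"""Respiratory motion estimation and correction.

Rigid in-plane translation is estimated frame-by-frame from the fat-only
images (whose appearance is stable over the contrast passage) inside an
automatically placed bounding box around the fat, using normalized gradient
fields (NGF) as the similarity measure — NGF compares gradient directions
and is therefore robust to global intensity changes.  The estimated
translations are applied to the raw k-space data as linear phase shifts
(lossless: no regridding or interpolation of samples).  Residual
non-rigid motion is refined after the final reconstruction by registering
each frame to a motionless synthetic series built from a principal
component decomposition of the frame ensemble.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .config import RegistrationConfig
from .containers import DynamicImageSeries, KTData, MotionTrace
from .fourier import freq_grids

log = logging.getLogger(__name__)


# --- ROI -------------------------------------------------------------------

def fat_roi(image_series: np.ndarray, cfg: RegistrationConfig | None = None):
    """Binary mask and bounding box around the epicardial fat.

    Thresholds the temporal maximum image at ``mask_threshold`` of its max
    and dilates by ``dilation_radius``.  When the mask splits into several
    components (epicardial ring, chest-wall fat), the component whose
    centroid lies closest to the image center is kept — the epicardial fat
    encircles the heart, whereas chest-wall fat hugs the field-of-view edge
    and is a poor (aliasing-prone) registration anchor.  Returns the mask
    and the tight bounding box (y0, y1, x0, x1).
    """
    cfg = cfg or RegistrationConfig()
    series = np.asarray(image_series)
    if series.size == 0:
        raise ValueError("empty image series")
    tmax = np.abs(series).max(axis=2) if series.ndim == 3 else np.abs(series)
    if tmax.max() <= 0:
        raise ValueError("image series has no signal; cannot place fat ROI")
    mask = tmax >= cfg.mask_threshold * tmax.max()
    if not mask.any():
        raise ValueError(
            "threshold produced an empty mask; lower mask_threshold")
    if cfg.dilation_radius > 0:
        mask = ndimage.binary_dilation(
            mask, structure=_disk(cfg.dilation_radius))
    labels, n = ndimage.label(mask)
    if n > 1:
        center = np.asarray(mask.shape, dtype=float) / 2
        sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
        centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
        candidates = [i for i in range(n) if sizes[i] >= 0.05 * sizes.max()]
        best = min(candidates,
                   key=lambda i: np.hypot(*(np.asarray(centroids[i]) - center)))
        mask = labels == best + 1
    ys, xs = np.nonzero(mask)
    box = (int(ys.min()), int(ys.max()) + 1, int(xs.min()), int(xs.max()) + 1)
    return mask, box


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2


# --- NGF similarity --------------------------------------------------------

def _normalized_gradient(img: np.ndarray, eps: float):
    gy, gx = np.gradient(img)
    norm = np.sqrt(gy**2 + gx**2 + eps**2)
    return gy / norm, gx / norm


def ngf_similarity(u: np.ndarray, v: np.ndarray, eps: float) -> float:
    """Normalized-gradient-field similarity (higher = more aligned).

    NGF(u, v) = sum ( <grad u, grad v> / (|grad u|_eps |grad v|_eps) )^2.
    Invariant to positive rescaling of either image.
    """
    uy, ux = _normalized_gradient(u, eps)
    vy, vx = _normalized_gradient(v, eps)
    return float(((uy * vy + ux * vx) ** 2).sum())


def _auto_eps(img: np.ndarray) -> float:
    """Gradient-noise level for NGF: high percentile of |grad|.

    eps must sit at the level of noise/aliasing gradients so that only
    salient anatomical edges keep unit weight; the gradient histogram of a
    sparse fat image is dominated by weak artifact gradients, hence a high
    percentile rather than the median.
    """
    gy, gx = np.gradient(img)
    mag = np.hypot(gy, gx)
    p95 = float(np.percentile(mag, 95))
    return max(p95, 1e-6 * max(float(img.max()), 1e-12))


def estimate_translations(
    fat_series: np.ndarray,
    box,
    cfg: RegistrationConfig | None = None,
    reference_frame: int = 0,
) -> MotionTrace:
    """Per-frame translation maximizing NGF similarity to the reference frame.

    Integer grid search within ``max_shift`` (circular shifts, evaluated on
    the bounding box) followed by sub-pixel refinement via a separable
    quadratic fit of the similarity surface.  The estimate is returned
    re-referenced so the reference frame has zero shift.
    """
    cfg = cfg or RegistrationConfig()
    series = np.asarray(fat_series, dtype=float)
    ny, nx, nt = series.shape
    if nt < 2:
        raise ValueError("need at least two frames")
    y0, y1, x0, x1 = box
    if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError("bounding box outside image")
    sl = (slice(y0, y1), slice(x0, x1))

    ref = series[..., reference_frame]
    eps = cfg.ngf_epsilon if cfg.ngf_epsilon is not None else _auto_eps(ref)
    ry, rx = _normalized_gradient(ref, eps)
    ry, rx = ry[sl], rx[sl]

    max_s = int(cfg.max_shift)
    dx = np.zeros(nt)
    dy = np.zeros(nt)
    padded = {}
    for t in range(nt):
        if t == reference_frame:
            continue
        my, mx = _normalized_gradient(series[..., t], eps)
        # wrap-padding + slicing == circular shift, without per-shift rolls
        padded[t] = (np.pad(my, max_s, mode="wrap"),
                     np.pad(mx, max_s, mode="wrap"))
        dy[t], dx[t] = _search_shift(padded[t], (ry, rx), box, max_s,
                                     0, 0, max_s, t)
        dy[t], dx[t] = _refine_subpixel(series[..., t], (ry, rx), sl, eps,
                                        dy[t], dx[t])
    return MotionTrace(dx=dx, dy=dy, reference_frame=reference_frame)


def _refine_subpixel(moving, ref_grad, sl, eps, dy0, dx0):
    """Continuous NGF maximization around the grid estimate.

    The quadratic fit of the discrete surface carries a small bias from
    surface asymmetry; a short derivative-free polish on Fourier-shifted
    images removes it.
    """
    from scipy.optimize import minimize

    from .fourier import shift_image

    ry, rx = ref_grad

    def neg(shift):
        aligned = shift_image(moving, -shift[0], -shift[1])
        my, mx = _normalized_gradient(aligned, eps)
        return -(((my[sl] * ry + mx[sl] * rx) ** 2).sum())

    res = minimize(neg, x0=[dy0, dx0], method="Nelder-Mead",
                   options={"xatol": 5e-3, "fatol": 1e-9, "maxiter": 60})
    fy, fx = res.x
    if np.hypot(fy - dy0, fx - dx0) > 1.0:  # polish must stay local
        return dy0, dx0
    return float(fy), float(fx)


def _search_shift(moving_padded, ref_grad, box, max_s, cy, cx, radius, t):
    """Integer NGF search in a square window around (cy, cx) + sub-pixel fit."""
    pmy, pmx = moving_padded
    ry, rx = ref_grad
    y0, y1, x0, x1 = box
    sy_range = np.arange(max(cy - radius, -max_s), min(cy + radius, max_s) + 1)
    sx_range = np.arange(max(cx - radius, -max_s), min(cx + radius, max_s) + 1)
    sim = np.empty((len(sy_range), len(sx_range)))
    for i, sy in enumerate(sy_range):
        ysl = slice(y0 + sy + max_s, y1 + sy + max_s)
        for j, sx in enumerate(sx_range):
            xsl = slice(x0 + sx + max_s, x1 + sx + max_s)
            sim[i, j] = ((pmy[ysl, xsl] * ry + pmx[ysl, xsl] * rx) ** 2).sum()
    i, j = np.unravel_index(np.argmax(sim), sim.shape)
    if i in (0, len(sy_range) - 1) or j in (0, len(sx_range) - 1):
        if abs(sy_range[i]) >= max_s or abs(sx_range[j]) >= max_s:
            log.warning("frame %d: translation search hit max_shift bound", t)
        sub_y = sub_x = 0.0
    else:
        sub_y = _parabolic(sim[i - 1, j], sim[i, j], sim[i + 1, j])
        sub_x = _parabolic(sim[i, j - 1], sim[i, j], sim[i, j + 1])
    return sy_range[i] + sub_y, sx_range[j] + sub_x


def _parabolic(fm, f0, fp) -> float:
    denom = fm - 2 * f0 + fp
    if denom >= 0:  # not a maximum; keep the grid point
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def select_reference_frame(trace: MotionTrace) -> int:
    """Frame whose superior-inferior displacement is closest to the mean.

    Ties break to the lowest index.
    """
    if len(trace) == 0:
        raise ValueError("empty motion trace")
    dev = np.abs(trace.dy - trace.dy.mean())
    return int(np.argmin(dev))


def estimate_motion(
    fat_series: np.ndarray,
    water_series: np.ndarray | None = None,
    cfg: RegistrationConfig | None = None,
) -> MotionTrace:
    """Two-pass translation estimation from the fat images.

    The bounding box is placed from the water images when given (their
    bright blood pools outline the heart, and hence the epicardial fat,
    far more reliably than the sparse fat signal itself); registration then
    runs on the fat images inside that box.  A provisional trace against
    frame 0 selects the reference frame (SI displacement closest to the
    mean); the final trace is re-estimated against that reference.
    """
    cfg = cfg or RegistrationConfig()
    _, box = fat_roi(water_series if water_series is not None else fat_series,
                     cfg)
    provisional = estimate_translations(fat_series, box, cfg, reference_frame=0)
    ref = select_reference_frame(provisional)
    final = estimate_translations(fat_series, box, cfg, reference_frame=ref)
    return final


# --- k-space correction -----------------------------------------------------

def apply_phase_shift(kt: KTData, trace: MotionTrace) -> KTData:
    """Shift each frame's image content by (dx, dy) via k-space linear phase.

    Samples of frame t are multiplied by
    exp(-i 2 pi (kx dx_t / nx + ky dy_t / ny)); the mask is unchanged and
    per-frame k-space energy is conserved exactly.  To *correct* motion,
    pass the negated estimated trace.
    """
    samples = np.asarray(kt.samples)
    nc, ny, nx, nt, ne = samples.shape
    if len(trace) != nt:
        raise ValueError("trace length does not match frame count")
    ky, kx = freq_grids(ny, nx)
    phase = np.exp(
        -2j * np.pi * (ky[None, :, :, None, None] * trace.dy[None, None, None, :, None]
                       + kx[None, :, :, None, None] * trace.dx[None, None, None, :, None]))
    return KTData(samples=samples * phase, mask=kt.mask, coil_maps=kt.coil_maps,
                  acq=kt.acq, frame_times=kt.frame_times, aif_images=kt.aif_images)


def correct_kt(kt: KTData, trace: MotionTrace) -> KTData:
    """Motion-correct k-space data with an estimated trace (negated shift)."""
    return apply_phase_shift(kt, trace.negated())


# --- non-rigid refinement ---------------------------------------------------

def pca_synthetic_series(series: np.ndarray, n_components: int) -> np.ndarray:
    """Motionless surrogate series: projection onto the leading principal
    components of the frame ensemble (mean included).

    Low-rank temporal structure captures the contrast dynamics while
    averaging out frame-specific residual displacements.
    """
    ny, nx, nt = series.shape
    if n_components >= nt:
        raise ValueError("n_components must be < number of frames")
    casorati = series.reshape(ny * nx, nt)
    mean = casorati.mean(axis=1, keepdims=True)
    u, s, vh = np.linalg.svd(casorati - mean, full_matrices=False)
    approx = (u[:, :n_components] * s[:n_components]) @ vh[:n_components]
    return (mean + approx).reshape(ny, nx, nt)


def nonrigid_refine(
    series: DynamicImageSeries,
    cfg: RegistrationConfig | None = None,
    return_fields: bool = False,
):
    """Deformable refinement of residual motion against a PCA surrogate.

    Each magnitude frame is registered to its synthetic (PCA-projected)
    counterpart with symmetric-forces diffeomorphic demons; returns the
    warped series (and optionally the deformation fields).
    """
    import SimpleITK as sitk

    cfg = cfg or RegistrationConfig()
    data = np.abs(np.asarray(series.data, dtype=float) if np.isrealobj(series.data)
                  else series.data).astype(float)
    if data.ndim != 3:
        raise ValueError("nonrigid_refine expects a single-echo magnitude series")
    target = pca_synthetic_series(data, cfg.pca_components)

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(cfg.demons_iterations)
    demons.SetStandardDeviations(cfg.demons_smoothing)

    out = np.empty_like(data)
    fields = np.empty(data.shape[:2] + (data.shape[2], 2))
    for t in range(data.shape[2]):
        fixed = sitk.GetImageFromArray(target[..., t])
        moving = sitk.GetImageFromArray(data[..., t])
        field = demons.Execute(fixed, moving)
        warped = sitk.Warp(moving, field,
                           outputSize=fixed.GetSize(),
                           outputSpacing=fixed.GetSpacing())
        out[..., t] = sitk.GetArrayFromImage(warped)
        fields[..., t, :] = sitk.GetArrayFromImage(field)
    refined = DynamicImageSeries(data=out, pixel_spacing=series.pixel_spacing,
                                 frame_times=series.frame_times)
    if return_fields:
        return refined, fields
    return refined
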