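"""Regularized SENSE reconstruction of k-t undersampled dynamic images.

Solves  x_hat = argmin_x  1/2 ||E x - k||^2 + alpha ||x||_* + beta ||Psi x||_1
with E the (mask o FFT o coil) SENSE encoding operator, ||.||_* the nuclear
norm of the space x time Casorati matrix (temporal low rank) and Psi the
spatial anisotropic total-variation operator, by a monotone proximal
gradient scheme with backtracking: a data-consistency gradient step
followed by singular-value thresholding and a TV proximal step, applied
sequentially.  A spatial-wavelet-only variant (no temporal regularization)
is provided as the compressed-sensing comparator baseline.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt

from .config import ReconConfig
from .containers import DynamicImageSeries, KTData
from .fourier import fft2c, ifft2c

log = logging.getLogger(__name__)


# --- encoding operator ------------------------------------------------------

def _as4d(x: np.ndarray) -> np.ndarray:
    return x[..., None] if x.ndim == 3 else x


def encode(x: np.ndarray, coil_maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """SENSE forward operator: per coil j and frame t, M_t o F(c_j x_t).

    ``x`` is (y, x, frame[, echo]); returns (coil, ky, kx, frame, echo).
    """
    x4 = _as4d(np.asarray(x))
    ny, nx, nt, _ = x4.shape
    if coil_maps.shape[1:] != (ny, nx) or mask.shape != (ny, nx, nt):
        raise ValueError("encode: inconsistent shapes")
    k = fft2c(coil_maps[:, :, :, None, None] * x4[None], axes=(1, 2))
    return mask[None, :, :, :, None] * k


def encode_adjoint(k: np.ndarray, coil_maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`encode`: sum_j conj(c_j) F^H (M_t o k_j)."""
    km = mask[None, :, :, :, None] * k
    imgs = ifft2c(km, axes=(1, 2))
    return (np.conj(coil_maps)[:, :, :, None, None] * imgs).sum(axis=0)


# --- proximal operators -----------------------------------------------------

def svt(casorati: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: prox of tau * nuclear norm."""
    if not np.isfinite(casorati).all():
        raise ValueError("svt: non-finite entries")
    if tau < 0:
        raise ValueError("svt: tau must be >= 0")
    if tau == 0:
        return casorati
    u, s, vh = np.linalg.svd(casorati, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (u * s) @ vh


def tv_anisotropic(frame: np.ndarray) -> np.ndarray:
    """Stacked horizontal/vertical forward differences (replicate boundary).

    Returns shape (2,) + frame.shape; the last row/column difference is zero.
    """
    dv = np.diff(frame, axis=0, append=frame[-1:, :])
    dh = np.diff(frame, axis=1, append=frame[:, -1:])
    return np.stack([dv, dh])


def _tv_adjoint(p: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`tv_anisotropic` (negative divergence)."""
    dv, dh = p[0], p[1]
    out = np.zeros_like(dv)
    out[0, :] -= dv[0, :]
    out[1:, :] -= dv[1:, :] - dv[:-1, :]
    out[-1, :] += dv[-1, :]  # cancel the zero-difference boundary row
    outh = np.zeros_like(dh)
    outh[:, 0] -= dh[:, 0]
    outh[:, 1:] -= dh[:, 1:] - dh[:, :-1]
    outh[:, -1] += dh[:, -1]
    return out + outh


def prox_tv(frame: np.ndarray, w: float, n_iter: int = 25) -> np.ndarray:
    """Proximal operator of w ||Psi .||_1 by dual projected gradient.

    Solves min_z 1/2 ||z - x||^2 + w ||Psi z||_1 with a fixed number of
    Chambolle-type dual iterations (deterministic, tolerance-free).
    """
    if w < 0:
        raise ValueError("prox_tv: weight must be >= 0")
    if w == 0:
        return frame
    dt = frame.dtype if np.iscomplexobj(frame) else np.result_type(frame, float)
    pv = np.zeros(frame.shape, dtype=dt)
    ph = np.zeros(frame.shape, dtype=dt)
    t = 0.125  # 1 / ||Psi||^2
    for _ in range(n_iter):
        z = frame - _div_pair(pv, ph)
        pv += t * np.diff(z, axis=0, append=z[-1:, :])
        ph += t * np.diff(z, axis=1, append=z[:, -1:])
        np.divide(pv, np.maximum(np.abs(pv) / w, 1.0), out=pv)
        np.divide(ph, np.maximum(np.abs(ph) / w, 1.0), out=ph)
    return frame - _div_pair(pv, ph)


def _div_pair(pv: np.ndarray, ph: np.ndarray) -> np.ndarray:
    """Adjoint of the stacked forward differences, from separate components."""
    out = np.empty_like(pv)
    out[0, :] = -pv[0, :]
    out[1:, :] = pv[:-1, :] - pv[1:, :]
    out[-1, :] += pv[-1, :]
    out[:, 0] += -ph[:, 0]
    out[:, 1:] += ph[:, :-1] - ph[:, 1:]
    out[:, -1] += ph[:, -1]
    return out


# boundary rows of tv_anisotropic are structurally zero; drop their adjoint
# contribution so Psi^T is the exact adjoint of the map actually applied
def _tv_l1(frame: np.ndarray) -> float:
    g = tv_anisotropic(frame)
    return float(np.abs(g).sum())


# --- wavelet comparator prox ------------------------------------------------

def wavelet_transform(frame: np.ndarray, wavelet: str = "db4", level: int = 3):
    return pywt.wavedec2(frame, wavelet, mode="periodization", level=level,
                         axes=(0, 1))


def wavelet_inverse(coeffs, wavelet: str = "db4"):
    return pywt.waverec2(coeffs, wavelet, mode="periodization", axes=(0, 1))


def _soft(c: np.ndarray, t: float) -> np.ndarray:
    mag = np.abs(c)
    return c * np.maximum(1 - t / np.maximum(mag, 1e-300), 0.0)


def _prox_wavelet(x: np.ndarray, t: float, wavelet: str, level: int) -> np.ndarray:
    coeffs = wavelet_transform(x, wavelet, level)
    out = [_soft(coeffs[0], t)]
    for band in coeffs[1:]:
        out.append(tuple(_soft(b, t) for b in band))
    return wavelet_inverse(out, wavelet)


def _wavelet_l1(x: np.ndarray, wavelet: str, level: int) -> float:
    coeffs = wavelet_transform(x, wavelet, level)
    total = float(np.abs(coeffs[0]).sum())
    for band in coeffs[1:]:
        total += sum(float(np.abs(b).sum()) for b in band)
    return total


# --- solvers ----------------------------------------------------------------

def _casorati_nuclear(x4: np.ndarray, joint: bool) -> float:
    ny, nx, nt, ne = x4.shape
    if joint:
        s = np.linalg.svd(x4.reshape(ny * nx, nt * ne), compute_uv=False)
        return float(s.sum())
    total = 0.0
    for e in range(ne):
        s = np.linalg.svd(x4[..., e].reshape(ny * nx, nt), compute_uv=False)
        total += float(s.sum())
    return total


def _svt_series(x4: np.ndarray, tau: float, joint: bool):
    """SVT of the Casorati matrix per echo; also returns the nuclear norm of
    the thresholded result (free from the shrunk singular values)."""
    ny, nx, nt, ne = x4.shape
    if joint:
        mat = x4.reshape(ny * nx, nt * ne)
        u, s, vh = np.linalg.svd(mat, full_matrices=False)
        s = np.maximum(s - tau, 0.0)
        return ((u * s) @ vh).reshape(x4.shape), float(s.sum())
    out = np.empty_like(x4)
    nuc = 0.0
    for e in range(ne):
        u, s, vh = np.linalg.svd(x4[..., e].reshape(ny * nx, nt),
                                 full_matrices=False)
        s = np.maximum(s - tau, 0.0)
        out[..., e] = ((u * s) @ vh).reshape(ny, nx, nt)
        nuc += float(s.sum())
    return out, nuc


def _solve(kt: KTData, cfg: ReconConfig, penalty: str) -> DynamicImageSeries:
    work_dtype = np.dtype(cfg.dtype)
    mask = kt.mask.mask.astype(
        np.float32 if work_dtype == np.complex64 else np.float64)
    maps = np.asarray(kt.coil_maps, dtype=work_dtype)
    k = np.asarray(kt.samples, dtype=work_dtype)

    x0 = encode_adjoint(k, maps, mask)
    scale = float(np.abs(x0).max())
    if cfg.normalize and scale > 0:
        k = k / scale
        x0 = x0 / scale

    def residual(x4):
        return encode(x4, maps, mask) - k

    def data_term(r):
        return 0.5 * float(np.vdot(r, r).real)

    def apply_prox(x4, step):
        """Prox step; returns the new iterate and its penalty value."""
        if penalty == "lrs":
            out = x4
            nuc = 0.0
            if cfg.alpha > 0:
                out, nuc = _svt_series(out, step * cfg.alpha,
                                       cfg.joint_echo_lowrank)
            if cfg.beta > 0:
                out = prox_tv(out, step * cfg.beta, cfg.tv_inner_iter)
                if cfg.alpha > 0:
                    nuc = _casorati_nuclear(out, cfg.joint_echo_lowrank)
            return out, cfg.alpha * nuc + cfg.beta * _tv_l1(out)
        if cfg.lam > 0:
            out = _prox_wavelet(x4, step * cfg.lam, cfg.wavelet,
                                cfg.wavelet_level)
        else:
            out = x4
        return out, cfg.lam * _wavelet_l1(out, cfg.wavelet, cfg.wavelet_level)

    def penalty_value(x4):
        if penalty == "lrs":
            return (cfg.alpha * _casorati_nuclear(x4, cfg.joint_echo_lowrank)
                    + cfg.beta * _tv_l1(x4))
        return cfg.lam * _wavelet_l1(x4, cfg.wavelet, cfg.wavelet_level)

    x = x0.copy()
    step = cfg.step
    r = residual(x)
    obj_prev = data_term(r) + penalty_value(x)
    obj_initial = obj_prev
    objective_log = []
    margin = 1e-5 if work_dtype == np.complex64 else 1e-12
    for it in range(cfg.n_iter):
        g = encode_adjoint(r, maps, mask)
        accepted = False
        for _ in range(8):
            x_new, pen_new = apply_prox(x - step * g, step)
            r_new = residual(x_new)
            obj_new = data_term(r_new) + pen_new
            if obj_new <= obj_prev * (1 + margin):
                accepted = True
                break
            step *= 0.5
        if accepted:
            x, r, obj_prev = x_new, r_new, min(obj_new, obj_prev)
        # else: keep x (objective flat); step stays reduced
        objective_log.append(obj_prev)
        if obj_prev > 10 * obj_initial:
            raise RuntimeError(
                f"reconstruction diverged at iteration {it}: "
                f"objective {obj_prev:.3e} > 10 x initial {obj_initial:.3e}")

    if cfg.normalize and scale > 0:
        x = x * scale
    x = x.astype(complex)
    out = x[..., 0] if np.asarray(kt.samples).shape[-1] == 1 else x
    series = DynamicImageSeries(data=out, frame_times=kt.frame_times)
    series.objective_log = np.asarray(objective_log)
    return series


def solve_lrs(kt: KTData, cfg: ReconConfig | None = None) -> DynamicImageSeries:
    """Low-rank plus total-variation regularized SENSE reconstruction.

    Runs exactly ``cfg.n_iter`` proximal-gradient iterations and records the
    objective per iteration in ``result.objective_log``.
    """
    return _solve(kt, cfg or ReconConfig(), "lrs")


def solve_wavelet_cs(kt: KTData, cfg: ReconConfig | None = None) -> DynamicImageSeries:
    """Spatial-wavelet-only compressed-sensing comparator (no temporal term)."""
    return _solve(kt, cfg or ReconConfig(), "wavelet")


def zero_filled(kt: KTData) -> DynamicImageSeries:
    """Adjoint (zero-filled) reconstruction, for baselines and normalization."""
    x = encode_adjoint(np.asarray(kt.samples, dtype=complex),
                       kt.coil_maps, kt.mask.mask.astype(float))
    out = x[..., 0] if np.asarray(kt.samples).shape[-1] == 1 else x
    return DynamicImageSeries(data=out, frame_times=kt.frame_times)
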