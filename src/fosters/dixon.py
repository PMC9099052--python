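"""Two-point water-fat separation from dual-echo complex images.

The echo times of the target protocol (1.1 / 1.9 ms at 3 T) are not an
in/out-of-phase pair (the fat phasor advances about -125 degrees between
echoes), so a flexible-TE two-point Dixon is used.  Per voxel the signal
model is

    S(TE_e) = (W + F c_e) P(TE_e),   c_e = exp(i 2 pi df_fat TE_e),

with real nonnegative water W and fat F and a unit-modulus phasor P
carrying B0 off-resonance and receiver phase.  Taking the echo ratio
r = S2/S1 eliminates W and F up to the fat:water ratio x = F/W, which
satisfies a real quadratic whose two roots are reciprocal (the classic
water-dominant / fat-dominant ambiguity).  Each root implies a candidate
inter-echo phasor; the ambiguity is resolved by assuming B0 varies smoothly
in space (region growing from the most reliable voxel), after which the
smoothed phasor is demodulated and W, F follow from a 2x2 linear solve.

T2* decay between the two echoes is neglected during separation; the AIF,
where the bias matters, is corrected separately.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import AcquisitionParams
from .containers import DynamicImageSeries, WaterFatPair


def _fat_phasors(acq: AcquisitionParams, echo_times=None) -> tuple[complex, complex]:
    df = acq.fat_offset_hz
    te1, te2 = echo_times if echo_times is not None else (acq.te1, acq.te2)
    c1 = np.exp(2j * np.pi * df * te1 * 1e-3)
    c2 = np.exp(2j * np.pi * df * te2 * 1e-3)
    if abs(c2 / c1 - 1.0) < 1e-3:
        raise ValueError(
            "echo spacing encodes no water-fat phase difference "
            "(fat phasor between echoes equals 1); separation is degenerate")
    return c1, c2


def _candidate_ratios(r: np.ndarray, c1: complex, c2: complex):
    """Roots of the fat:water ratio quadratic for each voxel.

    |1 + x c2|^2 = |r|^2 |1 + x c1|^2 gives
    q (x^2 + 1) + 2 x (Re c2 - |r|^2 Re c1) = 0 with q = 1 - |r|^2; the two
    real roots are reciprocal.  Noisy voxels with negative discriminant fall
    back to the double root.
    """
    r2 = np.abs(r) ** 2
    q = 1.0 - r2
    lin = c2.real - r2 * c1.real
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = lin**2 - q**2
        sq = np.sqrt(np.maximum(disc, 0.0))
        # the two roots are reciprocal; compute the larger-magnitude one
        # stably (no cancellation) and take 1/x for the other
        denom = np.where(np.abs(q) > 1e-300, q, 1e-300)
        xbig = -(lin + np.sign(lin) * sq) / denom
        xsmall = np.where(np.abs(xbig) > 1e-30, 1.0 / xbig, 1e12)
    # no positive root (pure voxel, or |r| pulled below 1 by inter-echo T2*
    # decay/noise): offer the water-like and fat-like limits and let the
    # phasor smoothness decision pick between them
    pure = xbig <= 0
    xa = np.where(pure, 0.0, np.clip(xsmall, 0.0, 1e12))
    xb = np.where(pure, 1e12, np.clip(xbig, 0.0, 1e12))
    return xa, xb


def _phasor_for(x: np.ndarray, r: np.ndarray, c1: complex, c2: complex):
    p = r * (1.0 + x * c1) / (1.0 + x * c2)
    mag = np.abs(p)
    return np.where(mag > 0, p / np.maximum(mag, 1e-300), 1.0)


def _region_grow_phasor(pa, pb, weight, reliability: float = 0.1):
    """Choose between the two candidate phasors per voxel by smoothness.

    Only voxels above ``reliability`` times the peak magnitude take part:
    in signal-free background both candidates are noise and a growth chain
    passing through it would randomize every decision downstream.  Each
    connected reliable component is grown separately in best-first order
    from its brightest voxel; each voxel picks the candidate closest to the
    mean phasor of its already-decided neighbors, and seeds pick the
    candidate with the smaller phase (small mean off-resonance assumption).
    Unreliable voxels keep a unit phasor (the subsequent magnitude-weighted
    smoothing overrides them from their bright surroundings).
    """
    from scipy import ndimage

    ny, nx = weight.shape
    chosen = np.ones((ny, nx), dtype=complex)
    decided = np.zeros((ny, nx), dtype=bool)
    reliable = weight >= reliability * weight.max()
    labels, n_comp = ndimage.label(reliable)
    neigh = ((-1, 0), (1, 0), (0, -1), (0, 1))
    for comp in range(1, n_comp + 1):
        inside = labels == comp
        masked = np.where(inside, weight, -1.0)
        sy, sx = np.unravel_index(np.argmax(masked), weight.shape)
        heap = [(-weight[sy, sx], sy, sx)]
        while heap:
            _, y, x = heapq.heappop(heap)
            if decided[y, x]:
                continue
            ref = 0.0 + 0.0j
            for dy, dx in neigh:
                yy, xx = y + dy, x + dx
                if 0 <= yy < ny and 0 <= xx < nx and decided[yy, xx]:
                    ref += chosen[yy, xx]
            cands = (pa[y, x], pb[y, x])
            if abs(ref) > 0:
                pick = min(cands, key=lambda c: abs(c - ref / abs(ref)))
            else:
                pick = min(cands, key=lambda c: abs(np.angle(c)))
            chosen[y, x] = pick
            decided[y, x] = True
            for dy, dx in neigh:
                yy, xx = y + dy, x + dx
                if (0 <= yy < ny and 0 <= xx < nx and not decided[yy, xx]
                        and labels[yy, xx] == comp):
                    heapq.heappush(heap, (-weight[yy, xx], yy, xx))
    return chosen


def separate_water_fat(
    dual_echo: DynamicImageSeries,
    acq: AcquisitionParams,
    smooth_sigma: float = 3.0,
    echo_times=None,
) -> WaterFatPair:
    """Flexible-TE two-point Dixon separation of a dual-echo dynamic series.

    The inter-echo phasor field (static in time) is estimated from the
    time-averaged echoes, disambiguated by region growing, smoothed, and
    then demodulated frame by frame.  Returns nonnegative water and fat
    magnitude series and the unit phasor field.
    """
    data = dual_echo.data
    if data.ndim != 4 or data.shape[3] != 2:
        raise ValueError("separate_water_fat requires exactly two echoes")
    c1, c2 = _fat_phasors(acq, echo_times)

    s1_avg = data[..., 0].mean(axis=2)
    s2_avg = data[..., 1].mean(axis=2)
    mag = np.abs(s1_avg)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mag > 0, s2_avg / np.where(mag > 0, s1_avg, 1.0), 1.0)
    xa, xb = _candidate_ratios(r, c1, c2)
    pa = _phasor_for(xa, r, c1, c2)
    pb = _phasor_for(xb, r, c1, c2)
    phasor = _region_grow_phasor(pa, pb, mag)

    # weighted smoothing keeps the estimate anchored to bright voxels
    wre = gaussian_filter(mag * phasor.real, smooth_sigma)
    wim = gaussian_filter(mag * phasor.imag, smooth_sigma)
    norm = np.hypot(wre, wim)
    phasor_s = np.where(norm > 0, (wre + 1j * wim) / np.maximum(norm, 1e-300), 1.0)

    # demodulate and solve the 2x2 system per voxel and frame
    s1 = data[..., 0]
    s2 = data[..., 1] * np.conj(phasor_s)[:, :, None]
    det = c2 - c1
    w_c = (s1 * c2 - s2 * c1) / det
    f_c = (s2 - s1) / det
    water = np.abs(w_c)
    fat = np.abs(f_c)
    return WaterFatPair(water=water, fat=fat, fieldmap_phasor=phasor_s,
                        water_complex=w_c, fat_complex=f_c)


def coherent_magnitude(series_complex: np.ndarray) -> np.ndarray:
    """Project a complex series onto its per-pixel temporal-mean phase.

    For a pixel with stable phase, Re(s exp(-i phi_mean)) equals the
    magnitude but keeps zero-mean complex noise zero-mean, avoiding the
    Rician/rectification bias of |s| that distorts low-signal dynamics.
    Values are floored at zero.
    """
    mean = series_complex.mean(axis=2)
    phase = np.where(np.abs(mean) > 0, mean / np.maximum(np.abs(mean), 1e-300), 1.0)
    coh = (series_complex * np.conj(phase)[:, :, None]).real
    return np.maximum(coh, 0.0)


def fat_fraction(pair: WaterFatPair) -> np.ndarray:
    """Fat signal fraction F/(W+F) in [0, 1]; NaN where W+F = 0."""
    total = pair.water + pair.fat
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = np.where(total > 0, pair.fat / np.where(total > 0, total, 1.0), np.nan)
    return np.clip(ff, 0.0, 1.0)
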