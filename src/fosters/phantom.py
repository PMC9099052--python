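"""Digital first-pass perfusion phantom.

Generates a short-axis slice with RV and LV blood pools, a myocardial
annulus (optionally with a hypoperfused sector), an epicardial fat ring and
a subcutaneous fat band; propagates a gamma-variate contrast bolus through
the blood pools and the 2CXM into the myocardium; forms saturation-recovery
dual-echo signals with concentration-dependent T2* loss and a single-peak
fat chemical shift; applies translational breathing motion; and encodes the
result into undersampled multi-coil k-t data.  Everything is deterministic
for a fixed seed, and all ground truth (images, motion, concentrations,
MBF) is retained for validation.
"""

from __future__ import annotations

import logging

import numpy as np

from . import quant
from .config import AcquisitionParams, PhantomConfig
from .containers import (AIFCurve, DynamicImageSeries, KTData, MotionTrace,
                         PhantomTruth, SamplingPattern)
from .fourier import fft2c, shift_image

log = logging.getLogger(__name__)

T2STAR_FLOOR_MS = 0.1


def generate_aif(aif_params, times) -> AIFCurve:
    """Gamma-variate bolus curve C(t) = A (t-t0)^a exp(-(t-t0)/b), in mM."""
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly ascending")
    p = aif_params
    if p.a <= 0 or p.b <= 0:
        raise ValueError("gamma-variate shape parameters must be positive")
    dt = t - p.t0
    conc = np.where(dt > 0, p.A * np.maximum(dt, 0) ** p.a * np.exp(-np.maximum(dt, 0) / p.b), 0.0)
    return AIFCurve(times=t, concentration=conc)


def _disc(ny, nx, center, radius):
    yy, xx = np.mgrid[0:ny, 0:nx]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_masks(config: PhantomConfig) -> np.ndarray:
    """Label image: 0 background, 1 RV, 2 LV, 3 myocardium, 4 fat."""
    ny, nx = config.grid_size
    g = config.geometry
    labels = np.zeros((ny, nx), dtype=np.uint8)
    fat = _disc(ny, nx, g.lv_center, g.fat_outer_radius) & ~_disc(
        ny, nx, g.lv_center, g.myo_outer_radius)
    myo = _disc(ny, nx, g.lv_center, g.myo_outer_radius) & ~_disc(
        ny, nx, g.lv_center, g.lv_radius)
    lv = _disc(ny, nx, g.lv_center, g.lv_radius)
    rv = _disc(ny, nx, g.rv_center, g.rv_radius)
    r0, r1 = g.chest_fat_rows
    labels[r0:r1, :] = PhantomTruth.LABEL_FAT
    labels[fat] = PhantomTruth.LABEL_FAT
    labels[rv & (labels == 0)] = PhantomTruth.LABEL_RV
    labels[myo] = PhantomTruth.LABEL_MYO
    labels[lv] = PhantomTruth.LABEL_LV
    return labels


def _defect_mask(config: PhantomConfig, labels: np.ndarray) -> np.ndarray:
    d = config.defect
    if d is None:
        return np.zeros(labels.shape, dtype=bool)
    ny, nx = labels.shape
    cy, cx = config.geometry.lv_center
    yy, xx = np.mgrid[0:ny, 0:nx]
    theta = np.arctan2(yy - cy, xx - cx)
    ang = np.angle(np.exp(1j * (theta - d.center_angle)))
    sector = np.abs(ang) <= d.width / 2
    mask = sector & (labels == PhantomTruth.LABEL_MYO)
    if not mask.any():
        raise ValueError("defect sector does not intersect the myocardium")
    return mask


def motion_trace(config: PhantomConfig) -> MotionTrace:
    """Programmed breathing translation, sinusoidal or drifting."""
    m = config.motion
    t = config.frame_times
    phase = 2 * np.pi * t / m.period
    if m.pattern == "sinusoid":
        dy = m.amplitude * np.sin(phase)
        dx = m.amplitude_lr * np.sin(phase + np.pi / 4)
    else:  # drift: incomplete breath-hold, slow drift plus breathing
        drift = np.linspace(0, m.amplitude, len(t))
        dy = drift + 0.3 * m.amplitude * np.sin(phase)
        dx = 0.3 * m.amplitude_lr * np.sin(phase)
    return MotionTrace(dx=dx, dy=dy, reference_frame=0)


def render_truth(config: PhantomConfig) -> PhantomTruth:
    """Ground-truth dynamic water/fat images, concentrations, motion and MBF."""
    acq = config.acquisition
    ny, nx = config.grid_size
    times = config.frame_times
    labels = make_masks(config)
    defect = _defect_mask(config, labels)

    lv_aif = generate_aif(config.aif_params, times)
    p = config.aif_params
    rv_params = type(p)(A=p.A * p.rv_scale, t0=p.t0 - p.rv_lead, a=p.a, b=p.b)
    rv_curve = generate_aif(rv_params, times).concentration

    kin = config.kinetics
    myo_curve = quant.cxm_forward(
        _kin_params(kin), lv_aif).concentration
    if config.defect is not None:
        defect_kin = type(kin)(Fp=config.defect.Fp, PS=kin.PS, vp=kin.vp,
                               ve=kin.ve, delay=kin.delay)
        defect_curve = quant.cxm_forward(_kin_params(defect_kin), lv_aif).concentration
    else:
        defect_curve = myo_curve

    # static (motion-free) concentration maps
    conc_static = np.zeros((ny, nx, config.n_frames))
    conc_static[labels == PhantomTruth.LABEL_RV] = rv_curve
    conc_static[labels == PhantomTruth.LABEL_LV] = lv_aif.concentration
    conc_static[(labels == PhantomTruth.LABEL_MYO) & ~defect] = myo_curve
    conc_static[defect] = defect_curve

    # water proton density and static fat content
    m0_water = np.zeros((ny, nx))
    m0_water[labels == PhantomTruth.LABEL_RV] = config.m0_blood
    m0_water[labels == PhantomTruth.LABEL_LV] = config.m0_blood
    m0_water[labels == PhantomTruth.LABEL_MYO] = config.m0_myo
    # epicardial fat carries a small water fraction; the subcutaneous band
    # is modeled as water-free
    geom = config.geometry
    epicardial = _disc(ny, nx, geom.lv_center, geom.fat_outer_radius) & ~_disc(
        ny, nx, geom.lv_center, geom.myo_outer_radius)
    m0_water[epicardial & (labels == PhantomTruth.LABEL_FAT)] = config.fat_ring_water
    t10 = np.full((ny, nx), np.inf)
    t10[(labels == PhantomTruth.LABEL_RV) | (labels == PhantomTruth.LABEL_LV)] = acq.t1_blood_0
    t10[labels == PhantomTruth.LABEL_MYO] = acq.t1_myo_0
    t10[labels == PhantomTruth.LABEL_FAT] = acq.t1_myo_0  # fat-ring water signal

    fat_static_img = np.zeros((ny, nx))
    g = config.geometry
    fat_sat = 1.0 - np.exp(-(acq.ts_long / 1000.0) / (config.t1_fat / 1000.0))
    ring = (labels == PhantomTruth.LABEL_FAT)
    fat_static_img[ring] = config.fat_ring_fat * fat_sat
    fat_static_img[g.chest_fat_rows[0]:g.chest_fat_rows[1], :] = (
        config.chest_fat_fat * fat_sat)
    fat_static_img *= (labels == PhantomTruth.LABEL_FAT)

    # saturation-recovery water signal per frame (long TS, high-res image)
    water_static = np.zeros((ny, nx, config.n_frames))
    inside = labels > 0
    for fi in range(config.n_frames):
        water_static[..., fi][inside] = quant.concentration_to_signal(
            conc_static[..., fi][inside], acq.ts_long, t10[inside],
            acq.r1_relaxivity, m0=m0_water[inside])

    trace = motion_trace(config)
    water = np.empty_like(water_static)
    fat = np.empty((ny, nx, config.n_frames))
    conc = np.empty_like(conc_static)
    for fi in range(config.n_frames):
        water[..., fi] = shift_image(water_static[..., fi], trace.dy[fi], trace.dx[fi])
        fat[..., fi] = shift_image(fat_static_img, trace.dy[fi], trace.dx[fi])
        conc[..., fi] = np.maximum(
            shift_image(conc_static[..., fi], trace.dy[fi], trace.dx[fi]), 0.0)

    mbf_map = np.zeros((ny, nx))
    mbf_map[labels == PhantomTruth.LABEL_MYO] = kin.Fp
    if config.defect is not None:
        mbf_map[defect] = config.defect.Fp

    # RV insertion points on the epicardial boundary (anterior first)
    cy, cx = g.lv_center
    rv_dir = np.arctan2(g.rv_center[0] - cy, g.rv_center[1] - cx)
    half = 0.9
    ins = []
    for s in (-1, +1):  # anterior (-y side) first
        th = rv_dir + s * half
        ins.append((cy + g.myo_outer_radius * np.sin(th),
                    cx + g.myo_outer_radius * np.cos(th)))
    ins.sort(key=lambda p_: p_[0])  # smaller row = superior/anterior
    rv_insertion = np.asarray(ins)

    # low-resolution short-TS AIF signals (both echoes), noiseless truth
    t2s_blood = _t2star_ms(acq, lv_aif.concentration)
    sat_short = 1.0 - np.exp(
        -(acq.ts_short / 1000.0)
        * (1.0 / (acq.t1_blood_0 / 1000.0) + acq.r1_relaxivity * lv_aif.concentration))
    s_short = config.m0_blood * sat_short
    aif_e1 = s_short * np.exp(-acq.te1 / t2s_blood)
    aif_e2 = s_short * np.exp(-acq.te2 / t2s_blood)

    fat_series = fat
    return PhantomTruth(
        water_series=water,
        fat_series=fat_series,
        concentration_maps=conc,
        motion_trace=trace,
        mbf_map=mbf_map,
        masks=labels,
        rv_insertion=rv_insertion,
        aif_true=lv_aif,
        water_static=water_static,
        fat_static=np.repeat(fat_static_img[..., None], config.n_frames, axis=2),
        region_curves={"rv": rv_curve, "lv": lv_aif.concentration,
                       "myo": myo_curve, "defect": defect_curve},
        aif_low_echo1=aif_e1,
        aif_low_echo2=aif_e2,
        t2star_blood=t2s_blood,
        frame_times=times,
    )


def _kin_params(kin):
    from .containers import KineticParams

    return KineticParams(Fp=kin.Fp, PS=kin.PS, vp=kin.vp, ve=kin.ve,
                         delay=kin.delay)


def _t2star_ms(acq: AcquisitionParams, conc) -> np.ndarray:
    """Concentration-dependent T2* in ms, clipped at a small floor."""
    r2s = 1000.0 / acq.t2star_0 + acq.r2star_relaxivity * np.asarray(conc)  # s^-1
    t2s = 1000.0 / r2s
    if np.any(t2s < T2STAR_FLOOR_MS):
        log.warning("T2* clipped at %.2f ms floor", T2STAR_FLOOR_MS)
    return np.maximum(t2s, T2STAR_FLOOR_MS)


def simulate_dual_echo(truth: PhantomTruth, acq: AcquisitionParams,
                       config: PhantomConfig | None = None) -> DynamicImageSeries:
    """Complex dual-echo signal formation from water/fat/concentration truth.

    S(TE) = (W + F exp(i 2 pi df_fat TE)) exp(-TE / T2*(C)) with the
    single-peak fat offset scaled by field strength and
    1/T2*(C) = 1/T2*_0 + r2* C.
    """
    water = truth.water_series
    fat = truth.fat_series
    conc = truth.concentration_maps
    if water.shape != fat.shape or water.shape != conc.shape:
        raise ValueError("truth series shapes are inconsistent")
    df = acq.fat_offset_hz
    t2s = _t2star_ms(acq, conc)  # (y, x, frame), ms
    out = np.empty(water.shape + (2,), dtype=complex)
    for e, te in enumerate((acq.te1, acq.te2)):
        fat_phasor = np.exp(2j * np.pi * df * te * 1e-3)
        out[..., e] = (water + fat * fat_phasor) * np.exp(-te / t2s)
    times = truth.frame_times
    return DynamicImageSeries(data=out, frame_times=times)


def make_coil_maps(ny: int, nx: int, n_coils: int, seed: int = 0) -> np.ndarray:
    """Smooth Gaussian coil sensitivities around the FOV, RSS-normalized.

    The root-sum-of-squares magnitude is 1 at every pixel so the SENSE
    adjoint is a proper left inverse on fully sampled data.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    maps = np.empty((n_coils, ny, nx), dtype=complex)
    radius = 0.6 * max(ny, nx)
    width = 0.6 * max(ny, nx)
    for j in range(n_coils):
        th = 2 * np.pi * j / n_coils + rng.uniform(-0.1, 0.1)
        cy = ny / 2 + radius * np.sin(th)
        cx = nx / 2 + radius * np.cos(th)
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * width**2))
        phase = 2 * np.pi * (rng.uniform(-0.5, 0.5) * xx / nx
                             + rng.uniform(-0.5, 0.5) * yy / ny) * 0.2
        maps[j] = mag * np.exp(1j * phase)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return maps / rss[None]


def acquire_kt(
    echo_series: DynamicImageSeries,
    coil_maps: np.ndarray,
    pattern: SamplingPattern,
    snr: float,
    acq: AcquisitionParams,
    seed: int = 0,
) -> KTData:
    """Encode the dual-echo series into noisy undersampled multi-coil k-space.

    k = M o F(c_j x) + n with complex white Gaussian noise of standard
    deviation peak|x| / snr on the sampled locations only.
    """
    x = echo_series.data
    if x.ndim == 3:
        x = x[..., None]
    ny, nx, nt, ne = x.shape
    if pattern.mask.shape != (ny, nx, nt):
        raise ValueError("sampling pattern shape does not match the series")
    if coil_maps.shape[1:] != (ny, nx):
        raise ValueError("coil map shape does not match the series")
    nc = coil_maps.shape[0]
    k = fft2c(coil_maps[:, :, :, None, None] * x[None], axes=(1, 2))
    rng = np.random.default_rng(seed)
    sigma = np.abs(x).max() / snr
    noise = sigma / np.sqrt(2) * (
        rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape))
    m = pattern.mask[None, :, :, :, None]
    samples = m * (k + noise)
    return KTData(samples=samples, mask=pattern, coil_maps=coil_maps, acq=acq,
                  frame_times=echo_series.frame_times)


def simulate_acquisition(config: PhantomConfig, pattern: SamplingPattern):
    """Full phantom acquisition: truth, coil maps and noisy k-t data.

    The low-resolution short-TS AIF image is simulated on a coarser grid
    (treated as fully sampled) and its noisy per-frame LV signals are
    attached to the returned KTData.
    """
    truth = render_truth(config)
    echoes = simulate_dual_echo(truth, config.acquisition, config)
    maps = make_coil_maps(*config.grid_size, config.n_coils, seed=config.seed + 1)
    kt = acquire_kt(echoes, maps, pattern, config.snr, config.acquisition,
                    seed=config.seed)
    kt.aif_images = _simulate_aif_images(config, truth)
    return truth, kt


def _simulate_aif_images(config: PhantomConfig, truth: PhantomTruth) -> np.ndarray:
    """Noisy low-resolution dual-echo AIF image series (y, x, frame, echo)."""
    acq = config.acquisition
    ny, nx = config.grid_size
    f = config.aif_downsample
    labels = truth.masks
    t2s = _t2star_ms(acq, truth.concentration_maps)
    # short-TS water signal over the full grid
    conc = truth.concentration_maps
    m0 = np.zeros((ny, nx))
    m0[(labels == PhantomTruth.LABEL_RV) | (labels == PhantomTruth.LABEL_LV)] = config.m0_blood
    m0[labels == PhantomTruth.LABEL_MYO] = config.m0_myo
    t10 = np.full((ny, nx), acq.t1_myo_0)
    blood = (labels == PhantomTruth.LABEL_RV) | (labels == PhantomTruth.LABEL_LV)
    t10[blood] = acq.t1_blood_0
    r1tot = 1.0 / (t10[..., None] / 1000.0) + acq.r1_relaxivity * conc
    s_short = m0[..., None] * (1.0 - np.exp(-(acq.ts_short / 1000.0) * r1tot))
    fat_sat_short = 1.0 - np.exp(-(acq.ts_short / 1000.0) / (config.t1_fat / 1000.0))
    fat_long = truth.fat_static[..., 0]
    fat_sat_long = 1.0 - np.exp(-(acq.ts_long / 1000.0) / (config.t1_fat / 1000.0))
    fat_short = fat_long / fat_sat_long * fat_sat_short
    df = acq.fat_offset_hz
    rng = np.random.default_rng(config.seed + 2)
    out = np.empty((ny // f, nx // f, config.n_frames, 2), dtype=complex)
    trace = truth.motion_trace
    for e, te in enumerate((acq.te1, acq.te2)):
        fat_phasor = np.exp(2j * np.pi * df * te * 1e-3)
        s = (s_short + fat_short[..., None] * fat_phasor) * np.exp(-te / t2s)
        for fi in range(config.n_frames):
            frame = shift_image(s[..., fi], trace.dy[fi], trace.dx[fi])
            low = frame.reshape(ny // f, f, nx // f, f).mean(axis=(1, 3))
            out[..., fi, e] = low
    sigma = np.abs(out).max() / config.snr
    out += sigma / np.sqrt(2) * (rng.standard_normal(out.shape)
                                 + 1j * rng.standard_normal(out.shape))
    return out
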