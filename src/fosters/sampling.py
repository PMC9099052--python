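"""Dynamically variable Cartesian k-t undersampling patterns.

The acquisition is 2D Cartesian with frequency encoding along kx, so
acceleration is realized by selecting a subset of ky lines per time frame.
Line density decreases from the k-space center outward as
(1 - |ky|/ky_max)^p, the central calibration region is fully sampled in
every frame, and the pseudo-random selection is varied frame to frame
(k-t sampling) so that aliasing stays incoherent in space-time.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import SamplingPattern


def generate_kt_mask(
    ny: int,
    nx: int,
    n_frames: int,
    R: float,
    center_fraction: float = 0.04,
    seed: int = 0,
    density_power: float = 2.0,
) -> SamplingPattern:
    """Variable-density pseudo-random ky line selection, distinct per frame.

    The per-frame number of sampled lines is forced to ``round(ny / R)``.
    Each frame draws from an independent substream of ``seed`` so patterns
    differ across frames but the whole mask is reproducible.
    """
    if R < 1:
        raise ValueError("acceleration R must be >= 1")
    if R > ny:
        raise ValueError(f"R={R} exceeds the number of ky lines ({ny})")

    n_lines = int(round(ny / R))
    n_lines = max(n_lines, 1)
    ky = np.arange(ny) - ny // 2
    n_center = int(round(center_fraction * ny))
    center = np.abs(ky) <= (n_center - 1) / 2 if n_center > 0 else np.zeros(ny, bool)
    if center.sum() > n_lines:
        warnings.warn(
            "fully sampled center exceeds the per-frame line budget; "
            "center lines are kept and the budget is raised",
            stacklevel=2,
        )
        n_lines = int(center.sum())

    ky_max = max(np.abs(ky).max(), 1)
    density = (1.0 - np.abs(ky) / (ky_max + 1)) ** density_power
    density[center] = 0.0

    mask = np.zeros((ny, nx, n_frames), dtype=np.uint8)
    streams = np.random.SeedSequence(seed).spawn(n_frames)
    outer = np.flatnonzero(~center)
    for t in range(n_frames):
        rng = np.random.default_rng(streams[t])
        lines = np.flatnonzero(center).tolist()
        n_extra = n_lines - len(lines)
        if n_extra > 0:
            p = density[outer] / density[outer].sum()
            extra = rng.choice(outer, size=n_extra, replace=False, p=p)
            lines.extend(extra.tolist())
        mask[np.asarray(lines, dtype=int), :, t] = 1

    return SamplingPattern(mask=mask, accel_requested=float(R),
                           center_fraction=center_fraction, seed=seed)


def realized_acceleration(pattern: SamplingPattern) -> float:
    """Actual undersampling factor: total k-space entries / sampled entries."""
    m = pattern.mask
    sampled = int(m.sum())
    if sampled == 0:
        raise ValueError("mask is empty; acceleration undefined")
    return m.size / sampled
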