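"""Image-quality metrics: edge sharpness and reconstruction error."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def sharpness(profile) -> float:
    """Edge sharpness of a 1D intensity profile, in pixels.

    Distance between the (linearly interpolated) positions where the
    profile crosses 20% and 80% of its intensity range, measured on the
    monotone run containing the steepest gradient.  Lower is sharper.
    Invariant to positive affine rescaling of the intensities.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 3:
        raise ValueError("profile must have at least 3 samples")
    rng = p.max() - p.min()
    if rng == 0:
        raise ValueError("constant profile: sharpness undefined")
    lo = p.min() + 0.2 * rng
    hi = p.min() + 0.8 * rng

    d = np.diff(p)
    k = int(np.argmax(np.abs(d)))
    sign = np.sign(d[k])
    # expand to the monotone run containing the steepest step
    a = k
    while a > 0 and sign * d[a - 1] > 0:
        a -= 1
    b = k + 1
    while b < len(d) and sign * d[b] > 0:
        b += 1
    seg = p[a : b + 1]
    pos = np.arange(a, b + 1, dtype=float)
    if sign < 0:
        seg = seg[::-1]
        pos = pos[::-1]

    def crossing(level):
        idx = np.flatnonzero(np.diff(seg >= level))
        if idx.size == 0:
            # level outside the run's range: clamp to its nearer end
            return pos[0] if seg[0] >= level else pos[-1]
        i = int(idx[0])
        frac = (level - seg[i]) / (seg[i + 1] - seg[i])
        return pos[i] + frac * (pos[i + 1] - pos[i])

    return float(abs(crossing(hi) - crossing(lo)))


def profile_along_line(image: np.ndarray, start, end, n_samples: int = 50):
    """Sample an intensity profile along a line segment (row, col) -> (row, col)."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = np.linspace(0, 1, n_samples)
    coords = start[:, None] * (1 - t) + end[:, None] * t
    return ndimage.map_coordinates(np.abs(image), coords, order=1)


def nrmse(estimate: np.ndarray, truth: np.ndarray, mask=None) -> float:
    """Root-mean-square error normalized by the peak of the truth."""
    est = np.abs(np.asarray(estimate))
    tru = np.abs(np.asarray(truth))
    if mask is not None:
        est = est[mask]
        tru = tru[mask]
    peak = tru.max()
    if peak == 0:
        raise ValueError("truth is identically zero")
    return float(np.sqrt(np.mean((est - tru) ** 2)) / peak)
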