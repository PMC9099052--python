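"""Centered orthonormal 2D FFT helpers and sub-pixel image shifting."""

from __future__ import annotations

import numpy as np


def fft2c(x: np.ndarray, axes=(0, 1)) -> np.ndarray:
    """Centered orthonormal 2D FFT along ``axes``."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(k: np.ndarray, axes=(0, 1)) -> np.ndarray:
    """Centered orthonormal 2D inverse FFT along ``axes``."""
    return np.fft.ifftshift(
        np.fft.ifft2(np.fft.fftshift(k, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def freq_grids(ny: int, nx: int):
    """Centered spatial-frequency grids in cycles/pixel, shape (ny, nx)."""
    ky = np.fft.fftshift(np.fft.fftfreq(ny))[:, None]
    kx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :]
    return ky, kx


def shift_image(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Circularly shift an image by (dy, dx) pixels.

    Integer shifts use an exact roll; fractional shifts use the Fourier
    shift theorem (consistent with the k-space phase model used for motion
    correction).  Real input returns real output.
    """
    if float(dy).is_integer() and float(dx).is_integer():
        return np.roll(img, (int(dy), int(dx)), axis=(0, 1))
    ky, kx = freq_grids(img.shape[0], img.shape[1])
    phase = np.exp(-2j * np.pi * (ky * dy + kx * dx))
    extra = phase.reshape(phase.shape + (1,) * (img.ndim - 2))
    out = ifft2c(fft2c(img) * extra)
    return out.real if np.isrealobj(img) else out
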