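"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np  # noqa: F401  (annotations)

from .config import AcquisitionParams


@dataclass
class SamplingPattern:
    """Binary k-t sampling mask, shape (ny, nx, n_frames)."""

    mask: np.ndarray
    accel_requested: float
    center_fraction: float
    seed: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.mask = m.astype(np.uint8)


@dataclass
class DynamicImageSeries:
    """Complex dynamic image stack, shape (y, x, frame) or (y, x, frame, echo)."""

    data: np.ndarray
    pixel_spacing: float = 1.6  # mm
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isfinite(self.data).all():
            raise ValueError("image series contains non-finite values")
        if self.frame_times is None:
            self.frame_times = np.arange(self.data.shape[2], dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly ascending")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3] if self.data.ndim == 4 else 1


@dataclass
class KTData:
    """Undersampled multi-coil k-space samples with mask and coil maps.

    ``samples`` has shape (coil, ky, kx, frame, echo); zero where unsampled.
    """

    samples: np.ndarray
    mask: SamplingPattern
    coil_maps: np.ndarray  # (coil, y, x)
    acq: AcquisitionParams
    frame_times: Optional[np.ndarray] = None
    aif_images: Optional[np.ndarray] = None  # low-res AIF series (y, x, frame, echo)

    def __post_init__(self) -> None:
        if self.coil_maps.shape[0] < 1:
            raise ValueError("need at least one coil")
        if self.samples.shape[0] != self.coil_maps.shape[0]:
            raise ValueError("coil count mismatch between samples and maps")


@dataclass
class MotionTrace:
    """Per-frame in-plane translation in pixels.

    ``dx`` is left-right (columns), ``dy`` superior-inferior (rows).
    """

    dx: np.ndarray
    dy: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx and dy must have equal length")

    def __len__(self) -> int:
        return len(self.dx)

    def re_referenced(self, reference_frame: int) -> "MotionTrace":
        """Trace relative to a reference frame (zero shift there)."""
        return MotionTrace(
            self.dx - self.dx[reference_frame],
            self.dy - self.dy[reference_frame],
            reference_frame,
        )

    def negated(self) -> "MotionTrace":
        return MotionTrace(-self.dx, -self.dy, self.reference_frame)


@dataclass
class WaterFatPair:
    """Water- and fat-only magnitude series plus the B0 phasor field.

    ``water_complex``/``fat_complex`` retain the complex-valued solutions of
    the per-voxel separation; projecting them onto their temporal-mean phase
    (see :func:`fosters.dixon.coherent_magnitude`) gives signal estimates
    whose zero-mean complex noise/aliasing stays zero-mean instead of
    rectifying into a positive bias, which matters for kinetic modeling.
    """

    water: np.ndarray  # (y, x, frame)
    fat: np.ndarray
    fieldmap_phasor: np.ndarray  # (y, x) complex, unit modulus
    water_complex: Optional[np.ndarray] = None
    fat_complex: Optional[np.ndarray] = None


@dataclass
class AIFCurve:
    """Arterial input function: signal per echo and derived concentration."""

    times: np.ndarray
    concentration: Optional[np.ndarray] = None  # mM
    signal_echo1: Optional[np.ndarray] = None
    signal_echo2: Optional[np.ndarray] = None
    t2star: Optional[np.ndarray] = None  # ms per frame
    corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("AIF times must be strictly ascending")


@dataclass
class TissueCurve:
    """Time-resolved tissue concentration (or raw signal) of a pixel/segment."""

    times: np.ndarray
    concentration: np.ndarray
    label: Optional[str] = None


@dataclass
class KineticParams:
    """2CXM parameter estimates: Fp/PS in mL/min/g, vp/ve in mL/g, delay in s."""

    Fp: float
    PS: float
    vp: float
    ve: float
    delay: float = 0.0
    posterior_sd: dict = field(default_factory=dict)
    rhat: Optional[dict] = None
    converged: bool = True

    def __post_init__(self) -> None:
        if min(self.Fp, self.PS, self.vp, self.ve) < 0:
            raise ValueError("kinetic parameters must be nonnegative")


@dataclass
class MBFMap:
    """Pixel-wise myocardial blood flow with AHA segment summary."""

    mbf: np.ndarray  # mL/min/g, nan outside myo_mask
    uncertainty: np.ndarray
    myo_mask: np.ndarray
    segments: Optional[object] = None  # pandas DataFrame of segment means/sds
    n_failed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth of the digital phantom.

    ``water_series``/``fat_series`` carry the programmed motion;
    ``water_static``/``fat_static`` are the motion-free references.
    """

    water_series: np.ndarray  # (y, x, frame)
    fat_series: np.ndarray
    concentration_maps: np.ndarray  # mM, (y, x, frame), motion applied
    motion_trace: MotionTrace
    mbf_map: np.ndarray  # mL/min/g, 0 outside myocardium
    masks: np.ndarray  # labels: 0 bg, 1 RV, 2 LV, 3 myo, 4 fat
    rv_insertion: np.ndarray  # two (row, col) points
    aif_true: AIFCurve
    water_static: Optional[np.ndarray] = None
    fat_static: Optional[np.ndarray] = None
    region_curves: dict = field(default_factory=dict)  # mM per region name
    aif_low_echo1: Optional[np.ndarray] = None  # noiseless low-res LV signals
    aif_low_echo2: Optional[np.ndarray] = None
    t2star_blood: Optional[np.ndarray] = None  # ms per frame in LV blood
    frame_times: Optional[np.ndarray] = None

    LABEL_RV = 1
    LABEL_LV = 2
    LABEL_MYO = 3
    LABEL_FAT = 4
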