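"""File I/O: HDF5 k-space containers, NIfTI image series, CSV curves/traces.

The HDF5 schema is bespoke but ISMRMRD-inspired:

    /kspace   complex128 (coil, ky, kx, frame, echo)
    /mask     uint8      (ky, kx, frame)
    /coils    complex128 (coil, y, x)
    /aif      complex128 (y, x, frame, echo)   [optional]
    attrs     acquisition parameters, mask metadata, frame times

NIfTI carries magnitude images with pixel spacing in the affine; complex
series round-trip through HDF5.
"""

from __future__ import annotations

import dataclasses

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .config import AcquisitionParams
from .containers import (AIFCurve, DynamicImageSeries, KTData, MotionTrace,
                         SamplingPattern)


class SchemaError(KeyError):
    """A required dataset or attribute is missing from a container file."""


def save_kt(path, kt: KTData) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kspace", data=kt.samples)
        fh.create_dataset("mask", data=kt.mask.mask)
        fh.create_dataset("coils", data=kt.coil_maps)
        if kt.aif_images is not None:
            fh.create_dataset("aif", data=kt.aif_images)
        if kt.frame_times is not None:
            fh.create_dataset("frame_times", data=np.asarray(kt.frame_times))
        for k, v in dataclasses.asdict(kt.acq).items():
            fh.attrs[f"acq_{k}"] = v
        fh.attrs["accel_requested"] = kt.mask.accel_requested
        fh.attrs["center_fraction"] = kt.mask.center_fraction
        fh.attrs["mask_seed"] = kt.mask.seed


def load_kt(path) -> KTData:
    with h5py.File(path, "r") as fh:
        for name in ("kspace", "mask", "coils"):
            if name not in fh:
                raise SchemaError(f"k-t container is missing dataset /{name}")
        acq_kwargs = {k[4:]: v for k, v in fh.attrs.items() if k.startswith("acq_")}
        acq = AcquisitionParams(**{k: float(v) for k, v in acq_kwargs.items()})
        pattern = SamplingPattern(
            mask=fh["mask"][()],
            accel_requested=float(fh.attrs.get("accel_requested", 0.0)),
            center_fraction=float(fh.attrs.get("center_fraction", 0.0)),
            seed=int(fh.attrs.get("mask_seed", 0)),
        )
        return KTData(
            samples=fh["kspace"][()],
            mask=pattern,
            coil_maps=fh["coils"][()],
            acq=acq,
            frame_times=fh["frame_times"][()] if "frame_times" in fh else None,
            aif_images=fh["aif"][()] if "aif" in fh else None,
        )


def save_series_nifti(path, series: DynamicImageSeries) -> None:
    """Write the magnitude of a dynamic series as a NIfTI volume (y, x, t)."""
    mag = np.abs(np.asarray(series.data))
    affine = np.diag([series.pixel_spacing, series.pixel_spacing, 1.0, 1.0])
    img = nib.Nifti1Image(mag.astype(np.float64), affine)
    dt = (np.diff(series.frame_times).mean() if len(series.frame_times) > 1 else 1.0)
    img.header["pixdim"][4] = dt
    nib.save(img, str(path))


def load_series_nifti(path) -> DynamicImageSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = float(img.affine[0, 0])
    dt = float(img.header["pixdim"][4]) or 1.0
    times = np.arange(data.shape[2]) * dt
    return DynamicImageSeries(data=data, pixel_spacing=abs(spacing),
                              frame_times=times)


def save_series_h5(path, series: DynamicImageSeries) -> None:
    """Lossless (complex) dynamic-series container."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=np.asarray(series.data, dtype=complex))
        fh.create_dataset("frame_times", data=series.frame_times)
        fh.attrs["pixel_spacing"] = series.pixel_spacing


def load_series_h5(path) -> DynamicImageSeries:
    with h5py.File(path, "r") as fh:
        if "data" not in fh:
            raise SchemaError("series container is missing dataset /data")
        return DynamicImageSeries(
            data=fh["data"][()],
            pixel_spacing=float(fh.attrs["pixel_spacing"]),
            frame_times=fh["frame_times"][()],
        )


def save_trace_csv(path, trace: MotionTrace) -> None:
    pd.DataFrame({
        "frame": np.arange(len(trace)),
        "dx": trace.dx,
        "dy": trace.dy,
    }).to_csv(path, index=False)


def load_trace_csv(path, reference_frame: int = 0) -> MotionTrace:
    df = pd.read_csv(path)
    for col in ("dx", "dy"):
        if col not in df:
            raise SchemaError(f"trace file is missing column {col!r}")
    return MotionTrace(dx=df["dx"].to_numpy(), dy=df["dy"].to_numpy(),
                       reference_frame=reference_frame)


def save_curve_csv(path, curve: AIFCurve) -> None:
    cols = {"time": curve.times}
    if curve.concentration is not None:
        cols["concentration"] = curve.concentration
    if curve.signal_echo1 is not None:
        cols["signal_echo1"] = curve.signal_echo1
    if curve.signal_echo2 is not None:
        cols["signal_echo2"] = curve.signal_echo2
    pd.DataFrame(cols).to_csv(path, index=False)


def load_curve_csv(path) -> AIFCurve:
    df = pd.read_csv(path)
    if "time" not in df:
        raise SchemaError("curve file is missing column 'time'")
    return AIFCurve(
        times=df["time"].to_numpy(),
        concentration=df["concentration"].to_numpy() if "concentration" in df else None,
        signal_echo1=df["signal_echo1"].to_numpy() if "signal_echo1" in df else None,
        signal_echo2=df["signal_echo2"].to_numpy() if "signal_echo2" in df else None,
    )


def save_map_nifti(path, arr: np.ndarray, pixel_spacing: float = 1.6) -> None:
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), str(path))
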