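"""Readers and writers for volumes, masks, curves and shape matrices.

DICOM series are read through pydicom with the rescale slope/intercept
applied so voxels are in Hounsfield units; mask stacks come from per-slice
PNG/TIFF images; ``.npz`` serves as the plain array-container format for
fixtures and intermediate artifacts.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .preprocess import CTVolume, ROIMask


def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Load a directory of single-frame CT DICOM files as one HU volume.

    Slices are ordered by ImagePositionPatient z (falling back to
    InstanceNumber); HU = stored * RescaleSlope + RescaleIntercept.
    """
    import pydicom

    paths = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
    datasets = []
    for p in paths:
        if p.is_file():
            try:
                datasets.append(pydicom.dcmread(str(p)))
            except Exception:
                continue
    if not datasets:
        raise FileNotFoundError(f"no readable DICOM files in {directory}")

    def z_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_key)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    vol = np.stack(slices, axis=0)
    ds0 = datasets[0]
    py, px = (float(v) for v in getattr(ds0, "PixelSpacing", (1.0, 1.0)))
    if len(datasets) > 1 and hasattr(ds0, "ImagePositionPatient"):
        dz = abs(z_key(datasets[1]) - z_key(datasets[0])) or 1.0
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    return CTVolume(voxels=vol, spacing=(dz, py, px))


def read_mask_stack(directory: str | os.PathLike) -> list[ROIMask]:
    """Load per-slice binary masks from PNG/TIFF files, sorted by filename."""
    import imageio.v3 as iio

    paths = sorted(
        p
        for p in Path(directory).iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    masks = []
    for k, p in enumerate(paths):
        img = np.asarray(iio.imread(str(p)))
        if img.ndim == 3:  # collapse color channels
            img = img.max(axis=-1)
        masks.append(ROIMask(pixels=img > 0, slice_index=k))
    return masks


def read_volume_npz(path: str | os.PathLike) -> CTVolume:
    """Load a CTVolume from the array-container format (``.npz``)."""
    with np.load(path) as f:
        return CTVolume(voxels=f["voxels"], spacing=tuple(f["spacing"]))


def write_volume_npz(path: str | os.PathLike, volume: CTVolume) -> None:
    np.savez(path, voxels=volume.voxels, spacing=np.asarray(volume.spacing))


def write_curves_csv(path: str | os.PathLike, curves) -> None:
    """Write boundary curves as CSV rows (slice_index, vertex_order, row, col)."""
    import pandas as pd

    rows = []
    for curve in curves:
        for order, (r, c) in enumerate(curve.points):
            rows.append((curve.slice_index, order, r, c))
    pd.DataFrame(
        rows, columns=["slice_index", "vertex_order", "row", "col"]
    ).to_csv(path, index=False)


def write_matrix_csv(path: str | os.PathLike, matrix: np.ndarray) -> None:
    """Write a shape matrix as CSV, one row per slice."""
    np.savetxt(path, np.asarray(matrix), delimiter=",", fmt="%.9g")
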