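"""CT intensity windowing, binarization, ROI extraction and nodule-box cropping.

The classification pipeline starts from a CT volume in Hounsfield units (HU).
A lung window maps an HU interval to displayable grayscale, slices are
binarized, connected components become regions of interest (ROIs), and a
fixed-size grayscale box centered on each annotated nodule is cut out as the
unit of classification.

Conventions used throughout the package: 0-based indices, ``(z, y, x)`` axis
order, pixel-center coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass
class CTVolume:
    """A CT scan: HU voxels (slices x rows x cols) plus voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # (z, y, x) mm

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("CTVolume.voxels must be 3D with at least 1 slice")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing values must be > 0")


@dataclass(frozen=True)
class WindowSpec:
    """CT display window: ``width`` HU centered on ``level`` HU.

    Defaults follow the standard lung window (width 1600, level -600).
    """

    width: float = 1600.0
    level: float = -600.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")


@dataclass
class ROIMask:
    """One connected region on one slice, as a boolean pixel mask."""

    pixels: np.ndarray
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("ROIMask.pixels must be 2D")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class NoduleBox:
    """Fixed-size grayscale subvolume centered on a nodule.

    ``gray`` holds values in [0, 255]; ``pad`` records how many zero-padded
    voxels were added on the (low, high) side of each axis when the box ran
    past the source volume.
    """

    gray: np.ndarray
    spacing: tuple[float, float, float]
    label: str | None = None  # "benign" | "malignant"
    center_voxel: tuple[int, int, int] = (0, 0, 0)
    pad: tuple[tuple[int, int], ...] = field(
        default=((0, 0), (0, 0), (0, 0))
    )

    def __post_init__(self) -> None:
        self.gray = np.asarray(self.gray)
        if self.gray.ndim != 3:
            raise ValueError("NoduleBox.gray must be 3D")
        if self.gray.size and (self.gray.min() < 0 or self.gray.max() > 255):
            raise ValueError("NoduleBox.gray values must lie in [0, 255]")


def window_hu(volume: CTVolume, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Map HU values to grayscale [0, 255] through a window/level transform.

    Values at or below ``level - width/2`` map to 0, values at or above
    ``level + width/2`` map to 255, with a linear ramp in between.  Output is
    real-valued (quantization to integers happens only at export).
    """
    hu = np.asarray(volume.voxels, dtype=np.float64)
    bad = ~np.isfinite(hu)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite HU value at voxel index {idx}")
    lo = spec.level - spec.width / 2.0
    gray = (hu - lo) * (255.0 / spec.width)
    return np.clip(gray, 0.0, 255.0)


def binarize(gray_slice: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold a grayscale slice: pixel true iff gray >= threshold.

    With ``threshold=None`` Otsu's method is applied to the slice, a
    parameter-free default suited to the bimodal histograms produced by lung
    windowing.
    """
    gray_slice = np.asarray(gray_slice)
    if threshold is None:
        if np.ptp(gray_slice) == 0:  # constant slice: Otsu undefined
            return np.zeros_like(gray_slice, dtype=bool)
        threshold = threshold_otsu(gray_slice)
    return gray_slice >= threshold


# 8-connectivity in 2D
_STRUCT8 = np.ones((3, 3), dtype=bool)


def extract_rois(
    mask: np.ndarray, min_area: int = 9, slice_index: int = 0
) -> list[ROIMask]:
    """Split a binary mask into 8-connected components of area >= min_area.

    Components are returned largest-first; an empty mask yields an empty list.
    The default ``min_area`` of 9 pixels filters speckle below the 3 mm nodule
    threshold at ~1 mm in-plane spacing.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    rois: list[ROIMask] = []
    for lab in range(1, n + 1):
        pix = labels == lab
        if pix.sum() >= min_area:
            rois.append(ROIMask(pixels=pix, slice_index=slice_index))
    rois.sort(key=lambda r: r.area, reverse=True)
    return rois


def roi_centroid(roi: ROIMask) -> tuple[float, float]:
    """Unweighted center of gravity of the ROI's true pixels, as (row, col)."""
    coords = np.argwhere(roi.pixels)
    if coords.size == 0:
        raise ValueError("cannot compute centroid of an empty ROI")
    r, c = coords.mean(axis=0)
    return float(r), float(c)


def crop_box(
    volume_gray: np.ndarray,
    center: tuple[int, int, int],
    size: int = 32,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    label: str | None = None,
) -> NoduleBox:
    """Cut a ``size``³ grayscale box around ``center``, zero-padding outside.

    The box spans the half-open interval [c - size//2, c - size//2 + size)
    per axis (floor-centered); padding amounts are recorded in the result.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    vol = np.asarray(volume_gray)
    if vol.ndim != 3:
        raise ValueError("volume_gray must be 3D")
    for ax, c in enumerate(center):
        if not (0 <= c < vol.shape[ax]):
            raise ValueError(
                f"center {tuple(center)} lies outside the volume on axis {ax}"
            )
    starts = [int(c) - size // 2 for c in center]
    box = np.zeros((size, size, size), dtype=vol.dtype)
    pad: list[tuple[int, int]] = []
    src, dst = [], []
    for ax, s in enumerate(starts):
        lo = max(s, 0)
        hi = min(s + size, vol.shape[ax])
        src.append(slice(lo, hi))
        dst.append(slice(lo - s, hi - s))
        pad.append((lo - s, s + size - hi))
    box[tuple(dst)] = vol[tuple(src)]
    return NoduleBox(
        gray=box,
        spacing=spacing,
        label=label,
        center_voxel=tuple(int(c) for c in center),
        pad=tuple(pad),
    )


def filter_nodules(annotations: list) -> list:
    """Apply the inclusion criteria for malignancy classification.

    Keeps solid nodules with diameter in [3, 30] mm and malignancy grade in
    {1, 2, 4, 5}; grade 3 (indeterminate) is excluded.  Grades 1-2 are labeled
    benign, 4-5 malignant (the annotation's ``label`` attribute is set).
    """
    kept = []
    for ann in annotations:
        grade = ann.malignancy_grade
        if not (1 <= grade <= 5):
            raise ValueError(f"malignancy grade {grade} outside 1-5")
        if grade == 3:
            continue
        if not ann.solid:
            continue
        if not (3.0 <= ann.diameter_mm <= 30.0):
            continue
        ann.label = "benign" if grade <= 2 else "malignant"
        kept.append(ann)
    return kept
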