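"""Radial scanning: pole-to-boundary distance series and shape matrices.

Each slice's closed boundary curve is scanned by rays cast from a pole (the
ROI centroid) at regular angular increments; the distance to the boundary at
each angle forms a series, and stacking the per-slice series of a nodule box
gives the slices x angles shape matrix that encodes boundary geometry.

Angle convention: theta is measured counter-clockwise from the +x (column)
axis, with y = -row so the convention is right-handed in image coordinates.
The ray at angle theta has direction (drow, dcol) = (-sin theta, cos theta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boundary import BoundaryCurve


def count_angles(angle_increment: float) -> int:
    """Number of samples in a full-circle scan at the given increment.

    A 2 degree increment gives 180 samples per slice; the default 11.25
    degrees gives 32, matching the 32x32 shape matrix.
    """
    if angle_increment <= 0:
        raise ValueError("angle_increment must be > 0")
    n = 360.0 / angle_increment
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{angle_increment} deg does not divide 360")
    return int(round(n))


@dataclass(frozen=True)
class RadialConfig:
    """Full-circle scan layout and normalization mode.

    ``n_angles * angle_increment`` must equal 360.  ``normalize`` applies to
    the stacked shape matrix: ``per_nodule_max`` divides the whole matrix by
    its maximum (preserving inter-slice size relations), ``per_slice_max``
    normalizes each row independently, ``none`` keeps pixel units.
    ``farthest_intersection`` controls which ray-boundary crossing is kept on
    non-star-shaped (spiculated) boundaries.
    """

    n_angles: int = 32
    normalize: str = "per_nodule_max"
    farthest_intersection: bool = True

    def __post_init__(self) -> None:
        if self.n_angles < 4:
            raise ValueError("n_angles must be >= 4")
        if self.normalize not in {"per_nodule_max", "per_slice_max", "none"}:
            raise ValueError(f"unknown normalization {self.normalize!r}")

    @property
    def angle_increment(self) -> float:
        return 360.0 / self.n_angles

    @classmethod
    def from_increment(cls, angle_increment: float, **kw) -> "RadialConfig":
        return cls(n_angles=count_angles(angle_increment), **kw)


@dataclass
class RadialSeries:
    """Pole-to-boundary distances at the scan angles, for one slice."""

    values: np.ndarray
    pole: tuple[float, float]
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be 1D")
        if np.any(self.values < 0):
            raise ValueError("radial distances must be >= 0")


def _point_in_polygon(p: np.ndarray, pts: np.ndarray) -> bool:
    """Even-odd rule on a horizontal ray from p (row, col coordinates)."""
    r, c = p
    a = pts
    b = np.roll(pts, -1, axis=0)
    crosses = (a[:, 0] > r) != (b[:, 0] > r)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at = a[:, 1] + (r - a[:, 0]) / (b[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    return bool(np.sum(crosses & (x_at > c)) % 2)


def radial_series(
    curve: BoundaryCurve,
    pole: tuple[float, float],
    cfg: RadialConfig = RadialConfig(),
) -> RadialSeries:
    """Scan a closed curve from ``pole`` at the configured angles.

    For each angle the ray from the pole is intersected exactly with every
    polygon edge (segment-parametric arithmetic); the farthest intersection
    distance is recorded (or the nearest, per config).  A ray with no
    intersection — the pole outside or on the curve — contributes 0 and a
    warning is raised once.
    """
    pts = curve.points
    n = len(pts)
    pole_arr = np.asarray(pole, dtype=np.float64)
    if not _point_in_polygon(pole_arr, pts):
        warnings.warn(
            "radial scan: pole lies outside the boundary curve; "
            "zero series recorded",
            RuntimeWarning,
            stacklevel=2,
        )
        return RadialSeries(
            values=np.zeros(cfg.n_angles),
            pole=(float(pole_arr[0]), float(pole_arr[1])),
            slice_index=curve.slice_index,
        )
    a = pts  # edge starts
    b = np.roll(pts, -1, axis=0)  # edge ends

    # edge vectors in (x, y) = (col, -row) coordinates
    ex = b[:, 1] - a[:, 1]
    ey = -(b[:, 0] - a[:, 0])
    px = a[:, 1] - pole_arr[1]
    py = -(a[:, 0] - pole_arr[0])

    k = np.arange(cfg.n_angles)
    theta = np.deg2rad(k * cfg.angle_increment)
    dx = np.cos(theta)
    dy = np.sin(theta)

    values = np.zeros(cfg.n_angles)
    missed = False
    for i in range(cfg.n_angles):
        # solve pole + t*d = a + s*(b - a) by Cramer:  t >= 0, s in [0, 1)
        denom = dx[i] * ey - dy[i] * ex
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (dy[i] * px - dx[i] * py) / denom
            t = (px * ey - ex * py) / denom
        ok = (np.abs(denom) > 1e-15) & (s >= 0.0) & (s < 1.0) & (t >= 0.0)
        if not np.any(ok):
            missed = True
            continue
        hits = t[ok]
        values[i] = hits.max() if cfg.farthest_intersection else hits.min()
    if missed:
        warnings.warn(
            "radial scan: some rays did not hit the boundary "
            "(pole outside or on the curve); zeros recorded",
            RuntimeWarning,
            stacklevel=2,
        )
    return RadialSeries(
        values=values, pole=(float(pole_arr[0]), float(pole_arr[1])),
        slice_index=curve.slice_index,
    )


@dataclass
class ShapeMatrix:
    """slices x angles matrix of stacked radial series for one nodule box."""

    matrix: np.ndarray
    normalize: str = "per_nodule_max"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("shape matrix must be 2D")
        if np.any(self.matrix < 0):
            raise ValueError("shape matrix entries must be >= 0")


def build_shape_matrix(
    box_curves: list[tuple[int, BoundaryCurve | None]],
    poles: dict[int, tuple[float, float]],
    cfg: RadialConfig = RadialConfig(),
    n_slices: int | None = None,
) -> ShapeMatrix:
    """Stack per-slice radial series into the nodule's shape matrix.

    ``box_curves`` pairs each slice index with its boundary curve (or None
    for slices without a ROI, which become zero rows).  After stacking the
    configured normalization is applied; an all-empty box yields an all-zero
    matrix with a warning.
    """
    indices = [k for k, _ in box_curves]
    if n_slices is None:
        n_slices = max(indices) + 1 if indices else 0
    mat = np.zeros((n_slices, cfg.n_angles))
    any_curve = False
    for k, curve in box_curves:
        if curve is None:
            continue
        any_curve = True
        mat[k] = radial_series(curve, poles[k], cfg).values
    if not any_curve:
        warnings.warn("all slices empty: zero shape matrix", RuntimeWarning,
                      stacklevel=2)
    if cfg.normalize == "per_nodule_max":
        m = mat.max()
        if m > 0:
            mat = mat / m
    elif cfg.normalize == "per_slice_max":
        row_max = mat.max(axis=1, keepdims=True)
        np.divide(mat, row_max, out=mat, where=row_max > 0)
    return ShapeMatrix(matrix=mat, normalize=cfg.normalize)
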