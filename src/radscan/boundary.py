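"""Closed boundary curves of ROIs and their polygonal simplification.

Each nodule cross-section is represented by the ordered closed polygon of its
outer boundary pixels.  Two sources are offered: Moore-neighbor tracing of the
binarized ROI (the default — it guarantees a closed simple curve) and Canny
edge detection on the grayscale slice.  Curves can then be reduced with the
Douglas-Peucker (DP) procedure, extended to closed curves by anchoring the
recursion at the vertex farthest from the region center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import feature

from .preprocess import ROIMask


@dataclass
class BoundaryCurve:
    """Ordered closed polygon of (row, col) boundary points for one slice.

    The curve is implicitly closed: the last point connects back to the
    first.  Orientation is counter-clockwise under the package convention
    (x = col rightward, y = row downward, angles counter-clockwise from +x).
    """

    points: np.ndarray
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (row, col)")
        if len(self.points) < 3:
            raise ValueError("a closed boundary curve needs at least 3 points")
        deltas = np.diff(self.points, axis=0)
        if np.any(np.all(deltas == 0, axis=1)):
            raise ValueError("consecutive boundary points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise orientation."""
        r = self.points[:, 0]
        c = self.points[:, 1]
        # x = col, y = -row so that CCW-from-+x matches the angle convention
        x, y = c, -r
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


@dataclass(frozen=True)
class SimplifyConfig:
    """DP tolerance epsilon, in pixels."""

    tolerance: float = 0.8

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class CannyConfig:
    gaussian_sigma: float = 1.0
    low_threshold: float = 0.1
    high_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold < self.high_threshold <= 1):
            raise ValueError("need 0 < low_threshold < high_threshold <= 1")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")


def canny_edges(gray_slice: np.ndarray, cfg: CannyConfig = CannyConfig()) -> np.ndarray:
    """Canny edge map: Gaussian smoothing, gradient, non-maximum suppression
    and hysteresis thresholding, yielding 1-pixel-wide contours."""
    gray_slice = np.asarray(gray_slice, dtype=np.float64)
    if gray_slice.shape[0] < 3 or gray_slice.shape[1] < 3:
        raise ValueError("slice must be at least 3x3")
    return feature.canny(
        gray_slice,
        sigma=cfg.gaussian_sigma,
        low_threshold=cfg.low_threshold,
        high_threshold=cfg.high_threshold,
        use_quantiles=False,
    )


# Moore neighborhood in clockwise order starting from west, as
# (drow, dcol) offsets.
_MOORE = [
    (0, -1), (-1, -1), (-1, 0), (-1, 1),
    (0, 1), (1, 1), (1, 0), (1, -1),
]


def trace_boundary(roi: ROIMask) -> BoundaryCurve:
    """Trace the ROI's outer contour over boundary pixel centers.

    Moore-neighbor tracing with Jacob's stopping criterion, started at the
    topmost-leftmost region pixel; holes are ignored.  The returned polygon is
    counter-clockwise.  Regions whose boundary encloses no area (single rows,
    columns, or fewer than 3 boundary pixels) are degenerate and rejected.
    """
    mask = np.asarray(roi.pixels, dtype=bool)
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("empty ROI")
    padded = np.pad(mask, 1)
    start = tuple(coords[0] + 1)  # raster order: topmost, then leftmost

    def trace(p, b):
        """From pixel p with backtrack (background) neighbor b, find the next
        boundary pixel clockwise and its backtrack."""
        off = (b[0] - p[0], b[1] - p[1])
        k0 = _MOORE.index(off)
        for i in range(1, 9):
            dr, dc = _MOORE[(k0 + i) % 8]
            q = (p[0] + dr, p[1] + dc)
            if padded[q]:
                prev = _MOORE[(k0 + i - 1) % 8]
                return q, (p[0] + prev[0], p[1] + prev[1])
        return None, b  # isolated pixel

    points = [start]
    p, b = trace(start, (start[0], start[1] - 1))
    if p is None:
        raise ValueError("degenerate ROI: isolated pixel has no closed boundary")
    first_move = p
    points.append(p)
    guard = 8 * padded.size
    while guard:
        guard -= 1
        q, b = trace(p, b)
        if q == start:
            # Jacob's criterion: stop when re-entering the start the same way
            nxt, _ = trace(q, b)
            if nxt == first_move:
                break
            points.append(q)
            p = q
            continue
        points.append(q)
        p = q
    pts = np.asarray(points, dtype=np.float64) - 1.0  # undo padding offset
    # collapse immediate duplicates (can arise at the closing step)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]
    if len(pts) >= 2 and np.all(pts[0] == pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("degenerate ROI: fewer than 3 boundary points")
    curve = BoundaryCurve(points=pts, slice_index=roi.slice_index)
    if abs(curve.signed_area) < 1e-12:
        raise ValueError("degenerate ROI: boundary encloses no area")
    if curve.signed_area < 0:  # enforce counter-clockwise orientation
        curve = BoundaryCurve(points=pts[::-1], slice_index=roi.slice_index)
    return curve


def _point_segment_distances(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(pts - a, axis=1)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def dp_simplify_open(points: np.ndarray, tolerance: float) -> np.ndarray:
    """Douglas-Peucker simplification of an open polyline.

    Keeps a subset of the input vertices including both endpoints; every
    input point ends up within ``tolerance`` of the simplified polyline.
    Recursion splits at the vertex farthest from the current chord (ties
    break to the lowest index).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least 2 points")
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        d = _point_segment_distances(pts[i + 1 : j], pts[i], pts[j])
        k = int(np.argmax(d))  # argmax returns the lowest index on ties
        if d[k] > tolerance:
            m = i + 1 + k
            keep[m] = True
            stack.append((i, m))
            stack.append((m, j))
    return pts[keep]


def dp_simplify_closed(
    curve: BoundaryCurve,
    tolerance: float,
    center: tuple[float, float],
    geometric_second_anchor: bool = False,
) -> BoundaryCurve:
    """DP simplification of a closed curve.

    The recursion needs a starting split: anchor A is the vertex farthest
    from ``center`` (the ROI centroid), anchor B the vertex half the cyclic
    vertex count away from A (or, with ``geometric_second_anchor``, the
    vertex geometrically farthest from A).  The two arcs A->B and B->A are
    simplified independently and concatenated; every original vertex lies
    within ``tolerance`` of the result.
    """
    pts = curve.points
    n = len(pts)
    center_arr = np.asarray(center, dtype=np.float64)
    d_center = np.linalg.norm(pts - center_arr, axis=1)
    ia = int(np.argmax(d_center))  # ties -> lowest index
    rolled = np.roll(pts, -ia, axis=0)
    if geometric_second_anchor:
        ib = int(np.argmax(np.linalg.norm(rolled - rolled[0], axis=1)))
    else:
        ib = n // 2
    arc1 = dp_simplify_open(rolled[: ib + 1], tolerance)
    arc2 = dp_simplify_open(
        np.vstack([rolled[ib:], rolled[:1]]), tolerance
    )
    out = np.vstack([arc1[:-1], arc2[:-1]])  # drop duplicated anchors
    if len(out) < 3:
        # both arcs collapsed to their chords; keep the vertex farthest from
        # the A-B chord so the result remains a valid (>= 3 point) polygon
        d = _point_segment_distances(rolled, rolled[0], rolled[ib])
        k = int(np.argmax(d))
        if k < ib:
            out = np.vstack([rolled[0], rolled[k], rolled[ib]])
        else:
            out = np.vstack([rolled[0], rolled[ib], rolled[k]])
    return BoundaryCurve(points=out, slice_index=curve.slice_index)
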