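import numpy as np
import pytest

from radscan.boundary import BoundaryCurve


@pytest.fixture
def circle_curve():
    """Polygonal circle, radius 10, centered at (50, 50), 720 vertices CCW."""
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    pts = np.c_[50 - 10 * np.sin(th), 50 + 10 * np.cos(th)]
    return BoundaryCurve(points=pts)


@pytest.fixture
def ellipse_curve():
    """Axis-aligned ellipse, semi-axes a=4 (cols) and b=2 (rows), at (50, 50)."""
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    pts = np.c_[50 - 2 * np.sin(th), 50 + 4 * np.cos(th)]
    return BoundaryCurve(points=pts)


def polygon_circle(radius, center=(0.0, 0.0), n=360):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.c_[center[0] - radius * np.sin(th),
                 center[1] + radius * np.cos(th)]
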