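import numpy as np
import pytest

from scartstv.contour import ContourSlice


@pytest.fixture
def unit_square() -> ContourSlice:
    return ContourSlice(0.0, [(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def triangle() -> ContourSlice:
    return ContourSlice(0.0, [(0, 0), (3, 0), (0, 3)])


@pytest.fixture
def l_hexagon() -> ContourSlice:
    """L-shape = [0,2]x[0,1] plus [0,1]x[1,2]; centroid known by decomposition."""
    return ContourSlice(0.0, [(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])


@pytest.fixture
def pacman() -> ContourSlice:
    """Concave disc with a wedge notch cut toward +x; rays through the notch
    cross the boundary three times."""
    r = 25.0
    theta = np.linspace(np.deg2rad(30), np.deg2rad(330), 121)
    arc = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    verts = np.vstack([[[0.0, 0.0]], arc])  # mouth apex at the disc center
    return ContourSlice(0.0, verts)


def circle_slice(radius: float, z: float = 0.0, n: int = 360, center=(0.0, 0.0)) -> ContourSlice:
    t = np.arange(n) * (2 * np.pi / n)
    verts = np.stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)], axis=1)
    return ContourSlice(z, verts)


def regular_ngon_area(n: int, r: float) -> float:
    return 0.5 * n * r * r * np.sin(2 * np.pi / n)
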