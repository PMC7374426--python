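import numpy as np
import pytest

from anthromesh.shapes import make_cube, make_prism
from anthromesh.transforms import RigidTransform


@pytest.fixture
def cube15():
    """Side-15 cube, base at y=0 (centered on the y-axis)."""
    return make_cube(15.0)


@pytest.fixture
def cube50():
    return make_cube(50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rigid_transform(rng, t_scale=30.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return RigidTransform.from_axis_angle(axis, rng.uniform(0, np.pi),
                                          rng.uniform(-t_scale, t_scale, size=3))


def random_convex_prism(rng, n_min=5, n_max=12):
    """Convex prism from the hull of random 2D points, extruded in y."""
    while True:
        pts = rng.uniform(-20, 20, size=(rng.integers(n_min, n_max + 1), 2))
        hull = _convex_hull_ccw(pts)
        if len(hull) >= n_min:
            break
    height = float(rng.uniform(5, 20))
    return make_prism(hull, height), hull, height


def _convex_hull_ccw(points):
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    return points[hull.vertices]  # scipy returns CCW order in 2D


def polygon_area(poly):
    x, z = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(z, -1)) - np.dot(z, np.roll(x, -1)))


def polygon_perimeter(poly):
    return float(np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1).sum())
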