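import numpy as np
import pytest

from onhmorph.geometry import fit_tps
from onhmorph.types import BMOEllipse, Plane


@pytest.fixture
def xy_plane() -> Plane:
    return Plane(point=[0.0, 0.0, 0.0], unit_normal=[0.0, 0.0, 1.0])


@pytest.fixture
def circle_ellipse() -> BMOEllipse:
    return BMOEllipse(center=[0.0, 0.0], a=600.0, b=600.0, angle=0.0)


def grid_sites(extent: float, n: int) -> np.ndarray:
    """n×n grid of (u, v) sites covering [-extent, extent]²."""
    x = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(x, x)
    return np.column_stack([xx.ravel(), yy.ravel()])


def surface_from(plane: Plane, uv: np.ndarray, h: np.ndarray, lam: float = 0.0):
    """TPS through heights h at plane-coordinate sites uv."""
    pts = plane.from_plane_coords(np.column_stack([uv, h]))
    return fit_tps(pts, plane, lam=lam)


@pytest.fixture
def flat_surface(xy_plane):
    uv = grid_sites(900.0, 7)
    return surface_from(xy_plane, uv, np.zeros(len(uv)))
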