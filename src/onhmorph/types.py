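"""Domain containers for ONH / anterior lamina cribrosa morphometry.

Conventions used throughout the package:

* all lengths are in micrometres (μm) internally; radii of curvature are
  reported in millimetres at the interface,
* the coordinate frame is right handed with the axial (z) direction
  positive *posterior* (away from the vitreous, toward the lamina),
* indexing is 0-based everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "EllipseFitError",
    "BScanMarkup",
    "MarkedONH",
    "Plane",
    "BMOEllipse",
    "ONHParameters",
    "FLAT",
]

#: Sentinel returned for a radius of curvature beyond the flat threshold
#: (a perfectly flat surface has infinite radius).
FLAT = math.inf


class DegenerateGeometryError(ValueError):
    """Raised when a point configuration cannot support the requested fit."""


class EllipseFitError(ValueError):
    """Raised when the best-fit conic through the points is not an ellipse."""


def _as_points(points, dim: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != dim:
        raise ValueError(f"expected an (n, {dim}) array of points, got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


@dataclass
class BScanMarkup:
    """Manual markup of a single radial B-scan.

    Parameters
    ----------
    scan_angle_deg:
        Orientation of the radial scan in degrees (0 = nasal-temporal axis
        of the acquisition frame).
    bmo_points:
        0–2 termination points of the RPE/Bruch's membrane complex, 3D μm.
    alcs_points:
        Marked anterior lamina cribrosa surface points, 3D μm.
    ilm_polyline:
        Ordered internal-limiting-membrane polyline in the B-scan plane,
        ``(s, z)`` μm where ``s`` is the signed lateral position along the
        scan direction and ``z`` the axial position (positive posterior).
    """

    scan_angle_deg: float
    bmo_points: np.ndarray
    alcs_points: np.ndarray
    ilm_polyline: np.ndarray

    def __post_init__(self) -> None:
        self.bmo_points = _as_points(self.bmo_points, 3) if len(self.bmo_points) else np.empty((0, 3))
        self.alcs_points = _as_points(self.alcs_points, 3) if len(self.alcs_points) else np.empty((0, 3))
        self.ilm_polyline = _as_points(self.ilm_polyline, 2) if len(self.ilm_polyline) else np.empty((0, 2))
        if len(self.bmo_points) > 2:
            raise ValueError("a radial B-scan crosses the neural canal opening at most twice")


@dataclass
class MarkedONH:
    """One eye at one time-point: every marked B-scan plus scale factors."""

    eye_id: str
    day: int
    bscans: list[BScanMarkup]
    lateral_scale: float = 1.0  # μm per pixel of the source scan
    axial_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise ValueError("scale factors must be positive")

    @property
    def bmo_points(self) -> np.ndarray:
        """All BMO points across B-scans, (n, 3) μm."""
        pts = [b.bmo_points for b in self.bscans if len(b.bmo_points)]
        return np.vstack(pts) if pts else np.empty((0, 3))

    @property
    def alcs_points(self) -> np.ndarray:
        """All marked ALCS points across B-scans, (n, 3) μm."""
        pts = [b.alcs_points for b in self.bscans if len(b.alcs_points)]
        return np.vstack(pts) if pts else np.empty((0, 3))

    def validate(self) -> None:
        n_scans = sum(1 for b in self.bscans if len(b.bmo_points) >= 2)
        if n_scans < 3 or len(self.bmo_points) < 6:
            raise DegenerateGeometryError(
                "need >=3 B-scans with 2 BMO points each (>=6 total) for a plane fit"
            )


@dataclass
class Plane:
    """Reference plane through the BMO points.

    ``unit_normal`` is oriented so that +normal points posteriorly, toward
    the lamina; heights measured along it are therefore positive for a
    surface displaced away from the vitreous.
    """

    point: np.ndarray
    unit_normal: np.ndarray
    #: In-plane orthonormal basis (rows e1, e2); fixed at construction so
    #: plane coordinates are reproducible.
    basis: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.unit_normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("zero normal vector")
            n = n / norm
        self.unit_normal = n
        if self.basis is None:
            # deterministic in-plane basis: project global x (or y) onto the plane
            seed = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(seed, n)) > 0.9:
                seed = np.array([0.0, 1.0, 0.0])
            e1 = seed - np.dot(seed, n) * n
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(n, e1)
            self.basis = np.vstack([e1, e2])
        else:
            self.basis = np.asarray(self.basis, dtype=float).reshape(2, 3)

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        """Map 3D points to ``(u, v, h)``: in-plane coordinates plus height
        along the normal (positive posterior)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.point
        uv = pts @ self.basis.T
        h = pts @ self.unit_normal
        return np.column_stack([uv, h])

    def from_plane_coords(self, uvh: np.ndarray) -> np.ndarray:
        uvh = np.atleast_2d(np.asarray(uvh, dtype=float))
        return self.point + uvh[:, :2] @ self.basis + np.outer(uvh[:, 2], self.unit_normal)

    def height(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points from the plane along +normal."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.unit_normal


@dataclass
class BMOEllipse:
    """Best-fit ellipse to the BMO points, expressed in plane coordinates.

    ``center`` is (u, v) μm, ``a >= b > 0`` are the semi-axes and ``angle``
    is the major-axis direction in radians within the plane frame.
    """

    center: np.ndarray
    a: float
    b: float
    angle: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        if not (self.a >= self.b > 0):
            raise ValueError("ellipse semi-axes must satisfy a >= b > 0")
        # normalise the axis direction to [0, pi)
        self.angle = float(self.angle) % math.pi

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def to_ellipse_frame(self, uv: np.ndarray) -> np.ndarray:
        """Rotate/translate (u, v) points into the ellipse's principal frame."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float)) - self.center
        c, s = math.cos(self.angle), math.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])
        return uv @ rot.T

    def from_ellipse_frame(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c, s = math.cos(self.angle), math.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return xy @ rot.T + self.center

    def contains(self, uv: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Boolean mask of points inside the ellipse scaled by ``scale`` on
        both semi-axes (``scale=1/sqrt(2)`` gives the equal-area core)."""
        xy = self.to_ellipse_frame(uv)
        return (xy[:, 0] / (self.a * scale)) ** 2 + (xy[:, 1] / (self.b * scale)) ** 2 <= 1.0

    def boundary(self, n: int = 256) -> np.ndarray:
        """(n, 2) points on the ellipse boundary in (u, v) coordinates."""
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        xy = np.column_stack([self.a * np.cos(t), self.b * np.sin(t)])
        return self.from_ellipse_frame(xy)


@dataclass
class ONHParameters:
    """Scalar ONH morphometry outputs for one eye/time-point."""

    alcsd: float  # mean ALCS depth, μm
    roc: float  # mean radius of curvature, mm; FLAT (inf) for flat surfaces
    mrw: float  # mean minimum rim width, μm
    rnflt: float | None = None  # instrument-supplied, μm
    n_bscans: int = 0
    extrapolation_flag: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.alcsd):
            raise ValueError("ALCSD must be finite")
        if self.mrw < 0:
            raise ValueError("MRW must be non-negative")
        if self.roc is not FLAT and not (self.roc > 0):
            raise ValueError("RoC must be positive when not flat")

    @property
    def roc_is_flat(self) -> bool:
        return math.isinf(self.roc)
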