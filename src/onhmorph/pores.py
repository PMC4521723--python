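"""Lamina cribrosa pore morphometry on the modelled ALCS.

Pores are annotated as 2D polygons on an en-face montage of the anterior
lamina surface. Because that view is a projection of a curved surface,
each polygon is lifted into 3D by mapping its (registered) vertices onto
the thin-plate-spline height field before measuring:

* **area** — true 3D surface area of the lifted polygon (μm²),
* **elongation** — √(λ₁/λ₂) of the second-central-moment matrix of the
  polygon region in its own best-fit local plane (1 = circle),
* **NND** — 3D Euclidean distance between a pore's area-weighted centroid
  and its nearest neighbouring centroid (μm).

Pores are partitioned into central/peripheral regions of equal area and
into 60° sectors measured from the BMO-ellipse major axis, with the
temporal half labelled superotemporal / temporal / inferotemporal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Polygon
from skimage.transform import SimilarityTransform

from .geometry import TPSSurface
from .types import BMOEllipse

__all__ = [
    "PoreAnnotation",
    "LiftedPore",
    "PoreMetrics",
    "PoreSet",
    "lift_pores",
    "compute_pore_metrics",
    "assign_partitions",
    "summarize_pores",
    "coverage_fraction",
    "pores_from_mask",
]

log = logging.getLogger(__name__)

TEMPORAL_SECTORS = ("superotemporal", "temporal", "inferotemporal")


@dataclass
class PoreAnnotation:
    """One marked pore: a simple polygon in montage pixel coordinates plus
    the similarity transform into the BMO-plane (u, v) frame (μm)."""

    pore_id: str
    polygon_2d: np.ndarray  # (k, 2) montage pixels, ordered, k >= 3
    registration: SimilarityTransform | None = None  # montage px -> (u, v) μm

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon_2d, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError(f"pore {self.pore_id}: polygon needs >=3 2D vertices")
        shp = Polygon(poly)
        if not shp.is_valid or shp.area <= 0:
            raise ValueError(f"pore {self.pore_id}: polygon must be simple with positive area")
        self.polygon_2d = poly

    def registered_polygon(self) -> np.ndarray:
        """Polygon vertices in the BMO-plane (u, v) frame, μm."""
        if self.registration is None:
            return self.polygon_2d
        return self.registration(self.polygon_2d)


@dataclass
class LiftedPore:
    """A pore polygon lifted onto the surface: (k, 3) vertices (u, v, h)."""

    pore_id: str
    vertices_3d: np.ndarray
    vertices_uv: np.ndarray  # the subdivided 2D polygon pre-lift


@dataclass
class PoreMetrics:
    pore_id: str
    area_um2: float
    elongation: float
    nnd_um: float = math.nan
    centroid_3d: np.ndarray = field(default=None)  # type: ignore[assignment]
    region: str = ""
    sector: str = ""


@dataclass
class PoreSet:
    """All pore metrics for one eye/time-point."""

    eye_id: str
    day: int
    pores: list[PoreMetrics]
    coverage_fraction: float = math.nan

    def __post_init__(self) -> None:
        ids = [p.pore_id for p in self.pores]
        if len(set(ids)) != len(ids):
            raise ValueError("pore ids must be unique")
        if not math.isnan(self.coverage_fraction) and not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pore_id": [p.pore_id for p in self.pores],
                "day": self.day,
                "area_um2": [p.area_um2 for p in self.pores],
                "elongation": [p.elongation for p in self.pores],
                "nnd_um": [p.nnd_um for p in self.pores],
                "region": [p.region for p in self.pores],
                "sector": [p.sector for p in self.pores],
            }
        )


# --------------------------------------------------------------------------
# lifting
# --------------------------------------------------------------------------

def _densify(polygon_uv: np.ndarray, max_edge: float) -> np.ndarray:
    """Subdivide polygon edges so no edge exceeds ``max_edge`` μm in (u, v)."""
    ring = np.vstack([polygon_uv, polygon_uv[:1]])
    line = LineString(ring).segmentize(max_edge)
    coords = np.asarray(line.coords)
    return coords[:-1]  # drop the duplicated closing vertex


def lift_pores(
    annotations: list[PoreAnnotation],
    surface: TPSSurface,
    max_edge_um: float = 10.0,
    domain_margin_um: float = 25.0,
) -> list[LiftedPore]:
    """Map registered pore polygons onto the TPS surface.

    Edges are subdivided to at most ``max_edge_um`` in (u, v) before
    lifting so surface bending inside a pore is captured. Pores with any
    vertex outside the surface's control-site hull (grown by
    ``domain_margin_um``) are excluded and logged, since their heights
    would be extrapolated.
    """
    lifted: list[LiftedPore] = []
    for ann in annotations:
        uv = _densify(ann.registered_polygon(), max_edge_um)
        if not bool(np.all(surface.covers(uv, margin=domain_margin_um))):
            log.warning("pore %s excluded: outside the surface domain", ann.pore_id)
            continue
        h = surface(uv)
        lifted.append(LiftedPore(ann.pore_id, np.column_stack([uv, h]), uv))
    return lifted


# --------------------------------------------------------------------------
# per-pore metrics
# --------------------------------------------------------------------------

def _fan_area_centroid(pore: LiftedPore) -> tuple[float, np.ndarray]:
    """3D area and area-weighted centroid from a fan triangulation.

    Triangle signs are taken from the 2D (u, v) orientation so simple
    non-convex outlines do not over-count folded fan triangles.
    """
    v3 = pore.vertices_3d
    v2 = pore.vertices_uv
    a3 = v3[1:-1] - v3[0]
    b3 = v3[2:] - v3[0]
    tri_areas = 0.5 * np.linalg.norm(np.cross(a3, b3), axis=1)
    a2 = v2[1:-1] - v2[0]
    b2 = v2[2:] - v2[0]
    sign2 = np.sign(a2[:, 0] * b2[:, 1] - a2[:, 1] * b2[:, 0])
    orient = np.sign(sign2.sum()) or 1.0
    signed = tri_areas * sign2 * orient
    area = float(signed.sum())
    if area <= 0:
        raise ValueError(f"pore {pore.pore_id}: degenerate polygon (non-positive area)")
    centers = (v3[0] + v3[1:-1] + v3[2:]) / 3.0
    centroid = (signed[:, None] * centers).sum(axis=0) / area
    return area, centroid


def _polygon_second_moments(xy: np.ndarray) -> np.ndarray:
    """Second central area moments [[μ20, μ11], [μ11, μ02]] of a simple
    polygon region (Green's theorem; classic closed forms)."""
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = 0.5 * cross.sum()
    cx = ((x + x1) * cross).sum() / (6.0 * A)
    cy = ((y + y1) * cross).sum() / (6.0 * A)
    Ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    Iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    Ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    mu20 = Ixx / A - cx * cx
    mu02 = Iyy / A - cy * cy
    mu11 = Ixy / A - cx * cy
    return np.array([[mu20, mu11], [mu11, mu02]])


def _elongation(pore: LiftedPore) -> float:
    """√(λ₁/λ₂) of the second-moment matrix in the pore's local tangent
    plane (the best-fit plane of its lifted vertices)."""
    v3 = pore.vertices_3d
    centered = v3 - v3.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    xy = centered @ vt[:2].T
    moments = _polygon_second_moments(xy)
    lam2, lam1 = np.sort(np.linalg.eigvalsh(moments))
    if lam2 <= 0:
        raise ValueError(f"pore {pore.pore_id}: collinear outline, elongation undefined")
    return float(math.sqrt(lam1 / lam2))


def compute_pore_metrics(lifted: list[LiftedPore]) -> list[PoreMetrics]:
    """Area, elongation and nearest-neighbour distance for each lifted pore.

    NND is the 3D Euclidean centre-to-centre distance between area-weighted
    centroids (at lamina curvatures the geodesic correction is < 0.01%);
    it is NaN when fewer than two pores are present.
    """
    if not lifted:
        raise ValueError("no pores to measure")
    metrics = []
    for pore in lifted:
        area, centroid = _fan_area_centroid(pore)
        metrics.append(PoreMetrics(pore.pore_id, area, _elongation(pore), centroid_3d=centroid))
    if len(metrics) >= 2:
        centroids = np.array([m.centroid_3d for m in metrics])
        dist = cdist(centroids, centroids)
        np.fill_diagonal(dist, np.inf)
        for m, d in zip(metrics, dist.min(axis=1)):
            m.nnd_um = float(d)
    return metrics


# --------------------------------------------------------------------------
# partitions
# --------------------------------------------------------------------------

def assign_partitions(
    pores: list[PoreMetrics],
    ellipse: BMOEllipse,
    laterality: str = "OD",
) -> list[PoreMetrics]:
    """Label each pore with a region (central/peripheral) and a 60° sector.

    The central region is the concentric, co-oriented ellipse with both
    semi-axes scaled by 1/√2, which halves the area exactly. Sector labels
    are wedges of the centroid's angle from the *temporal end* of the
    major axis: temporal within ±30°, superotemporal (30°, 90°],
    inferotemporal [−90°, −30°), everything nasal is "other". For OD the
    temporal end of the major axis is the one pointing toward −u and
    superior is +v; for OS the u axis is mirrored. Centroids outside the
    BMO ellipse are labelled peripheral (with their angular sector) and
    logged.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    mirror = -1.0 if laterality == "OS" else 1.0
    # unit vector of the major axis in (u, v); temporal end has negative u
    major = np.array([math.cos(ellipse.angle), math.sin(ellipse.angle)])
    if mirror * major[0] > 0:
        major = -major
    superior = np.array([-major[1], major[0]])  # +90° from temporal end
    if superior[1] < 0:
        superior = -superior

    for m in pores:
        uv = np.asarray(m.centroid_3d[:2], dtype=float)
        inside = bool(ellipse.contains(uv[None, :])[0])
        central = bool(ellipse.contains(uv[None, :], scale=1.0 / math.sqrt(2.0))[0])
        m.region = "central" if (inside and central) else "peripheral"
        if not inside:
            log.info("pore %s centroid outside the BMO ellipse", m.pore_id)
        rel = uv - ellipse.center
        angle = math.degrees(math.atan2(float(rel @ superior), float(rel @ major)))
        if -30.0 < angle <= 30.0:
            m.sector = "temporal"
        elif 30.0 < angle <= 90.0:
            m.sector = "superotemporal"
        elif -90.0 <= angle <= -30.0:
            m.sector = "inferotemporal"
        else:
            m.sector = "other"
    return pores


def coverage_fraction(imaged_region_uv: np.ndarray, ellipse: BMOEllipse) -> float:
    """Fraction of the BMO-ellipse area covered by the imaged-montage
    polygon (both in plane coordinates)."""
    imaged = Polygon(np.asarray(imaged_region_uv, dtype=float))
    bmo = Polygon(ellipse.boundary(512))
    return float(imaged.intersection(bmo).area / bmo.area)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def summarize_pores(poreset: PoreSet, grouping: str = "global") -> pd.DataFrame:
    """Per-group mean ± SD (n−1) and n for area, elongation and NND.

    ``grouping`` is one of ``global``, ``region`` or ``sector``. A group
    with a single pore reports SD = 0 with n = 1; empty groups report
    n = 0 and no mean.
    """
    df = poreset.to_frame()
    if grouping == "global":
        df["group"] = "global"
        levels = ["global"]
    elif grouping == "region":
        df["group"] = df["region"]
        levels = ["central", "peripheral"]
    elif grouping == "sector":
        df["group"] = df["sector"]
        levels = list(TEMPORAL_SECTORS) + ["other"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    for level in levels:
        sub = df[df["group"] == level]
        row: dict[str, object] = {"group": level, "n": len(sub)}
        for col in ("area_um2", "elongation", "nnd_um"):
            vals = sub[col].dropna().to_numpy()
            if len(vals) == 0:
                row[f"{col}_mean"] = math.nan
                row[f"{col}_sd"] = math.nan
            else:
                row[f"{col}_mean"] = float(np.mean(vals))
                row[f"{col}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mask input
# --------------------------------------------------------------------------

def pores_from_mask(
    mask: np.ndarray,
    registration: SimilarityTransform | None = None,
    min_area_px: int = 4,
) -> list[PoreAnnotation]:
    """Extract pore polygons from a binary mask (pores = nonzero).

    Connected components (8-connectivity) are traced with a marching-
    squares border following; holes are ignored. Component outlines are
    returned in (x, y) = (col, row) pixel coordinates.
    """
    from skimage import measure

    mask = np.asarray(mask) > 0
    labels = measure.label(mask, connectivity=2)
    annotations = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        component = labels == region.label
        contours = measure.find_contours(component.astype(float), 0.5)
        if not contours:
            continue
        outline = max(contours, key=len)  # outer border; holes ignored
        poly_xy = outline[:, ::-1]  # (row, col) -> (x, y)
        poly_xy = np.asarray(Polygon(poly_xy).simplify(0.2).exterior.coords)[:-1]
        if len(poly_xy) < 3:
            continue
        annotations.append(
            PoreAnnotation(pore_id=f"pore{region.label:03d}", polygon_2d=poly_xy,
                           registration=registration)
        )
    return annotations
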