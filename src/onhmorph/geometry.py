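"""Geometric modelling of the optic nerve head from marked point sets.

The anterior lamina cribrosa surface (ALCS) is modelled in three steps:

1. a reference plane is fit to the Bruch's membrane opening (BMO)
   termination points by orthogonal (total) least squares,
2. an ellipse is fit to the BMO points projected into that plane by a
   direct least-squares conic fit constrained to an ellipse,
3. a thin-plate spline (TPS) height field ``h(u, v)`` over the plane is fit
   to the marked ALCS points.

From the fitted model three scalar parameters are derived:

* **mean ALCSD** — the mean height of the TPS surface above the BMO plane,
  averaged over the interior of the BMO ellipse (positive posterior),
* **mean RoC** — the radius of a least-squares sphere fit to surface
  samples inside the projected ellipse (mm); surfaces flatter than a
  configurable threshold return the ``FLAT`` sentinel,
* **mean MRW** — the minimum rim width: for every BMO point, the minimum
  2D distance to the internal limiting membrane polyline within its own
  B-scan plane, averaged across all BMO points of all B-scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq, solve
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Point, Polygon

from .types import (
    FLAT,
    BMOEllipse,
    DegenerateGeometryError,
    EllipseFitError,
    MarkedONH,
    ONHParameters,
    Plane,
)

__all__ = [
    "fit_plane",
    "fit_bmo_ellipse",
    "TPSSurface",
    "fit_tps",
    "mean_alcsd",
    "mean_roc",
    "mean_mrw",
    "fit_sphere",
    "fit_onh",
    "FittedONH",
]


# --------------------------------------------------------------------------
# plane fit
# --------------------------------------------------------------------------

def fit_plane(points: np.ndarray, orient_toward: np.ndarray | None = None) -> Plane:
    """Orthogonal least-squares plane through ``points``.

    The plane minimises the sum of squared perpendicular distances (total
    least squares), appropriate because the BMO points come from radial
    scans at all orientations and no axis is privileged.

    Parameters
    ----------
    points:
        (n, 3) array, n >= 3, not collinear.
    orient_toward:
        Optional reference points (typically the marked ALCS points); the
        normal sign is chosen so their mean height is positive, i.e.
        +normal points posteriorly toward the lamina.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or a (numerically) collinear set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # eigen-decomposition of the scatter matrix: the normal is the
    # direction of least variance
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    scale = svals[0]
    if scale == 0 or svals[1] / scale < 1e-12:
        raise DegenerateGeometryError("points are collinear; the plane is undetermined")
    normal = vt[2]
    plane = Plane(point=centroid, unit_normal=normal)
    if orient_toward is not None and len(orient_toward):
        if float(np.mean(plane.height(orient_toward))) < 0:
            plane = Plane(point=centroid, unit_normal=-normal)
    return plane


# --------------------------------------------------------------------------
# ellipse fit
# --------------------------------------------------------------------------

def _conic_to_ellipse(coeffs: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Convert conic ``Ax² + Bxy + Cy² + Dx + Ey + F = 0`` to geometric
    ellipse parameters (center, a, b, angle)."""
    A, B, C, D, E, F = coeffs
    disc = B * B - 4.0 * A * C
    if disc >= 0:
        raise EllipseFitError("conic is not an ellipse (non-negative discriminant)")
    center = np.linalg.solve(np.array([[2.0 * A, B], [B, 2.0 * C]]), np.array([-D, -E]))
    cx, cy = center
    # constant term after translating to the center
    Fc = F + (D * cx + E * cy) / 2.0
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    evals, evecs = np.linalg.eigh(M)
    axes2 = -Fc / evals
    if np.any(axes2 <= 0):
        raise EllipseFitError("conic is a degenerate/imaginary ellipse")
    axes = np.sqrt(axes2)
    order = np.argsort(axes)[::-1]  # a >= b
    a, b = axes[order]
    major_vec = evecs[:, order[0]]
    angle = math.atan2(major_vec[1], major_vec[0])
    return center, float(a), float(b), angle


def fit_bmo_ellipse(bmo_points: np.ndarray, plane: Plane) -> BMOEllipse:
    """Direct least-squares ellipse fit to the BMO points in plane coordinates.

    Uses the numerically stable Halir–Flusser formulation of the
    ellipse-constrained conic fit. If the *unconstrained* best-fit conic
    through the points is not an ellipse (e.g. the points sample a
    hyperbola branch), an :class:`EllipseFitError` is raised rather than
    forcing an ellipse through non-elliptical data.
    """
    uvh = plane.to_plane_coords(np.asarray(bmo_points, dtype=float))
    uv = uvh[:, :2]
    if len(uv) < 5:
        raise EllipseFitError("ellipse fit needs at least 5 points")

    # normalise for conditioning
    mean = uv.mean(axis=0)
    scale = float(np.sqrt(((uv - mean) ** 2).sum(axis=1).mean()))
    if scale == 0:
        raise EllipseFitError("coincident points")
    x, y = ((uv - mean) / scale).T

    # unconstrained conic via SVD (full matrices: with exactly 5 points the
    # conic lives in the nullspace): detects non-elliptical data
    Dfull = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    _, _, vt = np.linalg.svd(Dfull, full_matrices=True)
    if vt[-1][1] ** 2 - 4.0 * vt[-1][0] * vt[-1][2] >= 0:
        raise EllipseFitError("best-fit conic through the points is not an ellipse")

    # Halir & Flusser direct ellipse-specific fit
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    Mmat = S1 + S2 @ T
    Mred = np.vstack([Mmat[2] / 2.0, -Mmat[1], Mmat[0] / 2.0])
    evals, evecs = np.linalg.eig(Mred)
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    idx = np.flatnonzero((cond > 0) & np.isreal(evals))
    if len(idx) == 0:
        raise EllipseFitError("no ellipse satisfies the conic constraint")
    a1 = np.real(evecs[:, idx[0]])
    coeffs = np.concatenate([a1, T @ a1])

    center_n, a_n, b_n, angle = _conic_to_ellipse(coeffs)
    return BMOEllipse(center=center_n * scale + mean, a=a_n * scale, b=b_n * scale, angle=angle)


# --------------------------------------------------------------------------
# thin-plate spline surface
# --------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r² log r, written as ½ r² log r² with U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = 0.5 * r2[nz] * np.log(r2[nz])
    return out


@dataclass
class TPSSurface:
    """Thin-plate spline height field ``h(u, v)`` over the BMO plane.

    h(u, v) = a0 + a1·u + a2·v + Σᵢ wᵢ U(‖(u,v) − sᵢ‖),  U(r) = r² log r

    The weights satisfy the side conditions Σwᵢ = Σwᵢuᵢ = Σwᵢvᵢ = 0, which
    make the bending energy finite; with ``lam = 0`` the surface
    interpolates every (merged) control site.
    """

    sites: np.ndarray  # (n, 2) control sites in plane coordinates, μm
    heights: np.ndarray  # (n,) control heights along the plane normal, μm
    weights: np.ndarray  # (n,) kernel weights (in the normalized frame)
    affine: np.ndarray  # (3,) a0, a1, a2 (in the normalized frame)
    lam: float = 0.0
    #: Internal coordinate normalization (center, scale). The TPS
    #: interpolant at λ=0 is equivariant under coordinate scaling, so the
    #: system is assembled on unit-scale sites for conditioning; λ > 0 is
    #: interpreted in the normalized frame.
    center: np.ndarray = field(default=None)  # type: ignore[assignment]
    scale: float = 1.0

    _hull: Polygon = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.center is None:
            self.center = np.zeros(2)

    def _norm(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return (uv - self.center) / self.scale

    @property
    def sites_normalized(self) -> np.ndarray:
        return self._norm(self.sites)

    def __call__(self, uv: np.ndarray) -> np.ndarray:
        q = self._norm(uv)
        s = self.sites_normalized
        out = np.empty(len(q))
        for lo in range(0, len(q), 4096):  # chunked to bound the kernel temporaries
            block = q[lo:lo + 4096]
            d = block[:, None, :] - s[None, :, :]
            K = _tps_kernel((d * d).sum(axis=2))
            out[lo:lo + 4096] = self.affine[0] + block @ self.affine[1:] + K @ self.weights
        return out

    def gradient(self, uv: np.ndarray) -> np.ndarray:
        """Analytic (∂h/∂u, ∂h/∂v); ∂U/∂x = x(log r² + 1)."""
        q = self._norm(uv)
        d = q[:, None, :] - self.sites_normalized[None, :, :]
        r2 = (d * d).sum(axis=2)
        g = np.zeros_like(r2)
        nz = r2 > 0
        g[nz] = np.log(r2[nz]) + 1.0
        grad = np.einsum("ij,ijk->ik", g * self.weights[None, :], d)
        return (grad + self.affine[1:]) / self.scale

    def hessian(self, uv: np.ndarray) -> np.ndarray:
        """Analytic second derivatives, shape (n, 2, 2)."""
        q = self._norm(uv)
        d = q[:, None, :] - self.sites_normalized[None, :, :]
        r2 = (d * d).sum(axis=2)
        nz = r2 > 0
        logr2 = np.where(nz, np.log(np.where(nz, r2, 1.0)), 0.0)
        inv = np.where(nz, 2.0 / np.where(nz, r2, 1.0), 0.0)
        w = np.where(nz, self.weights[None, :], 0.0)  # kernel curvature vanishes at r=0
        hess = np.empty((len(uv), 2, 2))
        hess[:, 0, 0] = (w * (logr2 + 1.0 + inv * d[:, :, 0] ** 2)).sum(axis=1)
        hess[:, 1, 1] = (w * (logr2 + 1.0 + inv * d[:, :, 1] ** 2)).sum(axis=1)
        hess[:, 0, 1] = hess[:, 1, 0] = (w * inv * d[:, :, 0] * d[:, :, 1]).sum(axis=1)
        return hess / self.scale**2

    @property
    def domain_hull(self) -> Polygon:
        """Convex hull of the control sites as a shapely polygon."""
        if self._hull is None:
            hull = ConvexHull(self.sites)
            self._hull = Polygon(self.sites[hull.vertices])
        return self._hull

    def covers(self, uv: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Which query points lie inside the site hull grown by ``margin`` μm."""
        import shapely

        poly = self.domain_hull.buffer(margin) if margin else self.domain_hull
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return shapely.intersects_xy(poly, uv[:, 0], uv[:, 1])


def _merge_duplicate_sites(uv: np.ndarray, h: np.ndarray, tol: float = 1.0):
    """Average heights of sites closer than ``tol`` μm to avoid a singular
    TPS system (simple grid-hash clustering; tol is 1 μm by default)."""
    keys = np.round(uv / tol).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    if np.all(counts == 1):
        return uv, h
    n_groups = len(counts)
    uv_m = np.zeros((n_groups, 2))
    h_m = np.zeros(n_groups)
    np.add.at(uv_m, inverse, uv)
    np.add.at(h_m, inverse, h)
    return uv_m / counts[:, None], h_m / counts


def fit_tps(
    alcs_points: np.ndarray,
    plane: Plane,
    lam: float = 0.0,
    merge_tol: float = 1.0,
) -> TPSSurface:
    """Fit a thin-plate spline to marked ALCS points.

    The 3D points are projected onto ``plane``; the (u, v) coordinates
    become interpolation sites and the heights along the plane normal the
    values. ``lam`` is the smoothing parameter added to the kernel block
    diagonal (0 = exact interpolation, matching surfaces fit *through*
    marked points).
    """
    if lam < 0:
        raise ValueError("regularization must be non-negative")
    uvh = plane.to_plane_coords(np.asarray(alcs_points, dtype=float))
    uv, h = _merge_duplicate_sites(uvh[:, :2], uvh[:, 2], tol=merge_tol)
    n = len(uv)
    if n < 4:
        raise DegenerateGeometryError("TPS fit needs at least 4 distinct sites")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), uv]), tol=1e-9 * max(1.0, np.abs(uv).max()))
    if rank < 3:
        raise DegenerateGeometryError("TPS sites are collinear in the plane")

    # assemble on unit-scale coordinates for conditioning (the λ=0
    # interpolant is equivariant under this rescaling)
    center = uv.mean(axis=0)
    scale = float(np.sqrt(((uv - center) ** 2).sum(axis=1).mean())) or 1.0
    q = (uv - center) / scale
    d = q[:, None, :] - q[None, :, :]
    K = _tps_kernel((d * d).sum(axis=2))
    P = np.column_stack([np.ones(n), q])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K + lam * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.concatenate([h, np.zeros(3)])
    sol = solve(A, rhs)
    weights, aff = sol[:n], sol[n:]
    return TPSSurface(sites=uv, heights=h, weights=weights,
                      affine=np.array([aff[0], aff[1], aff[2]]), lam=lam,
                      center=center, scale=scale)


# --------------------------------------------------------------------------
# derived scalars
# --------------------------------------------------------------------------

def _ellipse_grid(ellipse: BMOEllipse, grid_n: int) -> np.ndarray:
    """Uniform grid_n × grid_n grid over the ellipse bounding box, masked to
    the interior, returned in (u, v) plane coordinates."""
    x = np.linspace(-ellipse.a, ellipse.a, grid_n)
    y = np.linspace(-ellipse.b, ellipse.b, grid_n)
    xx, yy = np.meshgrid(x, y)
    mask = (xx / ellipse.a) ** 2 + (yy / ellipse.b) ** 2 <= 1.0
    xy = np.column_stack([xx[mask], yy[mask]])
    return ellipse.from_ellipse_frame(xy)


def mean_alcsd(
    surface: TPSSurface,
    ellipse: BMOEllipse,
    grid_n: int = 128,
    extrapolation_margin: float = 50.0,
) -> tuple[float, bool]:
    """Mean ALCS depth: average TPS height over the BMO-ellipse interior.

    Returns ``(alcsd_um, extrapolation_flag)``; the flag is set when part
    of the averaging grid falls outside the convex hull of the control
    sites grown by ``extrapolation_margin`` μm (the value is still
    computed, but rests on extrapolated surface there).
    """
    uv = _ellipse_grid(ellipse, grid_n)
    flag = not bool(np.all(surface.covers(uv, margin=extrapolation_margin)))
    return float(np.mean(surface(uv))), flag


def fit_sphere(points: np.ndarray, refine: bool = True) -> tuple[np.ndarray, float]:
    """Least-squares sphere through 3D points.

    An algebraic (linear) fit provides the start; a Gauss–Newton pass on
    the true geometric residuals ``‖p − c‖ − R`` refines it. Returns
    ``(center, radius)``. Near-planar data yields a very large radius
    rather than an error.
    """
    pts = np.asarray(points, dtype=float)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    bvec = (pts**2).sum(axis=1)
    sol, *_ = lstsq(A, bvec)
    center = sol[:3]
    r2 = sol[3] + center @ center
    radius = math.sqrt(max(r2, 0.0))
    if refine and radius > 0 and np.isfinite(radius):
        def residuals(params):
            return np.linalg.norm(pts - params[:3], axis=1) - params[3]

        res = least_squares(residuals, np.append(center, radius), method="lm", max_nfev=200)
        center, radius = res.x[:3], float(abs(res.x[3]))
    return center, float(radius)


def mean_roc(
    surface: TPSSurface,
    ellipse: BMOEllipse,
    grid_n: int = 64,
    flat_threshold_mm: float = 50.0,
    method: str = "sphere",
) -> float:
    """Mean radius of curvature of the surface within the projected BMO
    ellipse, in millimetres.

    ``method='sphere'`` (default): radius of a least-squares sphere fit to
    the 3D surface samples. ``method='curvature'``: average of the
    pointwise radius 1/|H| from the analytic mean curvature H of the
    height field. Radii beyond ``flat_threshold_mm`` (surfaces
    indistinguishable from flat, where the radius diverges) return the
    ``FLAT`` sentinel.
    """
    uv = _ellipse_grid(ellipse, grid_n)
    if len(uv) < 10:
        raise DegenerateGeometryError("too few surface samples for a curvature estimate")
    if method == "sphere":
        pts = np.column_stack([uv, surface(uv)])
        # seed from a rotationally symmetric quadric h ≈ c0 + c1 u + c2 v +
        # κ(u²+v²)/2: planar data (κ → 0) would otherwise let the algebraic
        # sphere fit collapse onto a meaningless in-surface circle
        design = np.column_stack([np.ones(len(uv)), uv, 0.5 * (uv**2).sum(axis=1)])
        coef, *_ = lstsq(design, pts[:, 2])
        kappa = coef[3]
        if abs(kappa) < 1.0 / (flat_threshold_mm * 1000.0):
            return FLAT
        r0 = 1.0 / abs(kappa)
        center0 = np.array([
            -coef[1] / kappa,
            -coef[2] / kappa,
            float(np.mean(pts[:, 2])) + 1.0 / kappa,
        ])

        def residuals(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

        res = least_squares(residuals, np.append(center0, r0), method="lm", max_nfev=200)
        roc_mm = float(abs(res.x[3])) / 1000.0
    elif method == "curvature":
        grad = surface.gradient(uv)
        hess = surface.hessian(uv)
        hu, hv = grad[:, 0], grad[:, 1]
        huu, hvv, huv = hess[:, 0, 0], hess[:, 1, 1], hess[:, 0, 1]
        denom = 2.0 * (1.0 + hu**2 + hv**2) ** 1.5
        H = ((1.0 + hv**2) * huu - 2.0 * hu * hv * huv + (1.0 + hu**2) * hvv) / denom
        cap = 1.0 / (flat_threshold_mm * 1000.0)
        radii = 1.0 / np.maximum(np.abs(H), cap)
        roc_mm = float(np.mean(radii)) / 1000.0
    else:
        raise ValueError(f"unknown RoC method: {method!r}")
    if not np.isfinite(roc_mm) or roc_mm > flat_threshold_mm:
        return FLAT
    return float(roc_mm)


def mean_mrw(marked: MarkedONH) -> float:
    """Mean minimum rim width.

    For every BMO point the minimum Euclidean distance to the ILM polyline
    is computed in 2D within that point's own B-scan plane (minimum over
    all polyline *segments*, not just vertices); the mean over all BMO
    points of all B-scans is returned.

    The in-scan lateral coordinate of a 3D BMO point is its projection on
    the scan direction (cos θ, sin θ, 0); radial scans share a common axis
    through the eye-frame origin.
    """
    distances: list[float] = []
    for scan in marked.bscans:
        if len(scan.bmo_points) == 0 or len(scan.ilm_polyline) < 2:
            continue
        theta = math.radians(scan.scan_angle_deg)
        direction = np.array([math.cos(theta), math.sin(theta), 0.0])
        ilm = LineString(scan.ilm_polyline)
        for p in scan.bmo_points:
            s = float(p @ direction)
            distances.append(ilm.distance(Point(s, p[2])))
    if not distances:
        raise DegenerateGeometryError("no B-scan has both BMO points and an ILM polyline")
    return float(np.mean(distances))


# --------------------------------------------------------------------------
# end-to-end convenience
# --------------------------------------------------------------------------

@dataclass
class FittedONH:
    """Fitted geometric model plus derived scalars for one eye/time-point."""

    plane: Plane
    ellipse: BMOEllipse
    surface: TPSSurface
    params: ONHParameters


def fit_onh(
    marked: MarkedONH,
    lam: float = 0.0,
    grid_n: int = 128,
    flat_threshold_mm: float = 50.0,
    roc_method: str = "sphere",
    rnflt: float | None = None,
) -> FittedONH:
    """Run the full geometric pipeline on one marked eye/time-point."""
    marked.validate()
    plane = fit_plane(marked.bmo_points, orient_toward=marked.alcs_points)
    ellipse = fit_bmo_ellipse(marked.bmo_points, plane)
    surface = fit_tps(marked.alcs_points, plane, lam=lam)
    alcsd, flag = mean_alcsd(surface, ellipse, grid_n=grid_n)
    roc = mean_roc(surface, ellipse, grid_n=min(grid_n, 64),
                   flat_threshold_mm=flat_threshold_mm, method=roc_method)
    mrw = mean_mrw(marked)
    n_bscans = sum(1 for b in marked.bscans if len(b.bmo_points))
    params = ONHParameters(alcsd=alcsd, roc=roc, mrw=mrw, rnflt=rnflt,
                           n_bscans=n_bscans, extrapolation_flag=flag)
    return FittedONH(plane=plane, ellipse=ellipse, surface=surface, params=params)
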