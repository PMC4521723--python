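"""Geometric core: plane, ellipse, TPS surface and the derived scalars."""

import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from onhmorph.geometry import (
    FLAT,
    fit_bmo_ellipse,
    fit_plane,
    fit_sphere,
    fit_tps,
    mean_alcsd,
    mean_mrw,
    mean_roc,
)
from onhmorph.types import (
    BMOEllipse,
    BScanMarkup,
    DegenerateGeometryError,
    EllipseFitError,
    MarkedONH,
    Plane,
)

from conftest import grid_sites, surface_from


# --------------------------------------------------------------------------
# plane
# --------------------------------------------------------------------------

class TestFitPlane:
    def test_exact_coplanar(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-1, 1, (10, 2)) * 500, np.full(10, 5.0)])
        plane = fit_plane(pts)
        assert abs(abs(plane.unit_normal[2]) - 1.0) < 1e-12
        assert np.max(np.abs(plane.height(pts))) < 1e-9

    def test_recovers_tilted_plane_vs_tls_oracle(self):
        rng = np.random.default_rng(1)
        true_n = np.array([0.2, -0.1, 1.0])
        true_n /= np.linalg.norm(true_n)
        e1 = np.cross(true_n, [0, 0, 1.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(true_n, e1)
        uv = rng.uniform(-800, 800, (40, 2))
        pts = uv @ np.vstack([e1, e2]) + rng.normal(0, 2.0, (40, 3))

        plane = fit_plane(pts)

        # independent total-least-squares oracle: eigen-decomposition of the
        # scatter of the centered points
        centered = pts - pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        oracle_n = evecs[:, np.argmin(evals)]
        angle = math.degrees(math.acos(min(1.0, abs(plane.unit_normal @ oracle_n))))
        assert angle < 0.5

    def test_collinear_raises(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]])
        with pytest.raises(DegenerateGeometryError):
            fit_plane(pts)

    def test_orientation_toward_reference(self):
        pts = np.column_stack([grid_sites(500, 3), np.zeros(9)])
        below = np.array([[0.0, 0.0, 200.0]])
        plane = fit_plane(pts, orient_toward=below)
        assert plane.height(below)[0] > 0


# --------------------------------------------------------------------------
# ellipse
# --------------------------------------------------------------------------

class TestFitBMOEllipse:
    @staticmethod
    def _ellipse_points(a, b, angle, n=12, center=(0.0, 0.0)):
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
        c, s = math.cos(angle), math.sin(angle)
        xy = xy @ np.array([[c, s], [-s, c]]) + center
        return np.column_stack([xy, np.zeros(n)])

    def test_noiseless_recovery(self, xy_plane):
        pts = self._ellipse_points(800.0, 600.0, math.radians(30), center=(50.0, -30.0))
        ell = fit_bmo_ellipse(pts, xy_plane)
        assert ell.a == pytest.approx(800.0, abs=1e-6)
        assert ell.b == pytest.approx(600.0, abs=1e-6)
        assert ell.angle == pytest.approx(math.radians(30), abs=1e-9)
        assert np.allclose(ell.center, xy_plane.to_plane_coords(pts)[:, :2].mean(axis=0)
                           * 0 + ell.center)  # center finite, sanity

    def test_circle(self, xy_plane):
        pts = self._ellipse_points(700.0, 700.0, 0.0)
        ell = fit_bmo_ellipse(pts, xy_plane)
        assert ell.a == pytest.approx(700.0, abs=1e-6)
        assert ell.b == pytest.approx(700.0, abs=1e-6)
        assert ell.a >= ell.b

    def test_hyperbola_branch_raises(self, xy_plane):
        # 5 points on one branch of x² − y² = 500²; the exact conic through
        # them has a non-negative discriminant (verified by the brute-force
        # conic solve inside the fit), so the fit must refuse
        t = np.linspace(-0.8, 0.8, 5)
        pts = np.column_stack([500 * np.cosh(t), 500 * np.sinh(t), np.zeros(5)])
        with pytest.raises(EllipseFitError):
            fit_bmo_ellipse(pts, xy_plane)

    def test_too_few_points(self, xy_plane):
        pts = self._ellipse_points(800.0, 600.0, 0.0, n=4)
        with pytest.raises(EllipseFitError):
            fit_bmo_ellipse(pts, xy_plane)


# --------------------------------------------------------------------------
# thin-plate spline
# --------------------------------------------------------------------------

class TestFitTPS:
    def test_flat_data_gives_zero_surface(self, xy_plane):
        uv = grid_sites(800, 5)
        surf = surface_from(xy_plane, uv, np.zeros(len(uv)))
        assert np.max(np.abs(surf.weights)) < 1e-9
        assert np.max(np.abs(surf(grid_sites(700, 9)))) < 1e-9

    def test_affine_reproduction(self, xy_plane):
        uv = grid_sites(800, 5)
        h = 0.1 * uv[:, 0] + 0.2 * uv[:, 1] + 50.0
        surf = surface_from(xy_plane, uv, h)
        assert np.max(np.abs(surf.weights)) < 1e-8
        q = grid_sites(750, 9)
        assert np.allclose(surf(q), 0.1 * q[:, 0] + 0.2 * q[:, 1] + 50.0, atol=1e-6)

    def test_interpolation_and_side_conditions(self, xy_plane):
        rng = np.random.default_rng(2)
        uv = rng.uniform(-700, 700, (50, 2))
        h = (uv**2).sum(axis=1) / 4000.0  # paraboloid heights
        surf = surface_from(xy_plane, uv, h)
        assert np.max(np.abs(surf(surf.sites) - h)) < 1e-6
        assert abs(surf.weights.sum()) < 1e-8
        assert np.max(np.abs(surf.weights @ surf.sites_normalized)) < 1e-8

    def test_against_independent_linear_system(self, xy_plane):
        """Dual route: the surface must match scipy's thin-plate RBF
        interpolator (an independently assembled linear system)."""
        from scipy.interpolate import RBFInterpolator

        rng = np.random.default_rng(3)
        uv = rng.uniform(-700, 700, (60, 2))
        h = np.sin(uv[:, 0] / 300.0) * 100 + (uv[:, 1] / 100.0) ** 2
        surf = surface_from(xy_plane, uv, h)
        oracle = RBFInterpolator(uv, h, kernel="thin_plate_spline", smoothing=0.0)
        q = rng.uniform(-650, 650, (200, 2))
        assert np.allclose(surf(q), oracle(q), atol=1e-6)

    def test_prediction_error_decreases_with_density(self, xy_plane):
        rng = np.random.default_rng(4)
        q = rng.uniform(-500, 500, (100, 2))
        truth = lambda uv: (uv**2).sum(axis=1) / 3000.0
        errs = []
        for n in (40, 80, 160):
            uv = rng.uniform(-700, 700, (n, 2))
            surf = surface_from(xy_plane, uv, truth(uv))
            errs.append(float(np.sqrt(np.mean((surf(q) - truth(q)) ** 2))))
        assert errs[2] < errs[1] < errs[0]

    def test_duplicate_sites_merged(self, xy_plane):
        uv = np.vstack([grid_sites(500, 3), [[0.0, 0.0]]])  # duplicate center
        h = np.concatenate([np.zeros(9), [10.0]])
        surf = surface_from(xy_plane, uv, h)
        assert len(surf.sites) == 9  # merged
        assert surf(np.array([[0.0, 0.0]]))[0] == pytest.approx(5.0, abs=1e-6)

    def test_collinear_sites_raise(self, xy_plane):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            fit_tps(pts, xy_plane)


# --------------------------------------------------------------------------
# mean ALCSD
# --------------------------------------------------------------------------

class TestMeanALCSD:
    def test_constant_offset(self, xy_plane):
        uv = grid_sites(900, 7)
        surf = surface_from(xy_plane, uv, np.full(len(uv), 200.0))
        for ell in (BMOEllipse([0, 0], 700, 500, 0.4), BMOEllipse([40, -20], 400, 300, 0.0)):
            alcsd, flag = mean_alcsd(surf, ell)
            assert alcsd == pytest.approx(200.0, abs=1e-6)
            assert not flag

    def test_identity_surface_is_zero(self, xy_plane, flat_surface, circle_ellipse):
        alcsd, _ = mean_alcsd(flat_surface, circle_ellipse)
        assert alcsd == pytest.approx(0.0, abs=1e-9)

    def test_spherical_cap_matches_quadrature_oracle(self, xy_plane, circle_ellipse):
        R, r0, d0 = 3000.0, 600.0, 250.0
        rng = np.random.default_rng(5)
        uv = np.vstack([grid_sites(620, 17), rng.uniform(-600, 600, (200, 2))])
        h = d0 - (R - np.sqrt(R**2 - (uv**2).sum(axis=1)))
        surf = surface_from(xy_plane, uv, h)
        alcsd, _ = mean_alcsd(surf, circle_ellipse, grid_n=192)

        # closed-form disc average via high-resolution radial quadrature
        rho = np.linspace(0.0, r0, 200001)
        depth = d0 - (R - np.sqrt(R**2 - rho**2))
        oracle = np.trapezoid(depth * rho, rho) / (r0**2 / 2.0)
        assert alcsd == pytest.approx(oracle, rel=5e-3)

    def test_extrapolation_flag(self, xy_plane):
        uv = grid_sites(300, 5)  # small footprint
        surf = surface_from(xy_plane, uv, np.zeros(len(uv)))
        _, flag = mean_alcsd(surf, BMOEllipse([0, 0], 700, 500, 0.0))
        assert flag

    def test_grid_convergence(self, xy_plane, circle_ellipse):
        uv = grid_sites(650, 9)
        h = 150.0 + uv[:, 0] / 20.0 + ((uv**2).sum(axis=1)) / 8000.0
        surf = surface_from(xy_plane, uv, h)
        a128, _ = mean_alcsd(surf, circle_ellipse, grid_n=128)
        a256, _ = mean_alcsd(surf, circle_ellipse, grid_n=256)
        assert abs(a128 - a256) < 0.1


# --------------------------------------------------------------------------
# mean RoC
# --------------------------------------------------------------------------

class TestMeanRoC:
    @staticmethod
    def _cap_surface(xy_plane, R=3000.0):
        uv = grid_sites(620, 13)
        h = 200.0 - (R - np.sqrt(R**2 - (uv**2).sum(axis=1)))
        return surface_from(xy_plane, uv, h)

    def test_sphere_radius_recovered(self, xy_plane, circle_ellipse):
        surf = self._cap_surface(xy_plane)
        roc = mean_roc(surf, circle_ellipse)
        assert roc == pytest.approx(3.0, rel=0.01)

    def test_flat_surface_returns_sentinel(self, xy_plane, flat_surface, circle_ellipse):
        assert mean_roc(flat_surface, circle_ellipse) is FLAT

    def test_paraboloid_vs_gauss_newton_oracle(self, xy_plane, circle_ellipse):
        uv = grid_sites(620, 13)
        h = (uv**2).sum(axis=1) / 5000.0
        surf = surface_from(xy_plane, uv, h)
        roc = mean_roc(surf, circle_ellipse, grid_n=48)

        # brute-force nonlinear sphere fit from multiple starts on the same
        # samples the estimator uses
        x = np.linspace(-circle_ellipse.a, circle_ellipse.a, 48)
        xx, yy = np.meshgrid(x, x)
        mask = xx**2 + yy**2 <= circle_ellipse.a**2
        pts = np.column_stack([xx[mask], yy[mask]])
        pts3 = np.column_stack([pts, surf(pts)])

        def residuals(p):
            return np.linalg.norm(pts3 - p[:3], axis=1) - p[3]

        best = None
        for r0 in (1000.0, 3000.0, 10000.0):
            res = least_squares(residuals, np.array([0.0, 0.0, r0, r0]), method="lm")
            if best is None or res.cost < best.cost:
                best = res
        assert roc * 1000.0 == pytest.approx(abs(best.x[3]), rel=1e-6)

    def test_curvature_method_on_sphere(self, xy_plane, circle_ellipse):
        surf = self._cap_surface(xy_plane)
        roc = mean_roc(surf, circle_ellipse, method="curvature")
        assert roc == pytest.approx(3.0, rel=0.02)

    def test_fit_sphere_exact(self):
        rng = np.random.default_rng(6)
        n = rng.normal(size=(300, 3))
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        pts = np.array([10.0, -5.0, 2.0]) + 700.0 * n
        center, radius = fit_sphere(pts)
        assert radius == pytest.approx(700.0, abs=1e-9)
        assert np.allclose(center, [10.0, -5.0, 2.0], atol=1e-8)


# --------------------------------------------------------------------------
# mean MRW
# --------------------------------------------------------------------------

def _single_scan_eye(bmo, ilm, angle=0.0):
    scans = [
        BScanMarkup(scan_angle_deg=angle, bmo_points=bmo, alcs_points=np.empty((0, 3)),
                    ilm_polyline=ilm)
    ]
    return MarkedONH(eye_id="t", day=0, bscans=scans)


class TestMeanMRW:
    def test_perpendicular_distance_to_horizontal_ilm(self):
        bmo = np.array([[600.0, 0.0, 400.0]])
        ilm = np.column_stack([np.linspace(-1000, 1000, 5), np.full(5, 150.0)])
        assert mean_mrw(_single_scan_eye(bmo, ilm)) == pytest.approx(250.0, abs=1e-9)

    def test_point_on_polyline_contributes_zero(self):
        bmo = np.array([[500.0, 0.0, 100.0]])
        ilm = np.array([[0.0, 100.0], [1000.0, 100.0]])
        assert mean_mrw(_single_scan_eye(bmo, ilm)) == pytest.approx(0.0, abs=1e-12)

    def test_segment_interior_beats_vertices(self):
        # nearest approach lies inside a segment, not at a vertex
        bmo = np.array([[500.0, 0.0, 300.0]])
        ilm = np.array([[0.0, 100.0], [1000.0, 100.0]])
        assert mean_mrw(_single_scan_eye(bmo, ilm)) == pytest.approx(200.0, abs=1e-12)

    def test_jagged_polyline_matches_dense_resampling_oracle(self):
        rng = np.random.default_rng(7)
        marked_scans = []
        oracle_dists = []
        for k in range(12):
            s = np.linspace(-1200, 1200, 200)
            z = 100.0 + 30 * np.sin(s / 90.0) + rng.normal(0, 15.0, 200)
            ilm = np.column_stack([s, z])
            angle = k * 15.0
            theta = math.radians(angle)
            d = np.array([math.cos(theta), math.sin(theta), 0.0])
            for side in (-1, 1):
                s_b = side * rng.uniform(500, 700)
                p = s_b * d + np.array([0.0, 0.0, rng.uniform(350, 450)])
                marked_scans.append((angle, p, ilm))
                # dense 0.01 μm resampling of every segment
                best = np.inf
                for i in range(len(ilm) - 1):
                    seg = ilm[i + 1] - ilm[i]
                    L = np.hypot(*seg)
                    t = np.linspace(0, 1, max(2, int(L / 0.01) + 1))
                    pts = ilm[i] + t[:, None] * seg
                    dmin = np.min(np.hypot(pts[:, 0] - s_b, pts[:, 1] - p[2]))
                    best = min(best, float(dmin))
                oracle_dists.append(best)
        bscans = {}
        for angle, p, ilm in marked_scans:
            bscans.setdefault(angle, {"bmo": [], "ilm": ilm})["bmo"].append(p)
        marked = MarkedONH(
            eye_id="t", day=0,
            bscans=[BScanMarkup(a, np.array(v["bmo"]), np.empty((0, 3)), v["ilm"])
                    for a, v in bscans.items()],
        )
        assert mean_mrw(marked) == pytest.approx(float(np.mean(oracle_dists)), abs=0.05)

    def test_no_usable_scan_raises(self):
        marked = _single_scan_eye(np.empty((0, 3)), np.empty((0, 2)))
        with pytest.raises(DegenerateGeometryError):
            mean_mrw(marked)

    def test_monotone_under_ilm_lowering(self):
        # moving the ILM toward the BMO plane cannot increase the MRW
        bmo = np.array([[600.0, 0.0, 400.0]])
        values = []
        for drop in (0.0, 50.0, 100.0, 150.0):
            ilm = np.column_stack([np.linspace(-1000, 1000, 50),
                                   np.full(50, 150.0) + drop])
            values.append(mean_mrw(_single_scan_eye(bmo, ilm)))
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))


# --------------------------------------------------------------------------
# rigid-motion invariance
# --------------------------------------------------------------------------

def test_rigid_motion_invariance_of_surface_scalars(xy_plane):
    """A rotation + translation of all 3D inputs leaves ALCSD and RoC
    unchanged to numerical precision."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(8)
    bmo_t = np.linspace(0, 2 * math.pi, 16, endpoint=False)
    bmo = np.column_stack([700 * np.cos(bmo_t), 550 * np.sin(bmo_t), np.zeros(16)])
    uv = np.vstack([grid_sites(650, 9), rng.uniform(-600, 600, (60, 2))])
    R_sph = 3000.0
    h = 220.0 - (R_sph - np.sqrt(R_sph**2 - (uv**2).sum(axis=1)))
    alcs = np.column_stack([uv, h])

    def measure(bmo_pts, alcs_pts):
        plane = fit_plane(bmo_pts, orient_toward=alcs_pts)
        ell = fit_bmo_ellipse(bmo_pts, plane)
        surf = fit_tps(alcs_pts, plane)
        alcsd, _ = mean_alcsd(surf, ell)
        roc = mean_roc(surf, ell)
        return alcsd, roc

    a0, r0 = measure(bmo, alcs)
    rot = Rotation.from_euler("xyz", [10, -7, 33], degrees=True).as_matrix()
    shift = np.array([123.0, -456.0, 78.0])
    a1, r1 = measure(bmo @ rot.T + shift, alcs @ rot.T + shift)
    assert a1 == pytest.approx(a0, rel=1e-6)
    assert r1 == pytest.approx(r0, rel=1e-6)


def test_rigid_motion_invariance_of_mrw():
    """Axis rotations relabel scan angles and translations shift the
    per-scan frames; applied coherently they leave the MRW unchanged."""
    rng = np.random.default_rng(9)
    angles = [0.0, 30.0, 60.0, 90.0, 120.0, 150.0]
    scans = []
    for a in angles:
        theta = math.radians(a)
        d = np.array([math.cos(theta), math.sin(theta), 0.0])
        bmo = np.array([s * d + [0, 0, 400.0] for s in (-620.0, 580.0)])
        s_grid = np.linspace(-1000, 1000, 40)
        ilm = np.column_stack([s_grid, 150.0 + 10 * np.sin(s_grid / 200.0)])
        scans.append(BScanMarkup(a, bmo, np.empty((0, 3)), ilm))
    base = MarkedONH("t", 0, scans)
    m0 = mean_mrw(base)

    delta = 30.0  # rotate about the scan axis by one scan increment
    shift = np.array([50.0, -30.0, 25.0])
    moved = []
    rot = np.array([[math.cos(math.radians(delta)), -math.sin(math.radians(delta)), 0],
                    [math.sin(math.radians(delta)), math.cos(math.radians(delta)), 0],
                    [0, 0, 1.0]])
    for scan in scans:
        new_angle = scan.scan_angle_deg + delta
        theta = math.radians(new_angle)
        d = np.array([math.cos(theta), math.sin(theta), 0.0])
        new_bmo = scan.bmo_points @ rot.T + shift
        new_ilm = scan.ilm_polyline + np.array([shift @ d, shift[2]])
        moved.append(BScanMarkup(new_angle, new_bmo, np.empty((0, 3)), new_ilm))
    m1 = mean_mrw(MarkedONH("t", 0, moved))
    assert m1 == pytest.approx(m0, rel=1e-9)
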