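"""Synthetic marked ONH geometries, pore fields and longitudinal studies.

Every stage of the pipeline is testable without imaging data because the
generator emits exactly the inputs the pipeline reads — marked B-scans,
pore polygon annotations, longitudinal parameter series — with known
ground truth. Defaults are calibrated to the summary statistics of the
reference study (see :mod:`onhmorph.reference_data`): normal-eye ALCSD
~214 μm, RoC ~3.6 mm, MRW ~309 μm; pore area ~850 μm², elongation ~1.7,
NND ~40 μm; control-eye visit-to-visit CoV per parameter from the
control-eye repeatability table; EG effect sizes from the reported
first-change and final-change percentages.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .pores import PoreAnnotation
from .types import BScanMarkup, MarkedONH

__all__ = [
    "EyeTruth",
    "PoreFieldTruth",
    "StudyTruth",
    "synth_eye",
    "synth_pore_field",
    "synth_longitudinal_study",
    "SyntheticStudy",
]

POSTERIOR = +1  # heights along the plane normal are positive posterior


class ParameterizationError(ValueError):
    """Raised when the requested ground truth is geometrically infeasible."""


# ==========================================================================
# marked eyes
# ==========================================================================

@dataclass
class EyeTruth:
    """Ground truth for one synthetic eye.

    The ALCS is a spherical cap (so the true radius of curvature is exact
    by construction) positioned so its mean depth below the BMO plane over
    the BMO-ellipse interior equals ``alcsd_um``. The ILM is built per
    B-scan as a rim line offset so the minimum BMO→ILM distance is exactly
    ``mrw_um``. Marking noise is isotropic Gaussian on every marked point.
    """

    alcsd_um: float = 214.0
    roc_mm: float = 3.6
    mrw_um: float = 308.7
    bmo_a_um: float = 800.0  # BMO ellipse semi-major
    bmo_b_um: float = 600.0  # BMO ellipse semi-minor
    tilt_deg: float = 5.0  # BMO plane tilt about the y axis
    ellipse_angle_deg: float = 20.0  # major-axis direction within the plane
    noise_um: float = 0.0  # marking noise σ
    n_bscans: int = 48  # radial pattern of the acquisition (20° field)
    alcs_per_scan: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alcsd_um, self.roc_mm, self.mrw_um, self.bmo_a_um, self.bmo_b_um) <= 0:
            raise ValueError("all truth magnitudes must be positive")
        if self.noise_um < 0:
            raise ValueError("noise must be non-negative")


def _cap_mean_sag(r_um: float, a: float, b: float, n: int = 256) -> float:
    """Mean of sqrt(R² − ρ²) over the ellipse interior (numeric)."""
    x = np.linspace(-a, a, n)
    y = np.linspace(-b, b, n)
    xx, yy = np.meshgrid(x, y)
    mask = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    rho2 = xx[mask] ** 2 + yy[mask] ** 2
    return float(np.mean(np.sqrt(r_um * r_um - rho2)))


def synth_eye(truth: EyeTruth, eye_id: str = "synth", day: int = 0) -> MarkedONH:
    """Generate a marked ONH whose fitted parameters recover the truth.

    Geometry: the BMO ring is an ellipse in a plane tilted by ``tilt_deg``;
    48 radial B-scans through the ONH axis each intersect the ring twice
    (those are the BMO points) and sample the spherical-cap ALCS along the
    scan's trace; the ILM is a rim polyline whose perpendicular distance
    from each BMO point equals the target MRW.
    """
    rng = np.random.default_rng(truth.seed)
    tau = math.radians(truth.tilt_deg)
    psi = math.radians(truth.ellipse_angle_deg)
    # plane frame: normal tilted about y; posterior = +z side
    n_vec = np.array([math.sin(tau), 0.0, math.cos(tau)])
    u1 = np.array([math.cos(tau), 0.0, -math.sin(tau)])
    u2 = np.array([0.0, 1.0, 0.0])
    e_maj = math.cos(psi) * u1 + math.sin(psi) * u2
    e_min = -math.sin(psi) * u1 + math.cos(psi) * u2

    a, b = truth.bmo_a_um, truth.bmo_b_um
    r_sphere = truth.roc_mm * 1000.0
    if r_sphere <= max(a, b):
        raise ParameterizationError(
            f"cap radius {truth.roc_mm} mm cannot cover a BMO semi-axis of {max(a, b)} μm"
        )
    # apex depth so that the mean cap depth over the ellipse equals ALCSD
    d0 = truth.alcsd_um + r_sphere - _cap_mean_sag(r_sphere, a, b)

    def cap_height(rho2: np.ndarray) -> np.ndarray:
        return d0 - r_sphere + np.sqrt(r_sphere * r_sphere - rho2)

    def to3d(xi: np.ndarray, eta: np.ndarray, h: np.ndarray) -> np.ndarray:
        plane_xy = np.outer(xi, e_maj) + np.outer(eta, e_min)
        return plane_xy + np.outer(h, n_vec * POSTERIOR)

    bscans: list[BScanMarkup] = []
    angles = np.arange(truth.n_bscans) * (180.0 / truth.n_bscans)
    for theta_deg in angles:
        theta = math.radians(theta_deg)
        d_scan = np.array([math.cos(theta), math.sin(theta), 0.0])
        m = np.array([-math.sin(theta), math.cos(theta), 0.0])  # scan-plane normal

        # BMO ring ∩ scan plane: solve α cos φ + β sin φ = 0 on the ellipse
        alpha = a * float(e_maj @ m)
        beta = b * float(e_min @ m)
        phi0 = math.atan2(-alpha, beta)
        bmo3d = []
        for phi in (phi0, phi0 + math.pi):
            xi = a * math.cos(phi)
            eta = b * math.sin(phi)
            p = to3d(np.array([xi]), np.array([eta]), np.array([0.0]))[0]
            bmo3d.append(p)
        bmo3d = np.array(bmo3d) + rng.normal(0.0, truth.noise_um, (2, 3))

        # ALCS samples along the scan trace in the plane, within the ring
        t_dir = np.array([float(e_min @ m), -float(e_maj @ m)])
        t_dir /= np.linalg.norm(t_dir)
        # ellipse radius along t_dir (ellipse frame): 1/sqrt((c/a)² + (s/b)²)
        r_t = 1.0 / math.sqrt((t_dir[0] / a) ** 2 + (t_dir[1] / b) ** 2)
        rho = np.linspace(-r_t, r_t, truth.alcs_per_scan)
        xi, eta = rho * t_dir[0], rho * t_dir[1]
        h = cap_height(xi**2 + eta**2)
        alcs3d = to3d(xi, eta, h) + rng.normal(0.0, truth.noise_um, (len(rho), 3))

        # ILM rim line: offset below (anterior to) the BMO chord so the
        # perpendicular distance from each BMO point is exactly the MRW
        s_bmo = bmo3d @ d_scan
        z_bmo = bmo3d[:, 2]
        slope = (z_bmo[1] - z_bmo[0]) / (s_bmo[1] - s_bmo[0])
        offset = truth.mrw_um * math.sqrt(1.0 + slope * slope)
        s_line = np.linspace(-2.0 * max(a, b), 2.0 * max(a, b), 61)
        z_line = z_bmo[0] + slope * (s_line - s_bmo[0]) - offset
        ilm = np.column_stack([s_line, z_line])
        ilm[:, 1] += rng.normal(0.0, truth.noise_um, len(ilm))

        bscans.append(BScanMarkup(scan_angle_deg=theta_deg, bmo_points=bmo3d,
                                  alcs_points=alcs3d, ilm_polyline=ilm))
    return MarkedONH(eye_id=eye_id, day=day, bscans=bscans)


# ==========================================================================
# pore fields
# ==========================================================================

@dataclass
class PoreFieldTruth:
    """Ground truth for a synthetic pore field on the BMO plane.

    Pores sit on a jittered hexagonal lattice (so the NND ground truth is
    the lattice spacing), rendered as ellipses with a target moment
    elongation and random orientation. Log-areas are a smooth spatial
    Gaussian field scaled by ``clustering`` plus independent noise, so
    ``clustering=0`` yields a spatially random area pattern and large
    values a patchy, positively autocorrelated one.
    """

    n_pores: int = 80
    mean_area_um2: float = 850.0
    elongation: float = 1.7
    spacing_um: float = 40.0  # lattice spacing = NND target
    clustering: float = 0.0  # SD of the spatial log-area field component
    area_log_sd: float = 0.25  # independent log-area noise
    elong_log_sd: float = 0.10  # per-pore spread of (elongation − 1)
    jitter_um: float = 1.0
    field_length_um: float = 120.0  # correlation length of the spatial field
    coverage_center: tuple[float, float] = (0.0, 0.0)
    coverage_radius_um: float = 450.0
    n_vertices: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        eq_r = math.sqrt(self.mean_area_um2 / math.pi)
        if self.spacing_um <= 2.0 * eq_r:
            raise ValueError("lattice spacing must exceed the pore diameter (no overlap)")

    def coverage_polygon(self) -> Polygon:
        return Point(self.coverage_center).buffer(self.coverage_radius_um, quad_segs=64)


def _hex_lattice(truth: PoreFieldTruth) -> np.ndarray:
    s = truth.spacing_um
    cx, cy = truth.coverage_center
    r = truth.coverage_radius_um + s
    ny = int(math.ceil(2 * r / (s * math.sqrt(3) / 2))) + 2
    nx = int(math.ceil(2 * r / s)) + 2
    pts = []
    for iy in range(-ny, ny + 1):
        y = cy + iy * s * math.sqrt(3) / 2.0
        x_off = (iy % 2) * s / 2.0
        for ix in range(-nx, nx + 1):
            pts.append((cx + ix * s + x_off, y))
    pts = np.array(pts)
    poly = truth.coverage_polygon()
    inside = np.array([poly.covers(Point(p)) for p in pts])
    pts = pts[inside]
    order = np.argsort(((pts - [cx, cy]) ** 2).sum(axis=1), kind="stable")
    return pts[order]


def synth_pore_field(
    truth: PoreFieldTruth,
) -> tuple[list[PoreAnnotation], dict]:
    """Generate pore polygon annotations plus their ground-truth labels.

    Annotations are in BMO-plane (u, v) μm with identity registration, so
    they can be lifted directly onto any surface whose domain covers the
    coverage polygon. Returns ``(annotations, truth_labels)`` where the
    labels carry the per-pore centers, areas and the latent spatial field.
    """
    rng = np.random.default_rng(truth.seed)
    centers = _hex_lattice(truth)
    if len(centers) < truth.n_pores:
        raise ValueError(
            f"coverage polygon holds only {len(centers)} lattice sites; "
            f"{truth.n_pores} pores requested (infeasible density)"
        )
    centers = centers[: truth.n_pores].astype(float)
    centers = centers + rng.normal(0.0, truth.jitter_um, centers.shape)
    n = len(centers)

    # smooth spatial log-area field (squared-exponential covariance)
    if truth.clustering > 0:
        d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        cov = np.exp(-d2 / (2.0 * truth.field_length_um**2)) + 1e-8 * np.eye(n)
        L = np.linalg.cholesky(cov)
        fld = L @ rng.standard_normal(n)
        fld = truth.clustering * (fld - fld.mean()) / (fld.std() or 1.0)
    else:
        fld = np.zeros(n)
    eps = rng.normal(0.0, truth.area_log_sd, n)
    total_var = truth.clustering**2 + truth.area_log_sd**2
    log_area = math.log(truth.mean_area_um2) - total_var / 2.0 + fld + eps
    areas = np.exp(log_area)

    t = np.linspace(0.0, 2.0 * math.pi, truth.n_vertices, endpoint=False)
    annotations: list[PoreAnnotation] = []
    radii: list[float] = []  # accepted semi-major axes, for a cheap overlap pre-check
    final_areas = np.empty(n)
    for i in range(n):
        ok = False
        for _ in range(50):
            q = 1.0 + (truth.elongation - 1.0) * math.exp(
                rng.normal(-truth.elong_log_sd**2 / 2.0, truth.elong_log_sd)
            )
            beta = math.sqrt(areas[i] / (math.pi * q))
            alpha = q * beta
            ang = rng.uniform(0.0, math.pi)
            c, s = math.cos(ang), math.sin(ang)
            verts = np.column_stack([alpha * np.cos(t), beta * np.sin(t)]) @ np.array(
                [[c, s], [-s, c]]
            ) + centers[i]
            # non-overlap by rejection against already accepted pores
            clear = True
            for j in range(len(annotations)):
                if np.linalg.norm(centers[i] - centers[j]) < alpha + radii[j]:
                    if Polygon(verts).intersects(Polygon(annotations[j].polygon_2d)):
                        clear = False
                        break
            if clear:
                ok = True
                break
            areas[i] *= 0.9  # shrink slightly and retry
        if not ok:
            raise ValueError("could not place a non-overlapping pore (infeasible density)")
        radii.append(alpha)
        final_areas[i] = areas[i]
        annotations.append(PoreAnnotation(pore_id=f"p{i:03d}", polygon_2d=verts))

    labels = {
        "centers": centers,
        "areas": final_areas,
        "field": fld,
        "spacing": truth.spacing_um,
    }
    return annotations, labels


# ==========================================================================
# longitudinal studies
# ==========================================================================

#: Control-eye baselines and visit-to-visit CoV (%), from the reference
#: study's control-eye repeatability table.
DEFAULT_BASELINES = {"alcsd": 214.0, "roc": 3.6, "mrw": 308.7, "rnflt": 105.6}
DEFAULT_COV = {"alcsd": 4.5, "roc": 21.7, "mrw": 2.3, "rnflt": 1.7}
#: Fractional change at the first significant time-point and at study end.
DEFAULT_FIRST_MAG = {"alcsd": +0.38, "roc": -0.55, "mrw": -0.19, "rnflt": -0.13}
DEFAULT_FINAL_MAG = {"alcsd": +1.33, "roc": -0.70, "mrw": -0.61, "rnflt": -0.34}
#: Injected onset order matches the observed sequencing: ALCSD earliest,
#: then MRW, pore geometry, RoC, RNFLT last.
DEFAULT_ONSETS = {"alcsd": 112, "mrw": 168, "pores": 224, "roc": 280, "rnflt": 336}

PARTITIONS = ("central", "peripheral", "superotemporal", "temporal", "inferotemporal")
#: Partition-level pore baselines (area μm², elongation, NND μm).
PORE_BASE = {
    "central": {"area": 801.9, "elongation": 1.72, "nnd": 36.1},
    "peripheral": {"area": 920.6, "elongation": 1.77, "nnd": 39.5},
    "superotemporal": {"area": 919.2, "elongation": 1.69, "nnd": 42.0},
    "temporal": {"area": 823.3, "elongation": 1.81, "nnd": 36.6},
    "inferotemporal": {"area": 961.9, "elongation": 1.63, "nnd": 40.4},
}
#: Fractional pore-parameter change at the first time-point of change.
PORE_EFFECT = {
    "central": {"area": +0.236, "elongation": 0.0, "nnd": +0.116},
    "peripheral": {"area": +0.299, "elongation": 0.0, "nnd": +0.224},
    "superotemporal": {"area": +0.241, "elongation": 0.0, "nnd": +0.132},
    "temporal": {"area": +0.355, "elongation": 0.0, "nnd": +0.171},
    "inferotemporal": {"area": +0.091, "elongation": 0.0, "nnd": +0.002},
}


def _default_days() -> np.ndarray:
    # four pre-laser imaging sessions (multiple baselines are standard in
    # longitudinal primate protocols, and the change-onset intervals need
    # honest degrees of freedom), then visits every two weeks for ~18 months
    return np.concatenate([[-42.0, -28.0, -14.0], np.arange(0.0, 533.0, 14.0)])


@dataclass
class StudyTruth:
    """Ground truth for one synthetic control/EG eye pair.

    ``onset_days`` maps parameter name (alcsd, mrw, roc, rnflt, pores) to
    the injected day of first change; an onset beyond the last visit makes
    the parameter never change (exercising censoring). EG trajectories
    jump to the first-change magnitude at onset and saturate exponentially
    (time constant ``tau_days``) toward the final magnitude, matching a
    study design in which the parameter is already clearly abnormal at its
    first significant visit and keeps progressing; ``trajectory='step'``
    holds the first-change magnitude instead. Visit noise is
    multiplicative with SD = CoV/100 × the current level.
    """

    days: np.ndarray = field(default_factory=_default_days)
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    cov_percent: dict = field(default_factory=lambda: dict(DEFAULT_COV))
    onset_days: dict = field(default_factory=lambda: dict(DEFAULT_ONSETS))
    first_magnitude: dict = field(default_factory=lambda: dict(DEFAULT_FIRST_MAG))
    final_magnitude: dict = field(default_factory=lambda: dict(DEFAULT_FINAL_MAG))
    tau_days: float = 100.0
    trajectory: str = "jump_saturate"  # or "step"
    noise_scale: float = 1.0  # multiplies every CoV (0 = noiseless study)
    iop_ctl_mean: float = 13.2
    iop_ctl_sd: float = 2.0
    iop_eg_mean: float = 28.0
    iop_eg_sd: float = 10.0
    iop_eg_range: tuple[float, float] = (14.0, 52.0)
    n_pores_per_partition: int = 25
    #: CV of the per-visit partition mean. Montage/segmentation noise hits
    #: measured areas hardest; pore shape is nearly invariant to it.
    pore_visit_cov: dict = field(default_factory=lambda: {
        "area": 0.05, "elongation": 0.015, "nnd": 0.03})
    pore_area_log_sd: float = 0.6  # within-partition per-pore spread
    pore_elong_log_sd: float = 0.25
    pore_nnd_sd: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("visit schedule must be strictly increasing")
        if self.days[0] > 0:
            raise ValueError("schedule needs at least one pre-laser visit")
        if self.trajectory not in ("jump_saturate", "step"):
            raise ValueError("trajectory must be 'jump_saturate' or 'step'")


@dataclass
class SyntheticStudy:
    """Generated control/EG pair plus pore observations and the truth."""

    control: "StudySeries"  # type: ignore[name-defined]
    eg: "StudySeries"  # type: ignore[name-defined]
    pore_values: dict  # day -> partition -> parameter -> per-pore values (EG eye)
    truth: StudyTruth


def _effect(t: np.ndarray, onset: float, first: float, final: float,
            tau: float, trajectory: str) -> np.ndarray:
    """Fractional change vs baseline at times ``t`` for one parameter."""
    out = np.zeros_like(t)
    after = t >= onset
    if trajectory == "step":
        out[after] = first
    else:
        growth = 1.0 - np.exp(-(t[after] - onset) / tau)
        out[after] = first + (final - first) * growth
    return out


def synth_longitudinal_study(truth: StudyTruth, eye_id: str = "synth") -> SyntheticStudy:
    """Generate one fellow-eye pair: a stable control and a progressing EG
    eye, with per-visit pore observations for the EG eye.

    Pore observations are per-pore parameter values per partition; their
    per-visit partition mean is exactly the target level times the visit
    noise factor (the per-pore scatter is mean-centred within each visit),
    so the partition-mean CV is the stated ``pore_visit_cov``.
    """
    from .longitudinal import StudySeries  # local import to avoid a cycle

    rng = np.random.default_rng(truth.seed)
    days = truth.days
    n = len(days)
    params = ("alcsd", "roc", "mrw", "rnflt")

    def noisy(level: np.ndarray, cov_pct: float) -> np.ndarray:
        sd = truth.noise_scale * cov_pct / 100.0
        return level * (1.0 + sd * rng.standard_normal(len(level)))

    ctl_values = {
        p: noisy(np.full(n, truth.baselines[p]), truth.cov_percent[p]) for p in params
    }
    eg_values = {}
    for p in params:
        onset = float(truth.onset_days.get(p, math.inf))
        eff = _effect(days, onset, truth.first_magnitude[p], truth.final_magnitude[p],
                      truth.tau_days, truth.trajectory)
        eg_values[p] = noisy(truth.baselines[p] * (1.0 + eff), truth.cov_percent[p])

    post = days >= 0
    iop_ctl = np.full(n, np.nan)
    iop_eg = np.full(n, np.nan)
    iop_ctl[post] = rng.normal(truth.iop_ctl_mean, truth.noise_scale * truth.iop_ctl_sd,
                               post.sum())
    iop_eg[post] = np.clip(
        rng.normal(truth.iop_eg_mean, truth.noise_scale * truth.iop_eg_sd, post.sum()),
        *truth.iop_eg_range,
    )
    iop_ctl[~post] = truth.iop_ctl_mean
    iop_eg[~post] = truth.iop_ctl_mean  # pre-laser: both eyes normotensive

    control = StudySeries(eye_id=f"{eye_id}-ctl", role="control", days=days,
                          values=ctl_values, iop=iop_ctl)
    eg = StudySeries(eye_id=f"{eye_id}-eg", role="EG", days=days,
                     values=eg_values, iop=iop_eg)

    # ---- pore observations (EG eye) ----
    pore_onset = float(truth.onset_days.get("pores", math.inf))
    k = truth.n_pores_per_partition
    pore_values: dict[float, dict[str, dict[str, np.ndarray]]] = {}
    for d in days:
        by_part: dict[str, dict[str, np.ndarray]] = {}
        for part in PARTITIONS:
            base = PORE_BASE[part]
            eff = PORE_EFFECT[part]
            entry: dict[str, np.ndarray] = {}
            for pname in ("area", "elongation", "nnd"):
                frac = _effect(np.array([d]), pore_onset, eff[pname], eff[pname],
                               truth.tau_days, "step")[0]
                level = base[pname] * (1.0 + frac)
                visit_factor = 1.0 + truth.noise_scale * truth.pore_visit_cov[pname] \
                    * rng.standard_normal()
                target_mean = level * visit_factor
                if pname == "area":
                    draw = np.exp(rng.normal(0.0, truth.noise_scale
                                             * truth.pore_area_log_sd, k))
                elif pname == "elongation":
                    draw = 1.0 + np.exp(rng.normal(0.0, truth.noise_scale
                                                   * truth.pore_elong_log_sd, k))
                else:
                    draw = np.clip(1.0 + truth.noise_scale * truth.pore_nnd_sd
                                   / base["nnd"] * rng.standard_normal(k), 0.05, None)
                # mean-centre the scatter so the visit mean is exactly on target
                entry[pname] = target_mean * draw / draw.mean()
            by_part[part] = entry
        pore_values[float(d)] = by_part

    return SyntheticStudy(control=control, eg=eg, pore_values=pore_values, truth=truth)
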