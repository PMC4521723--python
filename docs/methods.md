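# Methods

`onhmorph` quantifies optic nerve head (ONH) and anterior lamina cribrosa
surface (ALCS) structure from manually marked imaging data, and detects
when each structural parameter first departs from its normal range in a
longitudinal unilateral experimental-glaucoma (EG) design. This note
records the models, the defaults and why, and what the synthetic-data
generator does and does not emulate.

## Geometric model

**Reference plane.** The Bruch's membrane opening (BMO) termination
points, marked on radial B-scans, define the reference frame. The plane is
fit by orthogonal (total) least squares — the smallest principal component
of the centred point scatter — because the points come from radial scans
at all orientations and no axis is privileged. The normal is oriented so
the marked ALCS points have positive mean height: heights are positive
*posterior*, so a deeper lamina means a larger ALCSD.

**BMO ellipse.** The BMO points projected into the plane are fit with the
Halir–Flusser direct least-squares conic constrained to an ellipse. Before
that, the unconstrained best-fit conic is checked: if its discriminant is
non-negative (the data sample a parabola/hyperbola), the fit refuses
rather than force an ellipse through non-elliptical data.

**ALCS surface.** A thin-plate spline (TPS) height field h(u, v) over the
plane interpolates the marked ALCS points: affine part plus kernel
r² log r, with the classical side conditions (weights and their first
moments sum to zero). λ = 0 (exact interpolation) is the default because
the surface is fit *through* marked points; λ > 0 is available for noisy
synthetic experiments. The linear system is assembled on unit-scale
coordinates (the λ = 0 interpolant is equivariant under that rescaling),
which keeps the system well-conditioned at μm scales; λ is therefore
interpreted in the normalized frame. Duplicate (u, v) sites within 1 μm
are merged by averaging heights to avoid singular systems.

**Derived scalars.**

* *Mean ALCSD* — mean TPS height over a grid masked to the BMO-ellipse
  interior (default 128×128; converges to < 0.1 μm against 256×256 on
  smooth surfaces). The ellipse interior was chosen as the averaging
  domain for consistency with the curvature domain; the full control-site
  hull is available by configuration. If part of the grid leaves the
  convex hull of the control sites (grown by a 50 μm margin), an
  extrapolation flag is recorded with the value.
* *Mean RoC* — radius of a least-squares sphere fit to the 3D surface
  samples inside the ellipse. The fit is seeded by a rotationally
  symmetric quadric (h ≈ c₀ + c₁u + c₂v + κρ²/2) and refined with
  Gauss–Newton on the geometric residuals; without the quadric seed, the
  algebraic sphere fit collapses onto a meaningless in-surface circle for
  planar data. Surfaces with |κ| below 1/50 mm⁻¹, or a fitted radius
  above 50 mm, return a "flat" sentinel (infinite radius): the radius of
  a flat surface diverges and its sample variance explodes, so a sentinel
  is more honest than a huge number. A pointwise mean-curvature
  alternative (analytic TPS derivatives) is provided as
  `method="curvature"`; the sphere fit is the default because a single
  robust scalar matches how the quantity is reported.
* *Mean MRW* — for every BMO point, the minimum Euclidean distance to the
  internal limiting membrane polyline *within its own B-scan plane*
  (minimum over segments, not vertices), averaged over all BMO points of
  all B-scans. The 2D per-scan definition matches how the markings are
  made; no 3D ILM surface is reconstructed. Radial scans are assumed to
  share a common axis through the eye-frame origin; the in-scan lateral
  coordinate of a 3D point is its projection on (cos θ, sin θ, 0).

Units are μm internally everywhere; RoC is reported in mm. Indexing is
0-based in all files.

## Pore morphometry

2D pore polygons (montage pixels) are mapped by a similarity transform
into the plane frame, edges subdivided to ≤ 10 μm (halving this changes
areas < 0.2%), and vertices lifted onto the TPS surface. Per pore:

* *area* — fan triangulation of the lifted polygon, triangle signs taken
  from the 2D orientation (exact for convex outlines, sign-consistent for
  mildly non-convex ones); 3D area ≥ projected area always.
* *elongation* — √(λ₁/λ₂) of the second central *area* moments of the
  polygon in its own best-fit plane; 1 = circle, a/b for an ellipse. The
  moment definition was chosen because it is the standard moment-matched
  ellipse and reproduces the reported range (~1.5–1.9).
* *NND* — 3D Euclidean distance between area-weighted centroids (at
  R ≈ 3 mm and NND ≈ 40 μm the geodesic correction is < 0.01%). No edge
  correction: pores at the montage boundary bias NND slightly high,
  matching the acquisition situation.

Partitions: the central region is the concentric ellipse with semi-axes
scaled by 1/√2 (exactly half the area); sectors are 60° wedges from the
temporal end of the major axis (temporal ±30°, superotemporal to +90°,
inferotemporal to −90°), mirrored for left eyes; everything nasal is kept
as "other" so nasal data is representable even though the reference
analyses covered only the temporal half.

## Spatial statistics

* `cluster_bins`: exhaustive search over all ordered threshold pairs on
  the sorted values; the default objective maximises the *minimum* of the
  two adjacent bin-mean gaps ("each bin maximally separated from the next
  nearest"), with the gap-sum as an option. Ties prefer the more balanced
  partition, then lower thresholds. Thresholds are constrained to
  observed values (cuts never split ties).
* `morans_i`: I = (n/S₀)·Σ wᵢⱼ zᵢzⱼ / Σ zᵢ² with wᵢᵢ = 0. Default
  weights are inverse distance — the common default of distance-based
  implementations, since the original analysis environment is not
  specified — with binary k-NN and user matrices as options, and the
  choice recorded in the result. Inference: two-sided permutation p with
  (count+1)/(n_perm+1), default 999 seeded permutations, plus the
  normality-assumption analytic p for cross-checking.
* `rank_sum_test`: Mann–Whitney U with midranks; exact enumeration when
  n₁+n₂ ≤ 12 without ties, else tie-corrected normal approximation with
  continuity correction (scipy backend). Two-sided, α = .05 throughout;
  no multiple-comparison correction is applied anywhere, matching the
  reference analysis.

## Longitudinal analysis

**Control variability.** Per control eye and parameter: mean, SD (n−1),
CoR = 1.96·SD·√2, CoV = 100·SD/mean. The "95% interval" is mean ± 1.96·SD
— a tolerance interval for a single new observation — not ± 1.96·SE: the
onset rule compares *individual* EG visits against it, and an SE band
would shrink with visit count and flag normal fluctuation. SE-style
intervals remain available by configuration.

**First change.** The onset is the earliest visit outside the interval
with *no later visit returning inside*; otherwise censored at the last
visit. The rule is re-evaluated over the whole series on every call, so
appending an in-interval visit retracts a previously declared onset. A
relative tolerance of 1e-9 treats values equal to a bound (within float
error) as inside, which matters only for degenerate zero-width intervals.
An eye without a usable fellow control is analysed against the interval
of the pooled values of all other control eyes.

**Pore-geometry onset.** Pores lack a fellow-eye reference at matched
locations, so the reference is built from the eye's own early visits:
(1) the baseline set grows forward while every pore parameter, pooled
across the partitions shared with baseline, is rank-sum non-significant
against the pooled baseline pores (three tests per visit — testing every
parameter × partition separately, 15 tests at α = .05, would stop the
growth almost surely at the first follow-up and leave the interval SD
with ~3 degrees of freedom); (2) 95% intervals are mean ± 1.96·SD of the
baseline per-visit *means*, per parameter × partition; (3) the eye-level
onset is the minimum over parameter × partition of the first sustained
excursion. Partitions absent at a visit are skipped, and comparisons are
made only for partitions present both at the visit and at baseline.

**Sequencing.** Onset days are dense-ranked within each eye (ties share a
position; censored parameters are unranked) and positions averaged across
eyes. Event-based Kaplan–Meier curves (right-censored at the last visit)
and pairwise two-group log-rank tests (lifelines) compare parameters; a
global multi-group test is optional since the original description is
ambiguous between the two.

**IOP dose.** Cumulative IOP difference integrates each eye's IOP by the
trapezoid rule from day 0 (first laser) and subtracts control from EG,
interpolating linearly to the union of visit days first; it is additive
over intervals and antisymmetric under swapping eyes.

Printed tables are rounded half-up to one decimal, with a pre-round six
decimals below the target to absorb binary float error.

## Synthetic data: the stated world

The generator emits exactly the inputs the pipeline reads, with known
ground truth, calibrated once to the reference study's summary statistics
(bundled in `onhmorph.reference_data`):

* **Eyes** — a BMO ellipse (800 × 600 μm semi-axes) in a plane tilted 5°;
  48 radial B-scans; the ALCS is a *spherical cap* (so true RoC is exact
  by construction) positioned so its mean depth over the ellipse equals
  the target ALCSD; the ILM is a per-scan rim line offset so the
  perpendicular BMO→ILM distance is exactly the target MRW; isotropic
  Gaussian marking noise on every point. 17 ALCS points per scan by
  default: sparser marking leaves visible TPS interpolation bias in RoC
  (≈1.4% at 9 points/scan, ≈0.2% at 17). Defaults target the normal-eye
  means (ALCSD 214 μm, RoC 3.6 mm, MRW 308.7 μm).
* **Pore fields** — a jittered hexagonal lattice (spacing = NND ground
  truth, default 40 μm) of elliptical pores (mean area 850 μm², moment
  elongation 1.7) with log-areas driven by a smooth Gaussian spatial
  field scaled by a clustering strength (0 = spatially random) plus
  independent noise; non-overlap by rejection. Note the *measured* mean
  NND sits slightly below the spacing under jitter (the minimum over ~6
  equidistant neighbours is an order statistic; ≈ −1.3·σ√2 ≈ 1.7 μm at
  σ = 1 μm).
* **Studies** — control series are constant with multiplicative visit
  noise at the reference CoV levels (ALCSD 4.5%, RoC 21.7%, MRW 2.3%,
  RNFLT 1.7%); EG series jump to the reported first-change magnitude at
  the injected onset (+38% ALCSD, −55% RoC, −19% MRW, −13% RNFLT) and
  saturate exponentially (τ = 100 d) toward the reported final magnitude
  (+133%, −70%, −61%, −34%). The jump-then-saturate shape is the only one
  consistent with the parameter already being clearly abnormal at its
  first significant visit. Noise is multiplicative (SD = CoV × level)
  because CoV is a relative quantity and measurement scatter of, e.g., a
  curvature radius scales with its magnitude. IOP: control ≈ 13.2 mmHg,
  EG ≈ 28 mmHg with excursions to ~50, giving cumulative differences of
  the reported magnitude (≈7,500 mmHg·days over 500 days). Pore
  observations per visit carry per-partition effects from the reported
  first-change percentages (area +24…+36%, NND +0…+22%, elongation ~0),
  per-visit mean noise (area 5%, elongation 1.5%, NND 3%) and per-pore
  scatter that is mean-centred within each visit so the partition-mean CV
  is exactly the stated value. Three pre-laser visits plus day 0 give the
  onset intervals honest degrees of freedom.

What the generator does **not** emulate: real marking biases (systematic
under/over-calling of BMO terminations), montage coverage that varies
across visits (partitions are always present unless configured
otherwise), pore birth/death and correspondence across visits, speckle or
optics, and non-spherical lamina shapes. A green recovery test therefore
establishes that the estimators are unbiased and stable under the stated
noise — not that they are robust to every failure mode of real imaging.

## Known limitations and numerical notes

* RoC onset detection is the least reliable (≈83% within one visit over
  40 seeds at reference noise): the −55% effect is only ≈1.3 reference
  SDs beyond the interval at CoV 21.7%, so the no-return clause
  legitimately delays some detections. This mirrors the measured
  real-world variability of curvature on near-flat laminas.
* A stationary series yields a (false) onset in ≈5% of runs at the final
  visit: an outside last visit is trivially "sustained" because nothing
  after it can return. This is structural to the rule, not a bug; the
  censoring rate ceiling is ≈94.5%, not the nominal 95%.
* The fan-triangulation area is exact for convex pores; strongly
  non-convex outlines would need a constrained triangulation.
* Moran's inverse-distance weights are dense (O(n²)); fields beyond a few
  thousand pores would need sparse k-NN weights.
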