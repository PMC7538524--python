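# Methods

## Problem and scope

`cortimap` measures the cortical (compact) bone thickness of the tibial
diaphysis from clinical-resolution CT (in-plane pixels ≈ 0.7–0.8 mm, 1 mm
slice interval) and summarizes it over 12 standardized anatomical regions, the
layout used for regional reference data in long-bone morphometry.  At this
resolution a 1–5 mm cortex spans only a handful of voxels and naive
thresholding or full-width measures are badly biased; the package therefore
estimates thickness by model-based fitting of CT intensity profiles (cortical
bone mapping, CBM), which is accurate well below the voxel scale.

The pipeline is: synthetic phantom or CT volume → sub-pixel outer surface →
per-vertex profile fits → anatomical tibial frame → 12-region summaries →
group/reliability statistics.

## Image model and thickness estimation

At each surface vertex, HU values are sampled by trilinear interpolation along
a line through the vertex, perpendicular to the cortex (along the full 3-D
outward surface normal; positions increase inward, 0 at the vertex).  The
samples are fit with a blurred three-level density model

    m(x) = y0 + (y1 − y0)·Φ((x − x0)/σ) + (y2 − y1)·Φ((x − x1)/σ)

with Φ the standard normal CDF; `y0`, `y1`, `y2` are the background, cortical
and trabecular densities (HU), `x0`/`x1` the periosteal/endosteal edges (mm),
`σ` the imaging blur (mm), and the thickness is `t = x1 − x0`.  This is the
minimal model consistent with a constant-density cortex imaged by a scanner
with an approximately Gaussian point-spread function.

The fit is bounded nonlinear least squares (`scipy.optimize.least_squares`,
analytic Jacobian), parameterized in `(x0, t)` with `t > 0` so the edges can
never invert.  Initialization: edge positions from the extreme gradients of
the profile, plateau levels from the profile tails, `σ` from the voxel size.
A fit fails on non-convergence (200 function evaluations), a cortical level
not exceeding both plateaus, an edge pinned at a bound, or a periosteal edge
further than 3 mm from the vertex (the last rule also breaks ties when more
than one edge pair is plausible — the pair bracketing the vertex is kept).

When the cortex is thinner than roughly the blur width, `y1` and `t` are
jointly unidentifiable and the free fit overestimates `t`.  The map is
therefore computed in two passes: free fits everywhere; a global cortical
density taken as the median `y1` over free fits with `t > 3σ_fit` (edges
separated well beyond the blur resolve the plateau; at least 50 such fits are
required by default); then density-constrained refits with `y1` fixed.  If a
constrained refit fails where the free fit succeeded, the free fit is kept
rather than dropping the vertex.  Per-vertex failures are flagged invalid and
never abort the map.

Defaults: profile half-length 9 mm, step 0.25 mm, σ initialized at 0.5 mm.
Profiles are sampled along the 3-D normal, so obliquity on a tapering shaft
is intrinsic to the measurement rather than corrected post hoc.

## Surface extraction

The outer cortical boundary is contoured per transverse slice with marching
squares at sub-pixel precision (linear interpolation of the iso-level along
pixel edges).  The default iso-level is the midpoint between the robust
background and cortex modes (medians of the two Otsu classes), always
overridable.  Open contours and components smaller than 20 mm² are dropped
and the largest component per slice is retained — an automated replacement
for interactive contour editing.  Contours are resampled at uniform polar
angles (valid for the star-shaped diaphyseal cross-sections in scope),
stacked into a triangulated tube, capped, and decimated (slice stride plus
ring density) so a full-length tibia yields 5 000–9 000 measurement vertices,
the point density the regional summaries are calibrated to.  Normals are
area-weighted averages of incident tube triangles, oriented outward; the two
cap apexes are flagged and excluded from measurement.

## Anatomical tibial frame

Least-squares (Kåsa) circles are fit to the outer cross-sections at two
height fractions of the shaft (default 30% and 70% of the extent along the
surface's principal axis, bracketing the diaphysis); the line through their
centers is the temporal long axis, oriented superior.  The y-axis is the unit
vector from the posterior-cruciate-ligament attachment to the medial edge of
the tibial tuberosity (positive anterior).  Then x = ŷ × ẑ_temp (positive
toward the patient's right in an RAS-oriented patient space) and the true
z = x̂ × ŷ, giving a right-handed orthonormal triad that preserves y exactly
and keeps z within the plane of the temporal axis.  A literal reading of the
cross-product operand order alone cannot satisfy all three stated positive
directions with a right-handed triad, so the positive directions are treated
as the contract and the signs chosen to enforce them.  The origin is where
the true-z line through the distal circle center exits the distal end of the
segmented bone (articular cartilage is not segmented).  Construction fails
explicitly if the temporal axis is within 10° of the y-axis.

## Regions and standardization

Tibial length is the straight-line distance from the midpoint of the tibial
eminences to the midpoint of the medial and lateral points on the talar dome.
Height fractions are measured along the frame z-coordinate from the talar
dome midpoint (straight-line, not arc length).  Bands are half-open:
distal [30%, 43%), central [43%, 57%), proximal [57%, 70%]; outside the
30–70% diaphysis no label is assigned.  Each band is split into four 90°
sectors about the band's own vertex centroid (a bowed shaft would otherwise
bias membership): anterior within 45° of +y, posterior of −y, and the ±x
sectors named lateral/medial by side (right tibia: lateral = +x; left
mirrored).  A vertex exactly on a 45° boundary goes to the next sector
counter-clockwise, deterministically.  Sector membership uses vertex
position, not normal direction.

Per region the summary is the mean thickness over valid vertices, reported
both in mm and standardized (divided by tibial length, displayed ×10⁻³ by
convention) to remove body-size effects.  Empty regions are flagged, not
fatal.

## Synthetic phantoms

The generator produces a tube along +z: outer radius R(h) (h = height
fraction), inner surface at R(h) − T(h, θ) with a configurable thickness
field (constant, per-sector piecewise constant, or sinusoidal in the sector
angle), piecewise-constant densities (defaults: background 40 HU, cortex
1500 HU, trabecular 150 HU — configurable; clinical scanners vary), Gaussian
PSF blur (default σ 0.6 mm), and seeded additive Gaussian noise (default
20 HU) at clinical voxel spacing (default 0.7 × 0.7 × 1.0 mm).  Partial
volume is approximated by 3× supersampling before the blur; voxelization is
bit-reproducible under a fixed seed.  An optional rigid pose moves the
canonical bone; the volume grid is sized to cover it unless a fixed extent is
requested, in which case an oversized bone is an explicit error naming the
dimension.  Landmarks are placed on the canonical geometry (eminence midpoint
at the proximal end, talar dome points at the distal end, PCL/tuberosity
points spanning ≈ 58 mm anteroposteriorly so that millimetre landmark error
tilts the y-axis by less than 2°).

Because the geometry is analytic, the ground-truth thickness at any surface
point is exact, which is the oracle for the accuracy tests.  The phantom does
not emulate trabecular texture, cartilage or soft tissue, metaphyseal flare,
scanner-specific noise spectra, or beam hardening; passing tests demonstrate
the estimator's behaviour under the stated image model, not robustness to
those effects.

Cohorts of per-subject regional standardized thickness are drawn
independently per region from group normal distributions.  The default
calibration is the packaged regional reference table (per-group means and
95% CIs at n = 12/19/29/25); CIs are inverted to SDs t-based,
sd = halfwidth·√n / t₀.₉₇₅,ₙ₋₁.  The independence across regions within a
subject is a simplification — real regional thicknesses are correlated — so
cohort-level tests exercise the statistical machinery, not anatomy.

## Statistics

One-way fixed-effects ANOVA is computed from per-group (n, mean, sd), so it
runs identically from raw samples or from printed summary statistics (the two
paths agree to machine precision).  Tukey HSD uses the studentized-range
distribution with the Tukey–Kramer standard error for unequal n.  Observed
power is the mainstream-software convention: noncentrality λ = SS_between /
MSE and power = P(F′(df_b, df_w, λ) > F_crit(α)); α for power defaults to
0.05 independently of the α = 0.01 significance threshold used for the
comparisons (both are parameters; the saturated worked example is insensitive
to the choice).  Significance is strict: p < α, a boundary p = α is not
significant.  The four areas within a height are compared as independent
groups even though they are paired within subjects, reproducing the reference
analysis as published rather than "correcting" it to repeated measures.
For 12-region cohorts the total-diaphysis value of a subject is the mean of
its three height values per sector.

Repeat-measurement precision is the mean and maximum absolute first-minus-
second difference, with a t-based 95% CI of the mean signed difference.  ICC
is ICC(A,1) (two-way, absolute agreement, single measurement; McGraw & Wong),
used for intra-observer agreement of two measurements and, across observers,
applied to each observer's mean of its repeats.  The choice is configurable in
the sense that the ICC function accepts any n × k table.

## Numerical choices and problem sizes

* Map smoothing is symmetric graph-Laplacian diffusion on the mesh edge graph
  (cap apexes excluded), step factor 0.8/d_max, iteration count
  ⌈(radius/ℎ)²⌉ with ℎ the median edge length.  Symmetric weights conserve
  the map total exactly, so the mean of a fully valid map is invariant;
  invalid vertices are first imputed from valid neighbours and keep their
  invalid flag.
* Circle-fit slabs start at ±1.5 mm about the target height and widen
  geometrically if mesh decimation left fewer than 8 points.
* Test and acceptance phantoms use shortened shafts (40–120 mm) at full
  clinical voxel size and reduced mesh density (≈ 1 000–2 500 vertices), with
  one full-length 363 mm phantom at the default 5 000–9 000 vertex band for
  the region machinery; these sizes keep the whole suite at around a minute
  while exercising every code path at clinical resolution.
* The accuracy experiment (phantom at 0.7 × 0.7 × 1.0 mm, wall 3–8 mm,
  σ = 0.6 mm, noise 20 HU, two-pass constrained fit) yields a mean absolute
  error well under the 0.3 mm the method class is known for; the exact value
  is recomputed by `scripts/acceptance.py` and by the test suite, not quoted
  here.

## Known limitations

* The inner (endosteal) surface is never meshed; thickness comes from the
  profile fit alone.
* Epiphyseal/metaphyseal geometry is out of scope; contouring assumes
  star-shaped, single-component diaphyseal cross-sections.
* The contour stage requires an axis-aligned volume grid (clinical axial
  series); the frame and everything downstream are pose-general.
* Equivalence with any specific external CBM implementation is not asserted;
  the validated property is the sub-voxel accuracy bound on phantoms with
  analytic truth.
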