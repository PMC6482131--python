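# Methods

`aortrack` quantifies thoracic-aorta dilatation between a baseline and a
follow-up CTA scan of the same patient. This note describes the models and
procedures, the parameters that matter, what the synthetic phantom does and
does not emulate, and the numerical choices made where the design was open.

## Coordinate conventions and data model

All world coordinates are LPS (DICOM convention), in millimetres; NIfTI
input is converted on read. Volumes are stored as float32 Hounsfield units
regardless of on-disk type, with voxel indices `(x, y, z)` (x fastest as
stored) and half-open index ranges. The world↔voxel maps are mutually
inverse to below 1e-9 mm; cropping never changes the world position of a
retained voxel. Preprocessing is a manual z-crop, mirroring a workflow in
which the operator trims both scans to the thoracic aorta.

## Baseline centerline

The lumen intensity is modelled as a Gaussian fitted in a 5 mm ball around
a user seed (SD floored at 1 HU). Each voxel's cost is the shifted negative
log-likelihood `0.5 ((I - m)/s)^2`, zero at the model mean; the cost
depends only on `I - m`, so a global intensity shift applied to both the
image and the model leaves the extraction invariant. Voxels costlier than
the 3σ ceiling (cost 4.5) are inadmissible: they are excluded from the
search entirely, so an extraction can fail loudly but cannot return a path
outside the vessel.

The centerline is the minimum-cost path on the 26-connected grid between
the aortic-root and descending endpoints (Dijkstra; edge weight = mean of
the endpoint voxel costs times the Euclidean step, plus a 0.01 /mm length
penalty so that in homogeneous lumen the geometrically shortest admissible
route wins). Endpoints are detected automatically by scanning axial slices
caudally→cranially for admissible cross-section components — the first
large component is the descending endpoint, the first well-separated
newcomer the root — and can always be overridden manually; single seed
voxels pushed over the ceiling by noise are snapped to the nearest
admissible voxel within two voxels.

Shortest paths hug the inner side of bends, so each point is then moved to
the likelihood-weighted centroid of the admissible voxels in its normal
plane (disc radius 25 mm, chosen larger than any plausible lumen radius).
Four passes run on nodes spaced 4 mm apart — recentring at fine sampling
feeds tangent jitter back into the next pass and inflates the curve — with
the two endpoints pinned, because the half-covered discs at the tube ends
would otherwise erode the curve inward. The result is resampled at 1 mm
and smoothed with a 5-point moving average before tangents are computed.

On default noisy phantoms the extracted centerline lies within ~0.25 mm
(mean) of the true curve; the acceptance suite requires < 1.5 mm.

## Deformable subdivision-surface segmentation

The lumen surface is a generalized cylinder: R rings × K vertices
(defaults: 2 rings/cm, K = 16) swept along the centerline with
double-reflection rotation-minimizing frames (adjacent rings untwisted),
refined by two levels of Loop subdivision. The two open boundary rings use
the cubic B-spline boundary rules; subdivision is a fixed sparse linear
operator per topology, so it is precomputed once and commutes with
translation exactly.

The fit deforms control vertices so that the *near-limit* surface (the
image of the control vertices under the 2-level subdivision operator) sits
on the image's edge ridge. This matters quantitatively: a 16-gon ring
shrinks ~2.5% under subdivision, which would bias a 15 mm radius by
0.4 mm if the control polygon itself were fitted to the edge.

The cost image is the Gaussian-smoothed gradient magnitude (σ = 1 mm, in
HU/mm). Each iteration samples the cost along every vertex's outward
normal in ±search range (10 mm baseline, 6 mm follow-up; 0.25 mm steps)
and picks the **first local maximum scanning outward that reaches 50% of
the reference edge strength** — this lands on the lumen-wall ("inner
edge") interface rather than outer-wall or calcification edges. The 50%
reference is the ring-median of per-ray maxima rather than each ray's own
maximum: a single very bright interloper (vertebral bone grazing one ray)
must not raise the bar above the true lumen edge. Vertices move half-way
toward the selected offset (snapped to the sampling grid and only if the
sampled cost there is no worse), then the displacement field is smoothed
over the control lattice (weight 0.3); convergence is declared when the
largest displacement drops below 0.05 mm, with a 200-iteration cap. With
smoothing disabled, the update backtracks on the total sampled cost, making
the ascent monotone — the subdivision operator mixes neighbour
displacements, so a per-ray guard alone is not sufficient near the
boundary rings.

The baseline fit initializes ring radii from the median cost-ridge
distance over 8 rays per ring. A converged surface whose median vertex
cost falls below 20% of the strong-edge scale near the mesh is rejected as
a fit failure — the signature of a centerline that missed the vessel. On
noiseless phantoms ≥ 95% of rings land within 0.5 voxel of the true
radius; on default noise the mean radius error is ~0.1 mm.

### Follow-up path and adaptive threshold

The follow-up is segmented by deforming the *baseline* surface on the
aligned follow-up volume, so rings correspond one-to-one between time
points. First, a centerline-based adaptive threshold estimates local lumen
statistics (mean m, SD s) in 20 mm arc-length windows from voxels within
5 mm of the centerline (excluding the truncated tube ends) and clamps each
window's slab to `[m - 4s, m + 2s]` — asymmetric because bone lies far
above lumen intensity and must be suppressed harder than muscle below it.
Clamping through the lumen-wall transition would drag the gradient peak
inward by up to ~1 mm, so voxels within search-range + 2 mm of the current
surface estimate keep their original intensities: the threshold suppresses
*surrounding* tissue, never the boundary being detected. The clamp seam at
the shell boundary creates an artificial edge, but it lies (by that 2 mm
margin) beyond the fit's reach.

A 26-connected region-grow within an intensity interval is provided as a
QC overlay for the aortic arch and supra-aortic branches; it does not
modify the fitted surface.

## Rigid/affine mutual-information registration

The fixed-image region of interest is the axis-aligned bounding box of the
baseline surface expanded by 10 mm — large enough to contain the aorta and
its immediate mediastinal context, small enough to exclude most of the rib
cage. The metric is mutual information over jittered random in-mask
samples (32 bins; samples mapping outside the moving image are discarded,
and fewer than 50% valid samples is an error). The public metric uses hard
binning (so self-MI equals the marginal entropy exactly); the optimizer
uses linear soft-bin assignment, which makes the metric a smooth function
of the transform.

The rigid stage (3 Euler angles about the mask centroid + translation;
angles scaled by the mask radius so one parameter unit ≈ 1 mm of motion)
is optimized by stochastic gradient ascent: each iteration draws a fresh
2048-sample batch, estimates the gradient by central differences, and
takes a normalized step decaying as `t^-0.6`, over a 3-level pyramid
(4×/2×/1× with matched Gaussian smoothing; 250 iterations per level). The
affine stage (full 3×3 + translation) is a deterministic Powell ascent on
one larger seeded batch (16384 samples), initialized at the rigid result:
letting the nine linear parameters follow small stochastic batches invites
spurious scale, whereas the polish-batch ascent recovers genuine scale to
well under 1% and never returns a transform with lower batch-MI than its
initialization. The whole registration is deterministic given the seed.
The follow-up volume is resampled onto the baseline grid exactly once,
after the composite transform is known.

A methodological caveat worth knowing: a *uniform* dilation of the entire
aorta is partially expressible as an affine scale, so MI alignment of a
dilated pair is only well-posed when enough rigid anatomy (spine, sternum,
airways, structured soft tissue) lies inside the mask. The phantom's
default scene includes exactly that context; on real CTA the mediastinum
provides it naturally, and localized aneurysmal growth — the clinically
typical case — is not affine-expressible in the first place.

## Landmarks and diameters

Seven landmarks (STJ, MAA, PROX, MID_ARCH, DIST, DESC, DIAPHRAGM, in
anatomical order) are annotated as world points on the baseline; each is
projected to its nearest centerline position (annotations farther than
30 mm are rejected by name), and the measurement plane is normal to the
centerline tangent there. Anatomical placement is the annotator's
responsibility; the tool stores and projects the click. The same
baseline-defined planes are reused verbatim on the follow-up surface, so
the two measurements are co-planar by construction.

Each plane is intersected with the subdivided mesh; the intersection
segments are chained into loops (an open chain — the plane crossing a
boundary ring — is a reportable error, as is a miss), the loop nearest the
landmark is kept and ordered counterclockwise about the normal. The
maximal cross-sectional diameter is the diameter of the polygon vertex
set: the maximum pairwise distance, computed on the convex hull, which is
exact and oracle-checkable against the O(n²) brute force. On an analytic
cylinder the measured diameter follows the `d / cos θ` plane-tilt law to
within 1% up to 75°. Diameter-vs-arc-length curves sample the same
machinery every 2 mm (reported relative to the STJ when available), and
the per-vertex dilatation field assigns each baseline ring the follow-up −
baseline change of ring diameter, matched by arc length (the 0/5/10 mm
color-coded overlay).

Per-landmark failures are recorded as missing values with a reason, never
fatally; the difference column is exactly antisymmetric under swapping the
meshes.

## Agreement statistics

Bland–Altman: mean and SD (n−1) of paired differences with 95% limits of
agreement (±1.96 SD), plus the per-pair (mean, difference) points for
plotting. ICC: two-way mixed-effects, absolute-agreement, single-measure
ICC(A,1) from the mean-squares decomposition — absolute agreement is what
diameter comparability requires — and the variant name is printed in every
output row. `evaluate_agreement` applies both per landmark to two paired
report batches (observer vs observer, or tool vs a manual-measurement
CSV), reproducing the standard method-evaluation table layout. Both
implementations match exact rational-arithmetic hand computations on
3-subject examples and an independent reference implementation.

## The synthetic phantom

The phantom is a candy-cane tube (ascending limb, semicircular arch of
35 mm radius, descending limb) with a piecewise-linear lumen radius
profile whose defaults track adult thoracic calibers (diameters ~37 mm at
the STJ, ~44 mm at the MAA, tapering to ~24 mm at the diaphragm) and seven
landmarks at fixed arc-length fractions. Scene content: contrast-filled
lumen 300 HU, 2 mm wall shell at 60 HU, background 20 HU plus a smooth
soft-tissue texture field (80 HU SD, 3 mm correlation length, fixed
per-scene seed), vertebral-column and sternum-like bone sphere columns
(700/650 HU), a trachea-like air column (−950 HU), optional thin
supra-aortic branch tubes, 0.6 mm partial-volume blur and 10 HU Gaussian
noise. Tube ends are cut flat, as a field-of-view crop does. The follow-up
twin applies a nonnegative radius-increment profile (uniform, or a
trapezoidal localized bulge) and maps the whole scene — including the
texture, evaluated in scene coordinates — through a known rigid/affine
transform before rasterization, so centerline, radius profile, landmark
positions and applied motion are all known exactly.

What it deliberately does not emulate: calcification and thrombus texture,
dissection lumina, ECG-phase motion artifacts, contrast-bolus
heterogeneity along the vessel, streak artifacts, and anatomically
variable branch topology. Passing tests therefore demonstrate geometric
and numerical correctness of the pipeline under realistic contrast, noise
and mediastinal-context conditions — not clinical performance on patient
scans, which the original evaluation of such tools measures against manual
expert readings.

## Problem sizes and determinism

Default test and acceptance runs use 1.0 mm isotropic phantoms
(0.7 mm for the dedicated centerline-accuracy check, 1.5 mm for the
20-pair annotation-jitter cohort, whose per-case aortic caliber varies by
±15% to emulate between-patient variance), chosen so the full suite and
the acceptance script each run in minutes on one CPU. All randomness —
phantom noise, texture, sampling, registration — flows from explicit
seeds; identical seeds give bit-identical volumes, transforms and CSV
reports.

## Known limitations

- The wave-propagation/Dijkstra centerline and the subdivision-surface fit
  are implemented from their component descriptions; the original
  references' exact speed function and fitting energy are not public, so
  the Gaussian-NLL Dijkstra and the normal-direction ridge search with
  Laplacian smoothing are this package's own, declared formulations.
- "Inner-edge" measurement is honored through the segmentation's
  inner-ridge selection rule; on heavily calcified walls the inner edge
  and the strongest edge may differ more than the phantom can show.
- The affine stage will absorb part of a truly uniform whole-vessel
  dilation if the fixed-image mask contains too little rigid anatomy (see
  the registration caveat above).
- Endpoint auto-detection assumes a volume cropped to the thoracic aorta
  with both aortic ends reaching the caudal slices; other croppings need
  manual seeds (which every stage accepts).
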