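# Methods

## The measurement problem

A drilled bone tunnel is, immediately after surgery, a cylinder of known
diameter (the reamer size) oblique to the CT axes.  The package measures
that diameter four ways — three on a triangle-mesh model of the tunnel wall
extracted from the segmented CT, one directly on the 2D slices — and
quantifies each method's agreement with the known drill size.  All
geometry is carried out in world millimetres with the fixed convention
`world = origin + index · spacing`, voxel axis order (x, y, z).

## Synthetic phantoms

Real postoperative CTs are not publicly available, so validation uses
phantoms with exact ground truth.

**Geometry.**  A rectangular bone block (default 40 × 40 × 22 mm) of
cancellous density 300 with a 3 mm cortical shell of density 1200, in a
background of 0 (HU-like but uncalibrated — segmentation is threshold-based,
so only the separation of the three levels matters).  A cylindrical tunnel
of the drill diameter is carved through the block center at an obliquity of
20–40° from the slice normal (uniform random per tunnel), the range in
which clinical femoral tunnels sit and oblique enough to exercise the
anisotropic spacing.  The tunnel length (default 30 mm) exceeds the block
thickness along the tunnel axis, so both ends pierce the surface: real
tunnels are open at the bone surface, and open apertures are what make the
wall-thickness and section methods non-trivial.

**Voxelization.**  Default spacing 500/512 ≈ 0.977 mm in-plane and 0.75 mm
between slices (a 500 mm field of view on a 512×512 matrix with a 0.75 mm
slice increment — typical knee-CT geometry).  Partial volume is modeled by
an isotropic Gaussian blur of σ = 0.6 voxel applied to the density field,
followed by additive Gaussian noise of SD 20 density units (≈ 7% of the
cancellous–background contrast).  Each phantom is deterministic given its
seed; cohort generation draws diameters with replacement from the 0.5 mm
ruler grid 5.0–9.0 mm and randomizes obliquity, all from one cohort seed.

**What the phantoms do not emulate:** condylar anatomy, trabecular texture,
beam hardening, and the metal artifact of fixation hardware.  Passing
recovery tests on phantoms therefore demonstrates correctness of the
geometry and statistics pipeline under controlled imaging physics, not
robustness to scanner artifacts or to operator-dependent segmentation of
real knees.

## Segmentation

Bone is selected by a density window (default ≥ 150, the midpoint of
background and cancellous).  The tunnel cavity is recovered by
morphological closing of the bone mask with a Euclidean ball whose radius
(default 6 mm) must exceed the tunnel radius, subtracting the bone, and
keeping the 26-connected component containing a user seed point.
Morphology is computed via distance transforms with the physical spacing as
sampling, so the anisotropic slice direction does not bias the ball; the
mask is padded by the ball radius beforehand because a dilation that
saturates at the array boundary cannot be undone by the erosion and would
leave a spurious crust.

The cavity is surfaced by marching cubes at level 0.5 on a Gaussian-
smoothed copy of the binary mask.  The smoothing sigma defaults to **0.5
voxel**: smoothing a binary field moves a curved 0.5-level set toward the
center of curvature by roughly σ²/(2R) (one step of curvature flow), so a
1-voxel sigma would shrink a 6 mm tunnel's measured diameter by ≈ 0.3 mm
while 0.5 voxel keeps the bias below 0.1 mm and still removes the
staircase.  Raw-mask surfacing is available by flag.  Mesh normals are
oriented by probing the mask along each face normal and are normalized to
point into the lumen.

There is no manual mask-revision step: the clinical workflow this models
includes analyst cleanup of the aperture regions, which is replaced here by
two deterministic rules described below (cylinder-fit end trim, centerline
end-slab drop).

## The four methods

**Best-fit cylinder.**  Orthogonal-distance least squares over wall
vertices; residual `‖(p−c) − ((p−c)·d)d‖ − r`.  Initialization: first
principal axis, centroid, mean radial distance; Levenberg–Marquardt
refinement to gradient tolerance 1e-10 (≤ 200 iterations).  The direction
is parameterized as a perturbation of the initial axis in its transverse
plane, which avoids polar singularities.  A pre-check rejects clouds
without a dominant axis (longest-to-second principal extent < 1.2).
`end_trim_mm` (0 by default; 4 mm in the pipeline) excludes vertices near
the two axial extremes before fitting: where the tunnel crosses the
cortical shell, partial-volume averaging pulls the threshold boundary into
the lumen (the shell's depth along a 20–40° axis is 3.2–3.9 mm, hence the
4 mm default), and fitting that narrowed rim would bias the whole-tunnel
diameter low.  On an ideal cylinder the trim provably changes nothing.

**Centerline + transverse section.**  The centerline is the polyline of
slab centroids: vertices binned into 20 equal-width slabs along the initial
principal axis, slabs with fewer than 10 vertices dropped, and the two
extreme slabs always dropped — the slanted aperture rims contribute only
partial vertex rings whose centroids sit off-axis.  The section plane
passes through the arc-length station (default 0.5, "mid-length") with the
local tangent as normal; the mesh–plane intersection loops are chained, the
loop containing the centerline point is kept (innermost on nesting, with a
warning; a cut through an aperture yields no closed loop and raises).  The
circle fit is algebraic (Kåsa) followed by geometric refinement of
Σ(‖pᵢ−c‖−r)², tolerance 1e-10 — reported diameters are therefore
bit-reproducible given a mesh.

Known limitation: near a sharp bend, any planar slab captures part of the
inner-elbow vertex rings of the neighbouring straight segment, so
slab-centroid centerlines carry a deviation floor of roughly 7% of the
tunnel radius at a 10° bend (measured on miter-jointed test tubes across
slab counts 8–21).  Straight portions are recovered to within microns; the
floor matters only for visibly bent tunnels, which postoperative ACL
tunnels are not.

**Wall thickness.**  From each triangle centroid, a ray along the
into-lumen face normal; the first intersection with a triangle whose
centroid lies farther than the exclusion radius (default 1.0 mm, larger
than a triangle edge at default tessellation, so a ray cannot terminate on
its own neighbourhood).  Intersection uses a chunked, vectorized
Möller–Trumbore test over all triangles — exact, deterministic, and fast
enough for cohort-scale meshes.  Rays that exit through an aperture are
recorded as misses and excluded from the summary; a miss fraction above
50% attaches a warning, zero hits is an error.  The summary diameter is
the unweighted mean of recorded thicknesses (area-weighted mean and
vertex-origin rays available as options; which variant commercial tools
use is not documented, so both are exposed).  On rough walls the scattered
normals traverse chords rather than diameters, and a chord is never longer
than the diameter — hence the method's systematic underestimation, which
the test suite asserts against the cylinder fit on vertex-noise-perturbed
cylinders.

**2D CT.**  At the tunnel mid-point (centerline station 0.5 mapped to the
mask) the in-slice 8-connected component containing the mid-point is
contoured at the 0.5 level in each canonical plane, and its minimum Feret
width (rotating calipers over the convex hull) is the per-plane diameter;
the method value is the mean of the three planes.  The minimum caliper
width is used because an oblique tunnel cuts each plane in an elongated
section and the minor width is what a clinician's straight-line measurement
across the tunnel approximates; the maximum-Feret alternative is available
for sensitivity analysis.  The binary slice is smoothed with σ = 1 pixel
before contouring: caliper widths are extreme-point statistics, and raw
staircase corners protrude by up to half a pixel, which measurably inflates
the width of obliquely cut sections.

## Agreement statistics

ICC(2,1) — two-way random effects, single measures, absolute agreement —
from the two-way ANOVA mean squares:

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

with the McGraw–Wong F-based 95% interval (the construction used by
standard statistics packages for this form; verified against pingouin).
Negative estimates are reported as-is.  An all-equal table is defined as
perfect agreement (ICC 1, CI [1, 1]) with a warning rather than 0/0.
Classification: > 0.75 excellent; 0.40–0.75 fair to good, both boundaries
inclusive; < 0.40 poor.  "Agreement with the drill size" treats the drill
diameter as a second rater column.  Difference summaries use signed
(measured − truth) differences with sample SD (n−1).

## Study conditions and problem sizes

The simulated study uses 24 tunnels (the clinical cohort size this
emulates), diameters 5.0–9.0 mm in 0.5 mm steps, spacing 0.977 × 0.977 ×
0.75 mm, blur σ 0.6 voxel, noise SD 20.  At those sizes a full study runs
in well under a minute per eight tunnels on one CPU; analytic-mesh checks
use 512 circumferential segments for the fitting methods (discretization
error ≪ 1 µm-scale tolerances) and 96 for ray casting, where the tolerance
is 1%.  The underestimation experiment uses vertex noise of SD 0.15 mm on
a 3.5 mm-radius cylinder over 10 seeds.

## Degenerate inputs and tie-breaks

Zero-vector axes, non-positive radii/diameters, empty masks, seeds outside
any cavity, incomplete rating tables and n < 3 subjects raise typed errors;
empty threshold results and >50%-miss thickness fields warn and proceed.
Nested section loops keep the innermost; multiple candidate loops keep the
one containing the centerline point; if none contains it (rough walls), the
nearest loop is used with a warning.  A cylinder fit that stops on the
iteration cap raises an error carrying the best iterate.
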