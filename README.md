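# tunnelmetrics

Measuring the diameter of drilled bone tunnels on CT — the clinical problem
behind anterior cruciate ligament (ACL) reconstruction follow-up.  After an
ACL reconstruction the femoral tunnel may widen over time, and a reliable
diameter measurement is essential for planning revision surgery.  The
reamer ("drill") size used at surgery is the ground-truth tunnel diameter
immediately postoperatively, which makes drilled tunnels an unusual setting
where measurement methods can be validated against a known truth.

`tunnelmetrics` implements four diameter measurements and the statistics to
compare them:

* **Best-fit cylinder** — an analytic cylinder minimizing the squared
  orthogonal distance `(‖(p−c) − ((p−c)·d)d‖ − r)²` over every vertex `p`
  of the tunnel-wall mesh; diameter = 2r.
* **Transverse section** — a center axis is fitted through the lumen
  (slab-centroid polyline), the mesh is cut perpendicular to the axis at
  mid-length, and a circle (Kåsa + geometric refinement) is fitted to the
  cut boundary.
* **Wall thickness** — from each wall triangle, a ray along the into-lumen
  normal to the opposite wall; the summary diameter is the mean recorded
  distance.  On rough segmented walls the rays traverse chords rather than
  diameters, which biases this method low — the package reproduces that
  failure direction.
* **2D CT** — the clinical bedside method: the in-slice width of the tunnel
  at its mid-point in the axial, coronal and sagittal planes (minimum Feret
  width of the in-slice region, sub-pixel contours), averaged.

Agreement with the drill size is quantified by the two-way random-effects,
single-measures, absolute-agreement intraclass correlation ICC(2,1), with
McGraw–Wong F-based 95% confidence intervals, classified as excellent
(> 0.75), fair to good (0.40–0.75) or poor (< 0.40), alongside mean ± SD
differences.

Because patient CTs are not public, the package ships a synthetic phantom
generator: a two-density bone block (cancellous interior + cortical shell)
pierced by an oblique cylindrical tunnel of known diameter, voxelized at
CT-like anisotropic spacing with partial-volume blur and noise.  Every
method is validated by parameter recovery on those phantoms.

## Worked example

```python
import tunnelmetrics as tm

# a 7.0 mm tunnel drilled 30 degrees oblique to the scan axis
spec = tm.PhantomSpec(drill_diameter_mm=7.0, tunnel_axis=tm.tilted_axis(30, 45), seed=42)
volume, truth = tm.make_phantom_volume(spec, tunnel_id="demo")

bone   = tm.threshold_segment(volume, low=150)                 # density window
cavity = tm.extract_tunnel_cavity(bone, closing_radius_mm=6.0,
                                  seed_point_mm=truth.axis_point_mm)
mesh   = tm.mask_to_mesh(cavity)                               # marching cubes, mm

for rec in tm.measure_all(mesh, cavity, truth=truth):
    print(f"{rec.method.value:20s} {rec.diameter_mm:6.2f} mm  (error {rec.error_mm:+.2f} mm)")
```

prints

```
cylinder_fit           6.82 mm  (error -0.18 mm)
transverse_section     6.96 mm  (error -0.04 mm)
wall_thickness         6.65 mm  (error -0.35 mm)
ct2d                   6.94 mm  (error -0.06 mm)
```

The transverse-section and 2D methods recover the drill size to well within
a tenth of a voxel; the cylinder fit carries a small negative bias from the
partial-volume-narrowed tunnel ends; wall thickness is biased lowest — the
same ordering the methods show clinically.

The full simulated study (24 tunnels, drill sizes 5.0–9.0 mm on a 0.5 mm
ruler grid, randomized obliquity) with a Table-style agreement report:

```python
result = tm.run_simulated_study(tm.RunConfig(seed=0), out_dir="study")
print(result["report"])   # per-method ICC, 95% CI, class, mean ± SD difference
```

## Command line

```sh
tunnelmetrics simulate --n 24 --seed 0 --out study/
tunnelmetrics segment --in scan.nii.gz --range 150:inf --seed-mm 12,40,33 \
                      --closing-mm 6 --out tunnel.stl
tunnelmetrics measure --mesh tunnel.stl --mask tunnel.nii.gz --out measurements.csv
tunnelmetrics agree --measurements measurements.csv --truth drill_record.csv --out report.csv
```

Formats: NIfTI/NRRD volumes (spacing honored), STL/PLY meshes, CSV/JSON
reports.  All randomness flows through explicit seeds; rerunning a study
with the same config produces bit-identical CSVs.

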