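# Methods

This note documents the models and procedures implemented in `aortax`, the
parameters that matter, the synthetic phantoms the test suite runs on, and
the numerical choices made where the design was open.

## Inputs and coordinate conventions

The pipeline consumes a CT volume in Hounsfield units and a co-registered
integer label map naming the aorta, the LV/RV blood pools, liver, kidneys,
the three arch branch arteries and the two common iliac arteries (the
vocabulary mirrors TotalSegmentator structure names, so real segmentations
drop in unchanged).  All volumes are reoriented on read to a fixed LPS
convention (axis 0 left-right, axis 1 posterior-anterior, axis 2
inferior-superior) and every geometric quantity downstream is expressed in
physical millimetres; voxel indices appear only inside rasterisation and
resampling kernels, because cohort CTA is anisotropic (0.25–0.5 mm
increments) and index arithmetic is error-prone there.

Arc length along the centerline is 0 at the iliac bifurcation and increases
toward the aortic valve.  "Distal" in the haemodynamic sense (with the
flow) therefore means decreasing arc length; landmark-ordering statements
in anatomical order translate to decreasing arc positions.

## Lumen refinement

The aorta label covers lumen, wall, plaque and (in disease) aneurysmal
sacs.  Pure-lumen statistics are estimated from the 3-D morphological
skeleton of the label dilated by `skeleton_dilation_mm` (**1 mm**) — a thin
core that is almost surely contrast-filled blood.  With sampled mean μ and
standard deviation σ, the lumen is the union of connected components of

    { v in aorta : μ − 5σ ≤ HU(v) ≤ μ + 3σ }

that touch the dilated skeleton (components are kept by skeleton contact
rather than size because cardiac scans legitimately contain two aorta
parts).  Morphological opening then closing with a 1-voxel ball removes
speckle and fills pinholes; the closing's erosion treats out-of-grid
neighbours as filled so a lumen that leaves the field of view keeps
touching the grid face.  After closing, voxels at or above the
calcification threshold are excluded again, so plaque can never be closed
back into the lumen.  A σ of exactly zero (constant-HU phantoms) is floored
at 1 HU so the band is never empty.

Calcification is defined on the removed voxels:

    calc = { v in aorta \ lumen : HU(v) ≥ max(v_minhu, μ + α σ) }

with defaults **α = 3** and **v_minhu = 400 HU**.  The calcification ratio
is `100 · |calc| / (|lumen| + |calc|)` — the denominator is a package
choice (configurable), as only the ratio's order of magnitude is
anatomically meaningful.  Raising α or `v_minhu` shrinks the calcification
mask monotonically (set inclusion), which the tests assert.

## Centerline and frames

Endpoints depend on the scan class: a full aorta runs from the iliac
bifurcation (most superior region where both dilated iliac labels meet the
lumen) to the LV junction (centre of mass of the dilated-LV ∩ dilated-lumen
overlap); an abdominal scan ends where the lumen crosses the superior grid
boundary; a cardiac scan yields two runs, the descending portion between
its two boundary crossings and the ascending portion from its boundary exit
to the LV junction.  For unclassified partial coverage the two largest
boundary-contact clusters are used, with a farthest-pair fallback.

The medial path is a Dijkstra shortest path over the 26-connected in-lumen
voxel graph with edge cost

    step_length / (ε + distance_to_boundary(target)),   ε = 0.1 mm

which makes wall-hugging routes expensive and keeps the path at the centres
of the maximally inscribed spheres.  The raw voxel path is then smoothed
with a 5-point moving average (endpoints pinned): the 26-connectivity
zigzag otherwise inflates the path length by several percent, which would
leak directly into tortuosity.

Each coordinate of the smoothed path is fitted by a cubic smoothing spline
against cumulative chord length and resampled at a uniform 1 mm arc-length
step.  The smoothing budget targets a residual RMS of **0.35 × the voxel
diagonal**; endpoint samples carry a large weight so smoothing cannot pull
the curve ends inward (that would bias chord lengths and hence tortuosity).
A larger budget visibly cuts the arch corner — it shortened arc coordinates
by ~3 mm and tilted slice planes at the arch exit — while a much smaller
one re-admits voxel jitter.  Note that a smoothing spline is not idempotent
on curved paths: re-fitting spends its residual budget again, so the
re-fit-stability property holds on straight geometry only.

Frames are propagated by the double-reflection rotation-minimising scheme
from an initial normal built from the anterior up-vector (lateral fallback
when near-parallel to the first tangent).  After each step the flip rule
enforces `dot(n_prev, n_curr) ≥ 0`: at curve inflections a naive Frenet
normal reverses sign, which would put seams into the straightened volume.
Frames are re-orthonormalised to 1e−6.

## Curved planar reformatting

Slices orthogonal to the centerline are sampled on a square grid
(`cpr_halfwidth_mm` = 40, `cpr_inplane_res_mm` = 0.5) at arc positions
`k · cpr_slice_step_mm` (step 1 mm), so the slice count is exactly
`floor(L/Δs) + 1`.  HU is interpolated trilinearly; the lumen mask is
resampled as the 0.5-level set of its 0.3-voxel-Gaussian-antialiased
indicator — still a binary mask, but with the boundary at sub-voxel
accuracy.  Nearest-neighbour mask sampling leaves half-voxel boundary
ripple that the max-over-angles diameter search collects as a systematic
+1.5 mm; the level-set variant is unbiased and conserves area to well
within the tolerances checked (per-slice area within 2 % of πr² on tube
phantoms, profile integral within 5 % of the voxel-counted volume).
Out-of-volume samples get −1024 HU and lumen false.  Sampling-plane
self-intersection at very high curvature is not corrected; affected slices
are caught by the per-slice aspect-ratio check.

## Landmarks and segments

* **Ventricular-aortic junction**: centre of mass of the dilated LV blood
  pool ∩ dilated lumen (5 mm dilation each), projected to the nearest
  centerline sample.
* **Proximal arch**: same overlap construction with the brachiocephalic
  trunk.  **Distal arch**: the left-subclavian projection shifted 20 mm
  along the arc toward the descending aorta (clamped with a warning at the
  centerline end).  The left-common-carotid landmark is computed and
  reported but drives no downstream rule.
* **Diaphragm**: starting from the most inferior RV surface point, the
  closest RV–liver surface pair is refined by alternating nearest-neighbour
  projections (distance non-increasing; tolerance 0.5 mm, ≤ 50 iterations);
  the pair midpoint is projected to the centerline.
* **Renal**: the centerline point closest to the infinite line through the
  two kidney centres of mass.
* **Root**: a combined LV–aorta centerline is built from the last 60 mm of
  the aortic centerline extended 30 mm into the LV blood pool by the same
  medial-path extraction restricted to lumen ∪ LV.  On its CSA profile the
  **sinus of Valsalva** is the area maximum within 20 mm distal to the
  ventricular-aortic landmark (window half-open, excluding the landmark),
  the **sinotubular junction** the minimum 5–25 mm beyond the sinus, and
  the **annulus** the minimum within 10 mm proximal to the junction; ties
  break toward the window start.

Segments follow the ESC partition with boundaries exactly at the landmark
arcs: infrarenal [0, renal], suprarenal [renal, diaphragm], descending
[diaphragm, distal arch], arch [distal, proximal arch], ascending
[proximal arch, valve].  A missing landmark marks the adjacent segments
unavailable — never silently merged — and abdominal/cardiac scans get the
subset their field of view supports.

## Biomarkers

Per available segment the measurement slice is the maximal-CSA slice
(minimal for sinotubular junction and annulus; ties to the lower arc), and
the diameter is the longest chord through the section's centre of mass over
180 ray angles (1° steps) with sub-pixel boundary crossings by linear
interpolation — ≤ 0.5 mm angular-resolution error at aortic scales.  A
centre of mass outside the section (crescent shapes) yields a zero diameter
that QC rejects.  The max chord is never below the equivalent-circle
diameter `2·sqrt(CSA/π)` up to grid tolerance.

Tortuosity = centerline arc length / Euclidean distance between the anchor
landmarks, so it is ≥ 1 by construction (descending: distal arch ↔
diaphragm; full aortic: bifurcation ↔ ventricular-aortic junction).

Agreement statistics against manual readings: MAE, MAPE, bias (mean error),
Pearson r, coefficient of variation as the mean signed per-pair difference
over the pair average in percent (an absolute-value variant sits behind the
`absolute_cv` flag, since conventions differ), and Bland–Altman limits of
agreement `bias ± 1.96 · SD(differences)` with the SD using ddof = 1.

## Quality control

* **Scan classification**: 26-connected aorta components ≥ 1 cm³ — two
  components ⇒ cardiac two-part; one component touching both the arch
  branches and the iliacs ⇒ full; kidneys present without arch branches ⇒
  abdominal; otherwise partial; no aorta ⇒ rejected.
* **Surface-to-volume**: marching-cubes surface area of the refined lumen
  over its voxel volume.  Smooth aortic lumina sit near 2/r ≈ 0.2–0.25 /mm;
  fragmented lumina from non-contrast or artifact-laden scans exceed
  **0.4 /mm** (calibrated on phantoms, configurable) and reject the scan.
* **Ellipse aspect ratio**: square root of the ratio of the in-plane
  second-moment eigenvalues; a slice above **2.5** (configurable) has its
  diameter discarded with a warning.  A ratio exactly at the threshold
  passes.

## The phantom generator

Phantoms define the study conditions for every test.  A tube of radius
10 mm (wall 2 mm) follows an analytic curve — straight, semicircle (radius
50 mm), inflected s-curve, or a full aorta built from an abdominal/
descending vertical run (150 mm, optional sinusoid), a semicircular arch
(radius 30 mm) and an ascending run (40 mm) down to the valve.  HU are
drawn per region: lumen N(300, 20), wall 50, soft-tissue background 40,
calcification ≈ 800 (blobs at the lumen/wall interface until a target
volume fraction is met), organs 90–300, with N(0, 10) noise elsewhere.
Organ ellipsoids and branch tubes are placed so every landmark rule has a
constructed ground truth: kidneys flank the tube at arc 40 mm, the RV/liver
pair brackets arc 95 mm, branches leave the arch at 145°/90°/35°, the LV
abuts the valve plane, iliacs leave the distal end.  Root features add a
sinus bulge (+3 mm, 10 mm before the valve), a sinotubular narrowing
(−1.5 mm at 22 mm) and an annular narrowing (−2.5 mm at the valve plane).
Voxels are assigned by centre-point inclusion (no partial volume), so mask
ground truth is exact; a fixed seed gives byte-identical volumes.  Cropping
the volume axially produces the abdominal and cardiac fields of view (the
cardiac crop removes the arch apex, leaving two components, as real cardiac
CTA does).  The non-contrast variant sets the lumen mean equal to the wall
HU and sprinkles clustered 900-HU speckle through the outer 65 % of the
lumen radius — a coarse emulation of the wall-adjacent calcification and
artifacts that fragment refined lumina on mislabelled non-contrast scans.

What the phantoms do **not** emulate: partial-volume blur, beam hardening,
stents and metal artifacts, ECG-gating motion, dissection flaps, and true
anatomical shape variability.  Passing tests therefore demonstrate that the
geometry, statistics and bookkeeping of the pipeline are correct at
realistic scales and noise levels — not that segmentation-dependent steps
are robust to every real-world artifact.

## Problem sizes and determinism

Anatomical phantoms run at 1.5 mm isotropic voxels (landmark tolerances are
10 mm segmental / 3 mm root; measured errors are ≤ ~3.6 mm and ≤ ~1.1 mm
respectively), geometric tube phantoms at 0.8 mm where analytic accuracy is
asserted (tortuosity to ±0.01, areas to 2 %).  The acceptance script uses
five seeded full-aorta phantoms for landmark recovery and one phantom per
remaining quantity.  All randomness flows from explicit seeds; reports are
written with sorted keys, rounded floats and no timestamps, so identical
inputs produce byte-identical JSON, including under multi-process batch
execution.

## Known limitations

* Tortuosity indices require the full-aorta field of view; abdominal and
  cardiac scans report none.
* The centerline is single-branch; arch vessels and iliacs get landmarks
  but no centerlines of their own.
* The annulus depends on the LV blood-pool label; without it the root
  landmarks degrade to missing with warnings.
* The calcification-ratio denominator and the two QC thresholds are
  package choices (documented above) — comparable within a study analysed
  with one configuration, not across tools.
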