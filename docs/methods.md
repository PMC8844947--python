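# Methods

`octastretch` measures how strongly vessel cross-sections in 3D OCT
angiography (OCTA) label volumes are stretched along the A-scan (depth)
axis.  This note records the model, the estimators, the numerical choices
and the limits of what the synthetic phantoms can show.

## Coordinate and unit conventions

Volumes are boolean arrays indexed `(x, y, z)`; `z` is the A-scan (depth)
axis, `x`/`y` the lateral (B-scan) axes.  Voxel `(i, j, k)` occupies the
half-open box `[i·sx, (i+1)·sx) × [j·sy, (j+1)·sy) × [k·sz, (k+1)·sz)` in
micrometers and its center is at `((i+0.5)·sx, …)`.  The default spacing
is the Optovue Avanti grid, 9.87 µm lateral and 12.54 µm axial; spacing
always travels with the volume and is never implicit, because every shape
ratio in this package is meaningless until the lateral/axial anisotropy
is divided out.  On disk, multi-page TIFF stores `z` as the page axis
(pages are `(y, x)`); NIfTI-1 data arrays are read as `(x, y, z)` with
header voxel sizes overriding caller-supplied spacing when present and
nonzero.

## Region of interest

The ROI is the slab of voxels between two retinal surfaces (ILM above,
ONL below), both included: voxel `(x, y, z)` belongs iff
`ilm(x,y) ≤ z ≤ onl(x,y)`.  Inclusive bounds make a flat pair at heights
2 and 4 give a 3-voxel slab, which is the reading consistent with
slab-thickness arithmetic (ROI count / (nx·ny) = thickness in voxels).
Surface gradients are computed in physical units (heights × sz against
x·sx, y·sy) with second-order central differences at interior pixels and
one-sided differences at borders; the percentile reported as p95 is the
linear-interpolation empirical quantile.  Whether slopes should be taken
in voxel or physical units is not observable from the slope statistics
alone; physical units are used because the worked angle conversions
(10 % ↔ 5.71°, 12.9 % ↔ 7.35°) are physical.

A vessel coursing along a sloped surface presents a slightly longer
chord to a vertical (z) measurement: a slope of angle θ inflates the
axial chord by 1/cos θ − 1.  At the 95th-percentile ILM slope (12.9 %,
7.35°) this is 0.83 % — two orders of magnitude below the effect under
study — which justifies reading vessel depth straight down the voxel
column.

## Skeletonization

Per-vessel statistics are evaluated once per centerline voxel, so the
mask is first thinned to a one-voxel-wide skeleton.  3D thinning is
implemented in this package as sequential simple-point peeling under the
(26, 6) digital topology: a border voxel may be deleted only if it is a
*simple point* (Malandain–Bertrand characterization on the 3×3×3
neighborhood: exactly one 26-connected foreground component among the
neighbors, and exactly one 6-connected background component in the
18-neighborhood touching the center's face neighbors), and voxels with
at most one foreground neighbor (curve endpoints, isolated voxels) are
never deleted.  Deletion runs in six directional subiterations with the
border list frozen per pass, and each pass processes the two lattice
parities separately — without the parity split, a chain of individually
simple deletions can consume a two-voxel-wide structure end-to-end; with
it, such structures stabilize as one-voxel staircase curves.  The
per-voxel tests are numba-compiled.

Guarantees (all property-tested): skeleton ⊆ mask; the 26-connected
component count is preserved exactly; no 2×2×2 block survives; straight
tubes reduce to a single path within one voxel of the true axis;
re-skeletonizing a skeleton changes at most the end voxels.  Like any
medial-axis-style thinning, blunt tube ends retract by roughly one tube
radius, so terminal measurement sites sit slightly inside the vessel.
Spur pruning exists (`prune_spurs`) but is off by default: nothing in
the measurement model justifies discarding short branches a priori.

The 2D variant delegates to scikit-image.  The 3D path does not: the
installed scikit-image release (0.26) deletes entire objects with
even-by-even cross-sections in its 3D thinning, which violates the
component-preservation guarantee this pipeline is built on.

## Cross-section area: the sphere-neighborhood estimator

At a skeleton voxel, take the spherical neighborhood of diameter
`d_sphere` voxels (membership: voxel-center distance ≤ d_sphere/2 in
index space), count the labeled voxels inside the sphere that are
connected to the center (26-connectivity by default, evaluated within
the sphere-restricted set so that an unrelated vessel crossing the
sphere is not counted), and divide:

    A_c = n / d_sphere        [voxel²]

For a straight tube threading the sphere, the counted set is a chord of
length ≈ d_sphere of cross-sections, so the division recovers the mean
per-plane area.  The sphere is chosen because it is rotation-invariant:
the estimate does not depend on vessel orientation (property-tested to
within 20 % across axis-aligned and diagonal tubes, the residual being
pure digitization).  The 2D analogue with a circle returns a vessel
width; the reference worked example (37 pixels, d_circle = 11 →
width 3.36 px) is an exact unit test.

Under the circular assumption the equivalent diameter is
`d_v = 2·sqrt(A_c/π)`.

Known, deliberate properties of the estimator:

* **Validity window.** Chord slices near the sphere poles have reduced
  in-sphere radius `sqrt((d/2)² − offset²)`, so A_c biases low as the
  cross-section radius approaches the sphere radius.  At the default
  `d_sphere = 9` the bias stays within 15 % of the digitized per-plane
  area for tube radii up to ~3 voxels — which covers the retinal-plexus
  calibers the default is sized for (mean area ≈ 14 vx² ↔ radius
  ≈ 2.1 vx) — and grows beyond.  Analyses of thicker phantoms therefore
  scale `d_sphere` up so the largest expected cross-section fits well
  inside the sphere (the stretch-recovery suite uses 45 vx for tubes of
  up to 12 vx axial semi-axis).  The complementary constraint is the
  tortuosity caveat: the sphere must stay smaller than the vessel's
  curve radius, or in-plane meanders inflate n.
* **End bias.** At the end of a vessel's centerline roughly half the
  sphere hangs outside the vessel, so A_c drops to ~50 % of the interior
  value (asserted at 0.35–0.65 on a border-truncated tube).  Because
  thinning retracts from blunt ends, the *thinned* skeleton's terminal
  voxel sits ~1 radius inside and shows a milder deficit; the 50 %
  figure applies to sites at the true vessel end, e.g. where vessels
  leave the imaged field.
* **Branch bias.** At a junction the sphere sees both branches, so A_c
  exceeds the single-tube value (asserted on a Y-phantom).
* Both biases lower the apparent elliptical quotient, so headline
  stretch estimates are conservative, not inflated.
* **Anisotropy.** The sphere lives in voxel index space, matching the
  practice of applying a voxel-diameter sphere directly to the native
  grid; the physical neighborhood is an ellipsoid.  Unit conversions
  happen afterwards and are exact.

## Depth, width and the elliptical quotient

The vessel cross-section is modeled as an ellipse with one axis lateral
and one axial — valid because vessels course nearly parallel to the
retinal surfaces.  Per skeleton voxel:

* `d_depth`: the contiguous labeled run along the voxel column through
  the site (floored at 1 voxel — a depth below one voxel cannot be
  labeled).  The *contiguous* run is used rather than the total labeled
  count in the column: counting disjoint runs would conflate overlapping
  plexus layers.  A flag-selectable total-column variant is not offered;
  the run-length reading follows from the en-face analogy of counting
  voxels above and below the site.
* `d_width`: from the ellipse area identity
  `A = π·a·b = (π/4)·d_width·d_depth`, so
  `d_width = 4·A_c/(π·d_depth)`.  The area route is preferred over a
  bounding box because it is less sensitive to stray mislabeled voxels.
* elliptical quotient: `ε_q = (d_depth·sz)/(d_width·s_lat)` — the
  physical axial-to-lateral axis ratio.  1 for a circular vessel, > 1
  when stretched along the A-scan.  ε_q equals `b/a = sqrt(1 − ε²)` of
  the ellipse; it is preferred over the eccentricity ε because ε is
  blind to which axis is the long one (the semi-major label swaps when
  stretching flips axis), while ε_q keeps that orientation.

Every record stores voxel and physical values; by construction
`area_µm² = (π/4)·width_µm·depth_µm` holds exactly, and doubling `sz`
alone doubles every ε_q (scale equivariance, both property-tested).

Aggregation reports the **mean of per-voxel ratios** as the headline
ε_q, and also the ratio-of-means (mean depth / mean width) as a separate
row — the two differ on real data (ratio of the printed mean depth and
width gives ≈ 2.26 while the per-voxel mean is higher) and conflating
them is a classic reporting error.  Sites whose sphere is clipped by the
volume border are flagged and excluded from headline aggregates by
default (their n biases low); a switch includes them.

Two rounding conventions coexist deliberately in the report module: the
width×depth count matrix rounds width to the nearest voxel (half-up),
while ε_q-by-area boxplot bins use the ceiling of the area — matching
the distinct conventions of the two displays.  Boxplot statistics use
linear-interpolation quartiles and 1.5·IQR whiskers (most extreme datum
within the fences), the standard convention.

## Synthetic phantoms

The generator stands in for hand-labeled clinical volumes and supplies
exact ground truth.  A tube is a straight physical segment with an
elliptical cross-section aligned to the z axis: lateral semi-axis `r`,
axial semi-axis `r·stretch`, so the tube's true elliptical quotient *is*
its stretch parameter and its true area is `π·r²·stretch`.  A voxel is
labeled iff its center lies inside some tube, with membership evaluated
at the nearest centerline point (the clamp at the endpoints produces
slightly rounded end caps).  The z-aligned-ellipse simplification is
valid for near-horizontal courses; generated course slopes are capped at
15 %.  Optional label noise flips voxels independently at a stated
probability.

Network phantoms emulate the study conditions of labeled OCTA data: a
304×304×160 grid at (9.87, 9.87, 12.54) µm; a smooth ILM-like surface
whose mean gradient is scaled to 5.9 % (the reported ILM average), with
the ROI slab 15 voxels thick (middle of the reported 13–17); tube
diameters 20–70 µm laid approximately parallel to the surface; tubes
added until a target labeled fraction of the ROI (default 5 %, inside
the reported 3–10 % range) is reached.  The default tube stretch is 1.0
— circular anatomy, the null hypothesis the quotient is designed to
test; pass `stretch` to emulate the artifact.  All randomness flows
through one seeded generator; equal seeds give bit-identical volumes.

What the phantoms do **not** emulate: OCTA speckle and flow-signal
physics, vessel taper and curvature, wall irregularity, capillary-scale
structure below the voxel size, and structured (non-independent) label
noise.  Passing the recovery suites therefore shows the *measurement
chain* is unbiased on known geometry; it does not validate the labeling
of real scans.

### Stretch-recovery study design

The recovery suite rasterizes one tube per stretch grade
{1.0, 1.5, 2.0, 2.5, 3.0} with lateral radius 50 µm (≈ 5.1 lateral
voxels) on a 140×48×50 grid under the device spacing, randomizing the
sub-voxel z position of the tube center.  `d_sphere = 45` so that even
the stretch-3 cross-section (axial semi-axis ≈ 12 vx) sits well inside
the 22.5 vx sphere radius, per the validity window above.  Only interior
sites (≥ d_sphere/2 from the tube ends, unflagged) enter the medians.
Problem sizes were chosen so the whole suite runs in seconds while
leaving > 50 sites per grade; recovered medians sit within ~4 % of truth
and increase strictly with the true stretch.

## Double-reflection artifact model

The candidate physical explanation for axial stretching: if the probe
beam reflects twice inside a vessel (extra in-vessel path h between the
two bounce points), the instrument registers a virtual penetration depth
h/2 beyond the true one, so the apparent axial extent of a vessel of
diameter d becomes d + h/2 and the implied quotient

    ε_q(h) = 1 + h/(2d),

affine in h with slope 1/(2d).  When both bounces lie in one lateral
cross-section, h ≤ d, capping the implied quotient at 1.5 (attained at
h = d); quotients above 1.5 — as observed on real data — require
longitudinal reflections, for which the model accepts h > d but does not
attempt a full ray-tracing geometry.  Larger vessels offer more
double-reflection opportunities, consistent with the observed increase
of ε_q with cross-section area.

## Inter-observer agreement

Voxel-wise Cohen's κ between two binary labelings over the ROI (or the
whole volume): `po` the fraction of agreeing voxels, `pe = pA·pB +
(1−pA)(1−pB)` the chance agreement from the two marginal positive rates,
`κ = (po − pe)/(1 − pe)`.  Chance correction matters because vessel
labels are sparse: two raters agreeing on "background" almost everywhere
produce po ≈ 1 regardless of skill.  Degenerate cases: two constant,
unanimous raters (pe = 1) are reported as κ = 1; constant-but-opposite
raters give pe = 0 and κ = 0.  κ is written with 4 decimals by the CLI.
The implementation is cross-checked against scikit-learn's
`cohen_kappa_score` in the test suite.

## Numerical and interface choices

* Sphere membership uses ≤ with a 1e-12 slack so voxels at exactly the
  nominal radius are included regardless of floating-point noise.
* `d_sphere` must be odd (a centered neighborhood); the default is 9,
  connectivity default 26, both CLI-configurable.
* Records CSV is written with `%.17g` floats and read back with
  round-trip parsing, so write→read is the identity, bit for bit.
* CLI exit codes: 0 success, 1 input error, 2 usage error; a YAML config
  may supply any flag, with explicit flags winning.
* Empty masks are data, not errors: they yield empty skeletons and empty
  record lists (with a logged warning); empty *aggregation* input is an
  error that tells the user to run `analyze` first.

## Known limitations

* A_c saturates for cross-sections approaching the sphere radius; the
  caller must size `d_sphere` to the vessels under study (see validity
  window).  No automatic selection is attempted.
* Sub-voxel cross-section estimation is out of scope: the pipeline
  consumes hard labels, and depth is floored at one voxel, which floors
  ε_q at `sz/(s_lat·d_width)` and compresses the quotient range for
  vessels only 1–2 voxels thick.
* The thinning retracts ~1 radius from blunt vessel ends, so per-vessel
  statistics slightly under-sample terminal regions.
* No correction of the stretching artifact is attempted — the package
  quantifies it.
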