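# Methods

## Background and model

Stereotactic centralized ablative radiation therapy (SCART) is a
spatially fractionated technique that prescribes a single ablative core
— the SCART treatment volume (STV) — inside a bulky gross tumor volume
(GTV), while holding the dose at the GTV border to a protection level of
about 5 Gy per fraction. The STV is a geometric construct: a shrunken,
spindle-shaped sub-volume centered in the GTV. This package generates it
from the GTV contour set alone; no CT intensities, dose grids or plan
objects are read.

The generation pipeline, per axial GTV slice:

1. **Seed center.** The 2-D area centroid of the slice polygon
   (shoelace formula).
2. **Polar resampling.** The boundary is resampled onto a uniform
   angular grid about the center; the radius at each angle is the
   distance to the *nearest* boundary crossing of the ray. Using the
   nearest crossing guarantees the polar region — and any radially
   shrunken contour derived from it — is contained in the slice polygon
   even when the slice is not star-shaped about the center (a warning is
   emitted when it is not).
3. **Center refinement.** The centroid of an irregular tumor is often a
   poor radial center: one direction is much longer than another, and a
   shrunken contour centered there sits asymmetrically inside the GTV.
   The refinement loop compares the longest and shortest radial
   distances, r_max and r_min, and shifts the center by
   `step_factor * (r_max − r_min)` toward the angle of r_max, repeating
   until the accepted shift falls below `tol`.
4. **Radial shrink.** Every radius is multiplied by the dose-dependent
   ratio (below) and the contour is rebuilt from the scaled radii at the
   same axial position.
5. **Minimum-radius rule.** STV slices whose equivalent circular radius
   `sqrt(area/π)` falls below 2 cm are removed: narrow slices cannot
   support an adequate lateral dose fall-off and risk high-dose leakage.
6. **Superior–inferior gap.** STV slices within `gap` mm (5–15 mm,
   default 10) of the GTV's axial extremes are removed to accommodate
   respiratory and positional motion along the inferior–superior axis.

An empty result after steps 5–6 raises an error stating that the tumor
is too small for SCART at the requested dose.

### Shrink ratio

Two modes:

* **table** (default): the clinical recommendation — STV/GTV diameter
  ratio 0.36, 0.27, 0.24, 0.21 at 15, 18, 21, 24 Gy with a 5 Gy border —
  linearly interpolated in the prescription dose between the tabulated
  points; extrapolation and non-5 Gy borders are rejected.
* **formula**: the analytic fallback `border_dose / scart_dose`
  (33 %, 28 %, 24 %, 21 % at the same four doses).

Because the shrink is applied per slice in 2-D polar coordinates (not as
a 3-D isotropic scale), the untrimmed volume ratio V_STV/V_GTV equals
ratio² rather than ratio³; the safety rules then reduce it further. The
sphere phantom reproduces ratio² to well within 0.5 %.

### Control ring

A ring of configurable width (default 3 mm) around the PTV (= GTV with
zero margin) is used clinically to cap the border dose. The outer
boundary is a radial expansion of each slice by the width about its
refined center, paired with the original contour as the inner boundary.
Radial expansion approximates a true uniform (Minkowski) margin: exact
for circles, and never off by more than `width·(1 − cos φ_max)` where
φ_max is the largest angle between a ray and the local boundary normal
(≈ 2.12–3.00 mm outward for a 3 mm expansion of a square).

## Numerical choices

* **Angular grid:** `n_angles` = 360 (1° sampling) anchored at the +x
  axis. Radial distances are computed by vectorized ray–edge
  intersection; a ray through a polygon vertex may register on both
  adjacent edges with equal distance, which is deliberate — a half-open
  edge interval can lose a vertex hit to floating-point rounding on both
  edges at once.
* **Refinement parameters:** `step_factor` = 0.1, `tol` = 0.01 mm,
  `max_iter` = 200. The plain shift rule oscillates around its attractor
  on elongated shapes (on an ellipse the max-radius angle flips by π
  each iteration), so a step that would leave the polygon *or would
  increase (r_max − r_min)* is halved until it improves or drops below
  `tol`. This makes the radial disparity monotonically non-increasing —
  the refined center is never worse-centered than the seed centroid —
  and the loop terminates in a handful of iterations on the phantom
  suite. On the egg phantom the result agrees with an exhaustive 0.1 mm
  grid search minimizing (r_max − r_min) to 0.008 mm.
* **Disparity sampling:** inside the refinement loop, r_max/r_min are
  sampled on the uniform grid *augmented with the exact vertex
  directions* from the current center. On a convex polygon the radius
  function attains its maxima at vertex directions, so this makes the
  sampled maximum exact; a uniform grid alone underestimates r_max once
  the center leaves a vertex ray and admits spurious descent steps
  (measured 0.125 mm drift on an equilateral triangle, which the
  augmented sampling eliminates — regular polygons return their exact
  center).
* **Tie-break:** when several angles share r_max, the smallest angle on
  the uniform grid wins; output is deterministic and bit-identical
  across reruns.
* **Known trade-off:** shifting toward the maximum-radius direction can
  *reduce* the worst-case clearance r_min on tapered shapes (up to
  ≈ 1.4 mm on the egg phantom), because the center moves into the
  narrower end. This is inherent to the shift rule, which optimizes
  radial symmetry, not minimum clearance; containment of the shrunken
  contour is guaranteed independently by the nearest-crossing radii.
* **"Radius" in the 2 cm rule:** the equivalent circular radius
  `sqrt(area/π)`, robust to radial spikes; maximum- and minimum-distance
  variants are exposed via `StvParams.radius_rule`.
* **Degenerate inputs:** contours with fewer than 3 distinct vertices,
  zero area, coincident consecutive vertices, or self-intersections are
  rejected with specific errors (self-intersecting input from a TPS is
  rejected, not auto-repaired). Multiple islands on one z keep the
  largest polygon with a warning; holes are unsupported.

## Synthetic phantoms

All geometric tests run on generated phantoms; no clinical contours are
bundled. The generators emulate the geometry the pipeline must handle —
known volumes (sphere, ellipsoid), the spindle target shape, a
deliberately asymmetric "egg" (convex hull of two merged spheres, whose
area centroid and radial center differ by construction), and irregular
star-shaped "lobed" tumors (random-phase cosine perturbations of a
sphere, driven by a single integer seed; identical seeds reproduce the
structure bit-for-bit). They do **not** emulate several features of real
GTVs: non-star-shaped or multi-island cross-sections, holes, contour
noise from manual segmentation, or slice-to-slice misalignment. Passing
phantom tests therefore demonstrates the geometric contracts
(containment, determinism, scaling, convergence) but not robustness to
every clinical contouring artifact.

Containment and determinism are exercised on 1000 seeded lobed phantoms
(base radius 30 mm, 10 mm spacing — five slices each — 120 angular
samples, refinement capped at 50 iterations); the sphere oracle uses
R = 60 mm at 2 mm spacing, and the center-refinement oracle compares
against a 1 mm exhaustive grid pass refined to 0.1 mm locally.

## Dose-band statistics

The bundled 21-patient table records, per patient and per arm (manual
vs automated STV), the percentage of GTV volume receiving dose in four
bands (1500–3000, 3000–4500, 4500–5400, > 5400 cGy). `column_summary`
reports the arithmetic mean and the **population** standard deviation
(divisor n): recomputing the manual 1500–3000 column gives 7.58 with
divisor n versus ≈ 7.77 with divisor n − 1, and only the former matches
the table's printed "STD V" row, so the population convention is
documented prominently. Two printed SD cells carry a last-digit rounding
quirk (exact 4.7737 printed as 4.78; exact 0.6259 printed as 0.62).

`paired_two_tailed_test` is the standard paired t-test (sample SD of
differences, n − 1 degrees of freedom), cross-checked against
`scipy.stats.ttest_rel`; identical vectors return p = 1 by convention.
Which dose-volume metric underlies the reported significance of the
manual-vs-auto comparison is not specified with the table, so no column
is asserted against it; for reference, running the test on the > 5400
cGy column of the bundled table yields p = 0.0023. `percent_change` on
the > 5400 cGy band means (6.8 → 7.8) gives +14.7 %, consistent with the
reported ≈ 15 % increase in high-dose volume, though the exact volume
definition behind that figure is not stated and is left unasserted.

## Serialization

The JSON contour dialect stores structures as named lists of
`{z, vertices}` slices in mm, serialized with sorted keys and fixed
`%.3f` floats (1 µm), so identical documents produce identical bytes.
DICOM RT Structure Sets are read and written with pydicom
(CLOSED_PLANAR contour items only; other geometric types are rejected).
Written RT-STRUCT files are standalone — generated frame-of-reference
UID, no referenced image series — which suits synthetic data; importing
into a clinical TPS may require the referenced CT series.

## Limitations

* The algorithm assumes co-planar photon delivery with an approximately
  rotationally symmetric dose fall-off; it is not meant for particle
  therapy, and for non-co-planar techniques it tends to be conservative.
* OAR-driven reshaping of the STV (e.g. enforcing a 1.5 cm separation
  from a critical organ) is a planning decision and is out of scope;
  only the geometric ring construction is provided.
* Dose is never computed: the dose-band statistics operate on an
  externally supplied table, and the STV is a contour, not a dose
  object.
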