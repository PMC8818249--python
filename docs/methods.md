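# Methods

This note documents the models, numerical choices and limitations behind
`shouldersim`, in the order data flows through the package.

## Coordinate conventions

All world coordinates are DICOM LPS (x to the patient's left, y
posterior, z superior), in mm. NIfTI files carry RAS affines and are
reoriented on read/write; a single internal convention avoids
view-direction sign errors between the volume, the projector and the
landmarks. Voxels are indexed from 0 and voxel *centers* lie on the
world grid, so a grid of shape `n` with spacing `s` spans
`[-s/2, (n-1/2)·s]` — the convention assumed by trilinear interpolation
and by the projector's ray/box intersection.

## Synthetic shoulder phantom

The phantom emulates the contrast of a 3D T1-weighted spoiled
gradient-echo shoulder acquisition (transverse plane, 0.3 × 0.3 mm
in-plane, 0.4 mm slices, ~150 × 150 × 80 mm³ field of view): bright soft
tissue, dark cortical bone, a textured trabecular interior, near-zero
background. It is deliberately *geometric*, not anatomical — every
structure is a sphere, spherical shell, ellipsoid or box, so each has a
closed-form projection and exact landmark positions:

* humeral head: sphere (default radius 18 mm) with a 1.5 mm cortical
  shell and trabecular core;
* glenoid: a 3 mm-thick spherical shell concentric with the head
  (radii 20–23 mm, leaving a 2 mm joint space), cut by a plane to a
  medial cap facing the head (default half-angle 40°);
* acromion: a box above the head, its inferior face 10 mm above the head
  apex (the phantom's true acromiohumeral distance);
* soft tissue: a large ellipsoid strictly enclosing all bone (required
  by the mask's hole-filling step, and true of a real shoulder).

Intensity defaults (fractions of maximum signal): soft tissue 0.8,
cortical bone 0.15, air 0.02, background noise SD 0.01. The trabecular
texture is a band-limited random field — white noise smoothed with a
Gaussian of 1.5 mm correlation length, thresholded to ±0.05 about the
cortical level — which gives the projector visible internal structure
without anatomical modeling. Noise is additive Gaussian clipped at zero;
a magnitude-MR Rician tail is not needed to exercise the pipeline.
Generation is a pure function of `(spec, seed)`.

The default grid is 96 × 96 × 64 at 1 mm isotropic so the full chain
runs in seconds; `PhantomSpec.clinical()` provides the full-resolution
variant (500 × 500 × 200 at 0.3/0.4 mm) with identical mm-scale anatomy.
The implied morphometrics — AHD 10 mm, CSA ≈ 32.3° — sit inside the
ranges reported for adult shoulders (AHD ≈ 7–14 mm, CSA ≈ 28–38°).

Landmarks are emitted in world mm, not voxel indices, because the
measurements are defined in mm and must survive resampling.

What passing tests on this phantom do **not** show: robustness to coil
bias fields, motion, wrap-around, partial-volume fat/water shifts, or
anatomical shape variation. The phantom validates the *computational*
chain (masking, inversion, enhancement, projection, measurement), not
clinical performance.

### Rasterization and the projector oracle

`rasterize_bodies` voxelizes analytic bodies with an anti-aliased edge:
the interior indicator ramps linearly from 1 to 0 over a configurable
width (default half the smallest voxel), approximating the partial
volume of boundary voxels. This matters quantitatively: the dominant
error when comparing a ray-marched projection of a voxelized sphere
against exact chord lengths is the O(voxel) rim discretization, and the
soft edge roughly halves it. On the 96³/1 mm grid a 42 mm unit sphere
projects with < 1% relative L2 error against the closed-form oracle at
`step_fraction = 0.25`; hard (non-anti-aliased) rasterization of the
same sphere gives ~1.3–1.9%. The oracle itself computes chords by
interval arithmetic — quadratic roots for spheres/ellipsoids, slab
clipping for boxes, half-space clipping for caps, inner-sphere
subtraction for shells — and is exact.

## CT-like conversion

The chain is mask → invert → CLAHE → 15th power → remask, with the mask
computed on the original volume and applied last.

* **Masking.** Otsu threshold (with a fixed-threshold fallback),
  morphological closing with a 2 mm ball, largest connected component,
  then hole filling. The hole filling is essential, not cosmetic: on a
  three-level image (air ≈ 0, bone ≈ 0.15, soft ≈ 0.8) Otsu's
  between-class criterion can place the threshold *above* bone, so dark
  bone interiors land on the background side; because bone is enclosed
  by soft tissue, filling holes in the largest component restores the
  correct body mask regardless of which side of the threshold bone fell
  on.
* **Inversion.** The power step is meaningless on arbitrary intensity
  scales, so inversion first rescales to [0, 1] by clipping at the 1st
  and 99th percentiles (robust to outlier voxels), then maps
  `x ↦ 1 − x`. With percentiles (0, 100) the step is an involution.
* **CLAHE.** Contrast-limited adaptive histogram equalization, by
  default per axial slice (the emulated sequence is acquired
  transversely) with 8 × 8 tiles and clip limit 0.01; a volumetric
  variant (`clahe_3d`) is available and is the one that commutes with
  axis permutations. Constant inputs pass through unchanged.
* **Power.** `x ↦ x¹⁵` pointwise. On [0, 1] this fixes 0 and 1, is
  strictly monotone, and contracts everything else
  (0.5¹⁵ ≈ 3.05 × 10⁻⁵), which is what turns "brightest" into
  "essentially alone in the image" — the CT-like bone contrast.
* **Remask.** Background is set to exactly 0 so enhancement artifacts in
  air can never streak the forward projection.

The defining output contract, asserted in tests: background exactly
zero, intensities in [0, 1], and mean(bone) > mean(soft tissue) whenever
the input ordering was the opposite.

Whether a renormalization belongs between CLAHE and the power step is a
genuinely open design point; the package keeps both the percentile
window and the exponent as parameters rather than hard-coding one
answer.

## Cone-beam projector

Fixed-step ray marching with trilinear interpolation. For each detector
pixel a ray runs from the point source through the pixel center; the
ray's chord through the volume bounding box is split into equal steps no
longer than `step_fraction` × min(spacing) and integrated by the
midpoint rule, so there is no end-of-ray truncation error; samples
outside the volume contribute zero. The projection is a plain line
integral — no Beer–Lambert exponentiation — because the CT-like volume
is a contrast surrogate, not calibrated attenuation, and the plain
integral directly yields bone-bright radiograph display.

Geometry defaults mimic clinical shoulder radiography: source-isocenter
1000 mm, source-detector 1150 mm (magnification 1.15), 512² detector
with pitch auto-chosen so the volume's projected diagonal fills ~80% of
the detector. The AP view runs along the anterior-posterior axis; the
scapular-Y view defaults to 45° about the superior-inferior axis; both
are conventions of this package, since clinical obliquity varies.
Detector rows run inferiorly (superior at the top of the image).

Verified properties: linearity in the volume, convergence under step
refinement, exact mass conservation for axis-aligned parallel
projection, shadow scaling by sdd/sid, and agreement with the
orthographic projector in the sid → ∞ limit (< 0.5% at sid = 10⁶ mm).

## Morphometry

AHD and CSA are computed from named landmarks only; the package never
detects landmarks in images (automatic landmarking is a separate,
harder problem). Both are rigid-motion invariant; CSA is additionally
scale-invariant. Pixel-click coordinates convert to mm via the detector
pitch, optionally divided by the magnification to report object-plane
distances — cone-beam projections magnify, and whether published
measurements are magnification-corrected is often unstated, so the
correction is explicit and opt-in.

The printed Samilson-Prieto bands (<3, 3–6, ≥7 mm) leave (6, 7) mm
unassigned. The package uses half-open bands [3, 7) → II and [7, ∞) → III
so every size has a grade and grading stays monotone, and warns when a
size falls in the ambiguous (6, 7) interval. The Bigliani acromion type
is recorded and validated but never computed: its definition
(flat/curved/hooked) is qualitative, with no numeric rule to implement.

## Agreement statistics

Cohen's κ is computed from the two raters' contingency table; Fleiss' κ
from the item × category count matrix. Both are implemented as
vectorized count-matrix computations so that the bootstrap (2000
resamples over items by default, percentile intervals, clipped to
[−1, 1], seeded) costs milliseconds; both are cross-checked in the test
suite against `statsmodels` and against an independently coded
brute-force evaluation of the formulas — exhaustively over every
two-rater table with ≤ 4 categories and ≤ 6 items.

Choices worth stating:

* **CI method.** Reader studies report intervals like "0.84
  (0.64, 1.00)" without naming a method. The percentile bootstrap over
  items is valid at small n and for ordinal data, and its clipping
  reproduces intervals that end exactly at 1.00.
* **Weighting.** Unweighted κ is the default; linear and quadratic
  weights are options for ordinal scales.
* **Degeneracy.** If both raters give one identical rating throughout,
  chance agreement is 1 and κ is defined as 1 with a warning.
* **Missing data.** Pairwise deletion per item, with a count in the
  warning.
* **Paired tests.** Paired t for numeric variables, McNemar (χ²,
  no continuity correction) for binary, Wilcoxon signed-rank for
  ordinal, all two-sided; Wilcoxon excludes zero differences and
  switches from the exact distribution to the normal approximation at
  25 non-zero pairs. All-zero difference vectors return p = 1 with a
  warning rather than an exception, since "no difference at all" is an
  answer, not an error.

The simulator draws rater 1 from a marginal distribution and lets
rater 2 copy with probability `a`, else redraw independently. Then
`p₀ = a + (1 − a)·Σpᵢ²` and `pₑ = Σpᵢ²`, so κ = a exactly — the copy
probability is the recoverable ground truth. Recovery and bootstrap-CI
coverage (≥ 90% over 200 replicates at n = 2000) are part of the
acceptance checks.

## Problem sizes

Tests and the acceptance script use the 96 × 96 × 64 (1 mm) phantom,
96³ oracle spheres, 128² detectors, 2000-item rating tables and
2000-resample bootstraps — sizes chosen so the full suite and the
acceptance run each complete in well under a minute of compute apiece
while keeping discretization and Monte-Carlo error far from the asserted
tolerances.

## Known limitations

* No MR physics: the phantom models contrast, not acquisition (no bias
  field, Rician noise, chemical shift, susceptibility).
* The projector has no scatter, beam hardening, focal-spot blur or
  detector noise; it is a geometric DRR engine.
* NIfTI spacing/origin round-trip to the precision of the format's
  float32 header, not to float64.
* Fleiss' κ requires an equal number of ratings per retained item.
* The DICOM reader supports axis-aligned (identity-orientation) series
  only — sufficient for phantom-derived data, not for arbitrary clinical
  acquisitions.
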