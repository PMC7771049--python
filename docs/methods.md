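# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what is computed, under what
assumptions, and what the synthetic phantoms do and do not emulate.

## Coordinate and pose conventions

All geometry lives in a single convention: voxel indices are 0-based, the
world frame is RAS in millimetres, and the world point of a voxel is its
centre.  Volumes carry a diagonal voxel-to-world mapping (spacing +
origin); paired volumes always share a grid, so no resampling machinery
exists.

A rigid pose is six parameters (tx, ty, tz in mm; rx, ry, rz in degrees).
Its matrix is `Translate(t) ∘ Rz(rz) ∘ Ry(ry) ∘ Rx(rx)`: right-handed
extrinsic rotations about the world axes at the world origin.  The
interactive workstation this models had its own (undocumented) rotation
sequence; any fixed, documented convention preserves the error statistics,
and reproducibility was preferred over fidelity to a commercial black box.
Pose averaging (the "geometric centre" gold standard over repeated
registrations) is the component-wise mean in parameter space.  For the
sub-degree, sub-millimetre spreads at issue this differs negligibly from
proper rotation averaging (quaternion/chordal); at larger spreads it would
not, which is a known limitation.

## Monte-Carlo registration error

The spatial error of one registration attempt against the gold pose is the
mean of ‖T_trial(p) − T_gold(p)‖ over points p in the cortex of interest,
delimited by a 3D binary mask (in the original workflow a contrast-raised
FDG-PET cortex; here a given input, since no threshold for it is
specified).  "Random pixels" are voxel centres drawn uniformly with
replacement from the mask, no intra-voxel jitter: the jitter contribution
is far below voxel size.  The default 5,000 points keep the estimator's
repeatability (SD over independent repeats) below 0.01 mm for ~1 mm
errors; for translation-only perturbations the estimate is exact for any
mask and any n, and `exhaustive_spatial_error` provides the brute-force
all-voxel reference used by the tests.  Distances are in world mm.
Intra-/interobserver variability are unweighted grand means of per-unit
(per-patient / per-operator) mean errors, rounded to 2 decimals for
display only.

A caveat inherited from the procedure itself: the gold standard is the
mean of the same trials scored against it, so the per-trial errors are not
independent of the gold pose.  The package computes exactly what the
procedure describes and does not correct for this.

## Fusion and thresholding

Fusion copies the structural channel and labels angiography voxels with
value **strictly greater** than the threshold as vein (the strict reading
of "above a specific brightness value" — applied uniformly everywhere a
threshold appears).  The monochrome-blue display is presentation only; the
data model stores a boolean label.  `threshold_sweep` quantifies the
high/low trade-off with voxel counts and 26-connected component counts
(26-neighbourhood is the standard choice for thin 3D vessels and makes the
"discontinuous and broken" fragmentation countable and reproducible).  The
per-case threshold is an input, never auto-selected.

## Sculpting and projection

Sculpting cuts are orthographic and depth-unbounded: every voxel whose
projection along the viewing direction falls **strictly inside** the
marked polygon is set to the background value 0; voxel centres exactly on
the polygon boundary are kept (documented tie rule; immaterial to any
statistic).  A sequence of cuts over rotated views equals the single
removal of the union of their 3D cut regions.

All rendering is orthographic (maximum-intensity projection and polyline
projection share one view frame: image axes `direction × up` and `up`), so
angles and lengths read in a view plane are exactly the projected 3D
quantities.  The six standardized views are fixed: view 1 looks along −z
(up = anterior); views 2/3 tilt it 40° toward frontal (+y) / occipital;
view 4 is the left lateral view (−x, up = superior) tilted 30° cranially;
views 5/6 tilt the lateral view 30° frontal/occipital **first**, then 30°
cranially (the verbal view definitions admit several composition orders;
this one is fixed and documented, and views 2/3 and 5/6 are mirror pairs
under y-negation).  The surgical photograph is modelled as an orthographic
view composed with an unknown 2D similarity, recovered from ≥2 matched
landmarks by the closed-form least-squares Procrustes-with-scale solution;
perspective and lens distortion are out of scope.

## Five-category validation

Marked vein sections are short 2D polylines.  The match score between two
sections is the mean symmetric polyline distance: both traces resampled at
0.5 mm arc-length steps, directed mean nearest-point distances averaged
both ways.  This is a reproducible surrogate for the original expert-eye
matching; it is exactly zero on coincident traces.  Matching is greedy
one-to-one in ascending distance (ties broken by lower section index),
accepting only pairs within a tolerance (default 3 mm — below typical
inter-vein spacing, above tracing jitter; no value is prescribed by the
source workflow, so it is configurable).  A matched pair counts **once**
(Category 0); the published totals (179 categorized = 140+21+8+4+6 vs 158
reconstruction + 161 photo sections) are only consistent with pairs
counted once, which fixes the bookkeeping.  Unmatched photo veins are
Category 1; unmatched reconstruction sections are Category 3 if within
tolerance of a photo artery trace, Category 4 if ≥50 % of their arc length
lies inside an occluded photo region, else Category 2.

## Bridging-vein anatomy

The superior sagittal sinus is an ordered anterior→posterior centreline;
thirds are arc-length thirds with half-open intervals [0, L/3), [L/3,
2L/3), [2L/3, L] — a junction exactly on a boundary goes to the posterior
interval.  Side is the vein's hemisphere; the generator assigns it
directly, and the documented tie-break for measured data (midline → left)
follows the junction-adjacent centroid's x sign.

The confluence angle is measured between (a) the vein's terminal unit
direction, pointing from the junction **away** from the sinus along the
vein, estimated from the first 5 mm of centreline (configurable, damps
tracing noise), and (b) the **posteriorly** oriented local sinus tangent,
both projected into the view plane of views 1–3; the result lies in
[0°, 180°].  This convention makes anterior (frontopolar) veins obtuse
(~110°) and occipital veins acute, matching the anterior-obtuse →
posterior-acute pattern of the measured group means.  The unprojected 3D
angle is reported alongside for comparison, since how the original
measurements corrected for out-of-plane foreshortening is not documented.
Group summaries use the mean and the mean absolute deviation
MAD = (1/n)Σ|xᵢ − mean|; per subject, up to the two largest-caliber veins
per positional group enter the angle sample.

Drainage types I–V are assigned from the caliber ranking of the Trolard,
Labbé and superficial Sylvian anastomotic veins by an **explicit,
parameterized stand-in rule** (balanced if max/min < 1.5; otherwise the
dominant vein decides II/III/IV; V if one vein is absent (< 0.3 mm) and
the remaining two are co-dominant; a hemisphere without recorded calibers
is "not assessable").  The published typology's source definitions are an
external reference not reproduced here; the rule table is not presented as
that classification.

## The phantom generator

The generator emulates the *statistical* conditions of the study, not MR
physics or cortical folding:

* **Grid**: 128³ at 1.5 mm isotropic (≈19 cm field of view), chosen so a
  full-pipeline run stays at desk scale.  Head = smooth ellipsoid
  (radii 60 × 75 × 60 mm, intensity 60), cortex = 4 mm outer shell
  (intensity 80), additive Gaussian noise σ = 5.
* **Sinus**: midline sagittal arc just beneath the vertex.
* **Counts**: per (side, third) Poisson with means 4.3/4.4/2.3 (left) and
  4.1/4.5/2.0 (right); junction arc positions uniform within their third.
* **Angles**: each junction's positional group is its arc-fraction sextile
  (anterior→posterior); its angle is drawn from a truncated normal with
  the group's reported mean and σ = MAD·√(π/2) (the normal-theory
  conversion), truncated to a per-group plausible range derived from the
  per-vein ranges reported for the veins composing each group.  Only
  means, MADs and ranges are reported for the angle data; the truncated
  normal is a stated distributional choice.  Where a range is strongly
  asymmetric about the mean (notably the occipital group), the truncated
  distribution's true mean differs from its location parameter by several
  degrees; parameter-recovery tests therefore compare measurements against
  the analytic truncated-normal mean (`group_truncated_mean`) — the mean
  of what the generator actually samples — so they test the measurement
  chain, not the truncation bias.
* **Vein geometry**: each vein starts at its junction with a straight
  10 mm terminal segment laid in the axial plane at the sampled angle to
  the axially projected posterior sinus tangent (so the view-1 measured
  angle equals the generated angle by construction), then a descending
  lateral segment.  Real veins curve continuously; this simplification is
  deliberate, because it makes ground truth exact.
* **Vessels**: tubes rasterized at intensity 100 over noise σ = 5, so the
  default threshold 50 segments ≥99 % of centreline voxels; vein radii
  uniform in 0.8–2.0 mm, sinus radius 3 mm.
* **Drainage**: per hemisphere, assessable with probability 19/23; types
  sampled with frequencies 9:3:3:3:1 (I:II:III:IV:V) and calibers
  constructed to realize the sampled type under the rule table.
* **Photographs**: reconstruction marks = projected vein polylines with
  i.i.d. Gaussian vertex jitter (σ = 0.5 mm); photo marks start from the
  exact projections, then a dropout fraction (0.15) is removed (truth
  Category 2), photo-only veins are added outside the footprint
  (Category 1, n = 3), some veins are replaced by artery traces offset
  0.6 mm (Category 3, n = 2) or covered by occlusion polygons
  (Category 4, n = 1); everything photo-side is mapped through a 2D
  similarity misalignment (scale 1.1, 5°, (4, −3) mm), with matched
  landmark pairs emitted for re-alignment.  Brain-shift-like smooth
  deformation is deliberately excluded: the working premise of vein-based
  validation is that veins move with the cortex, so a rigid + similarity
  alignment suffices at mark level.

What passing closed-loop tests show is that the *measurement chain* —
projection, alignment, matching, classification, angle and count
measurement — recovers known ground truth under controlled noise.  They do
not show robustness to gyral anatomy, TOF flow artefacts, perspective
photography or expert-judgment ambiguities, none of which the phantom
models.

## Numerical choices and degenerate inputs

Thresholds are strict everywhere; thresholding is monotone.  Empty masks,
empty trial sets, empty category lists, degenerate polygons, single
landmark pairs and veins projecting to a point in the measurement view all
raise `ValueError` rather than returning silent defaults.  Percentages are
rounded to one decimal, observer means to two, for display only — full
precision is kept internally, and per-side totals are full-precision sums
of thirds (so they may differ from sums of rounded per-third means in the
last digit).  All randomness flows through seeded `numpy` generators;
repeated-estimate spreads use independent child seeds spawned from one
`SeedSequence`.

## Problem sizes used by the test and acceptance runs

The repeatability and oracle checks run on the 128³ (1.5 mm) cortex-shell
mask (~63 k voxels, within exhaustive-oracle reach), with 20 × 5,000-point
estimates; parameter recovery uses 200 geometry-only phantoms (~400 angles
per group); closed-loop validation pools five phantoms' photographs
(~100 sections).  These sizes were chosen as the package's own desk-scale
defaults: large enough for the statistical bounds tested, small enough to
run interactively.
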