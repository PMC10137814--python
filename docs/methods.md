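# Methods

## Scope

`cinevol` measures left-ventricular function from short-axis cine MRI with
a pixel-based (intensity-classification) method, emulates the conventional
contour-surface method at mask level, estimates papillary-muscle volume
from the difference between the two readings, and tests method equivalence
with paired TOST statistics.  Because no image data ship with the package,
a digital cine phantom with analytic ground truth is a first-class module:
every downstream stage is validated against it.

## The digital cine phantom

**Geometry.** The acquisition emulated is a clinical SSFP cine protocol:
1.8 × 2.5 mm in-plane voxels, 8 mm slices with a 10 % gap (8.8 mm
centre-to-centre), 13 slices, 25 cardiac phases.  The nominal voxel volume
is spacing_row × spacing_col × thickness = 36 mm³; the gap enters only the
Simpson slice spacing.

**Shape model.** The endocardial cavity is a half-ellipsoid of revolution:
full radius R at the base, radius R·√(1 − (z/L)²) at depth z, closing at
the apex (z = L).  Analytic cavity volume (2/3)πR²L.  The myocardium is a
concentric half-ellipsoidal shell whose outer surface is scaled so that the
shell volume is a constant 130 mL in every phase — mass conservation is
built in analytically, so any per-phase variation of the truth myocardium
volume is pure voxelisation error (< 3 %).  Papillary muscles are vertical
cylinders (defaults: three bodies of radius 6.5 mm spanning 18–55 mm below
the base, ≈ 14 mL total, two pinned to the wall with 2.5 mm of shared
tissue, one free in the lumen at 35 % of the local cavity radius).  Their
axial extent is fixed in millimetres — muscle does not contract in volume —
so the papillary volume is nearly phase-constant, as the estimator algebra
assumes.

**Contraction.** The user specifies the true *blood* EDV and EF (defaults
177 mL and 0.508, typical adult cohort means).  Blood volume follows a
cosine curve from ED (phase 0) down to ES (phase 10 of 25) and back; for
each phase the cavity scale factor is solved numerically (Brent) so that
the blood volume — cavity minus the papillary cross-sections, integrated
along the long axis with circle–circle intersection areas — hits the target
exactly.  Requested and rasterised truth EF therefore agree to within
voxelisation error (2 % absolute tolerance in the tests).

**Rasterisation and truth.** Truth volumes are voxel counts on a 4×
in-plane oversampled rasterisation of the analytic shapes, per slice, times
the slice spacing.  Through-plane the same midpoint (slice-centre) rule is
used as in any slice-wise Simpson measurement, so truth and measurement
share the through-plane discretisation and differ only by in-plane partial
volume.  Native-resolution truth masks use pixel-centre membership.

**Intensities.** Blood 400, myocardium (and papillary muscle) 120,
background 40 (arbitrary units, bright-blood contrast); additive Gaussian
noise with σ = 20 (5 % of blood signal) by default, clipped at zero.
Intensity assignment is hard (pixel-centre class), without partial-volume
mixing: this keeps the noiseless phantom exactly recoverable by the
segmenter, which separates voxelisation error from algorithmic error in the
tests.  Consequences: passing tests bound discretisation and noise effects,
but say nothing about partial-volume bias, surface-coil shading, flow
artefacts or trabeculation in real scans.  One slice above the base carries
an atrial-transition scene (blood pool, 120° open myocardial arc) in the
intensities only, to exercise the basal-slice rule.

## Brush segmentation

At each cursor position of a stroke the local statistics (min, max, mean,
population variance) of the brush disk (Euclidean, pixel units, clipped to
the image) define an intensity window

    lo = max(min, mean − k·σ),  hi = min(max, mean + k·σ),   k = 2 default,

unless fixed thresholds are given, which replace the derived window
entirely.  Growth is a 4-connected component search restricted to the
brush disk, strictly 2D per slice; a seed whose intensity falls outside the
window contributes an empty mask and a warning (the operator painted
non-blood tissue) rather than an exception.  The union over a stroke's
positions is closed with a disk element of radius 1 pixel — large enough to
fill single-pixel noise holes, small enough not to bridge the blood pool to
the myocardium.

The k = 2 default makes the window cover ≈ 95 % of blood voxels under
Gaussian noise while excluding myocardium at the phantom's
contrast-to-noise ratio; the min/max clip keeps the window inside the
locally observed range when the variance is inflated by mixed tissue.

**Scripted strokes.** The interactive brush is replaced by a planner that
paints a target mask the way an operator would: coarse serpentine passes
with a radius-4 brush at positions whose whole disk lies inside the target
(single-tissue statistics), a fine radius-1 pass from interior pixels next
to anything the coarse disks missed, and — only for pixels in channels too
narrow for any single-tissue brush, e.g. between a wall-attached papillary
muscle and the wall — direct painting with fixed thresholds sampled
beforehand from the deepest blood pixel.  The planner sees only the target
mask (plus one intensity sample for the thresholds); segmentation decisions
remain the algorithm's.

## Volumetry conventions

* Basal slice: scanning from the atrial side, the first slice whose
  myocardial evidence covers ≥ 50 % of 360 angular bins around the
  blood-pool centroid.  Each evidence pixel blocks the angular interval it
  subtends (half a pixel diagonal wide), so a closed digital ring scores
  1.0 at any resolution; evidence farther than 3× the blood-pool radius is
  ignored.  The base is determined separately at ED and ES.
* ED is the first cine image; ES is the argmin of blood area over phases on
  the mid-third slice (basal + ⌊n_included/2⌋), ties to the lowest phase.
* Slices from the basal slice to the last non-empty one enter
  V = Σ areaᵢ × spacing; the spacing includes the 10 % gap by default
  (tissue in the gap has volume) with `include_gap=False` available for
  gap-free arithmetic.  Volumes are reported in mL.
* EF is stored as a fraction everywhere and rendered as percent only at
  I/O, because the papillary estimators divide by fractional EF.

## Contour emulation and papillary estimators

The contour reading of a slice is emulated as the hole-filled union of
blood and papillary masks — the comparison algebra depends only on the
enclosed region, not on how a human draws the spline.  The lumen-only
automatic papillary segmentation is emulated by dropping every papillary
component with a pixel 4-adjacent to the myocardium (a modelling choice;
the commercial rule is proprietary).

With KfM = PbM + PM per subject, the four estimators PM1–PM4 are exact
(property-tested to 1e-9 relative over random consistent triples); on
measured data their spread reflects measurement error and the arithmetic
mean is reported.  Aggregation over subjects averages per formula first;
rounding (half-even, 1 decimal) happens only at presentation.

## Statistics

Equivalence uses the two one-sided paired t-tests with margin
0.3 × SD(differences) — the paired Cohen's d_z convention, the only margin
computable from paired data alone; d and α (0.05) are configurable.  The
p-values match `statsmodels.stats.weightstats.ttost_paired` exactly given
the same margin (unit-tested).  Because the margin is estimated from the
sample, the procedure is slightly conservative: Monte-Carlo calibration at
a true difference equal to the margin gives an equivalence rate of ≈ 0.042
at nominal α = 0.05 (n = 50), and power > 0.95 at zero true difference
(n = 200).  No multiple-testing correction is applied.

The synthetic cohort generator draws per-subject EDV ~ N(177, 64²) mL
(truncated at 60), EF ~ N(0.50, 0.16²) (truncated to [0.13, 0.80]) and
PM ~ N(14.2, 3²) mL, constructs the contour reading as PbM + PM, and adds
independent N(0, 3²) mL measurement noise to each volume reading — the
structural situation the estimators assume, with SV equivalent between
methods and EF not.  Cohort reports flag subjects whose SV differs by more
than 15 % between methods for re-evaluation.

## Problem sizes used in the shipped checks

The default test run and the acceptance script use one full-size phantom
per noise condition (13 slices × 25 phases × 96 × 80 pixels), a reduced
phantom (9 × 8 × 64 × 48) for per-module tests, a 191-subject synthetic
cohort, 1000 random triples for estimator exactness, 100 random images for
the region-growing oracle, and 3000 Monte-Carlo replicates for the TOST
calibration.

## Known limitations

* No MRI physics (no Bloch/k-space simulation, Rician noise optional in
  principle but not implemented, no arrhythmia or breathing artefacts).
* Region growth is confined to the brush disk; whether the original
  interactive tool may leak along connected bright tissue beyond the brush
  is unspecified, and "within the brush size" is read strictly.
* The wall-adjacency rule for luminal papillary volume is an emulation of
  proprietary behaviour.
* Published per-patient tables and cohort p-values cannot be reproduced
  without the original patient data; the property suites bound the
  algorithmic behaviour instead.
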