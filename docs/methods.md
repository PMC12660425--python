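# Methods

## Background and scope

In polycystic liver disease (PLD), progressive cyst growth enlarges and
deforms the liver, and total liver volume is the key morphometric endpoint
for staging and for judging treatment effect (e.g. after transcatheter
hepatic artery embolization, TAE). The reference measurement —
slice-by-slice manual tracing of the liver on axial CT, summed by a
workstation ("semi-automatic volumetry") — is accurate but slow.
`pldvol` implements two simplified linear-dimension proxies and the
statistical machinery used to validate them against reference volumetry,
together with a synthetic phantom generator so the entire pipeline can be
exercised, end to end, without clinical data.

## Volume indices

All diameters are in cm, volumes in cm³ ≡ mL. Slice thickness enters in
mm and is converted once at ingestion.

**BASiM** (bi-axial simplified measurement). Three diameters on axial CT:

* CC — count of axial slices containing liver × slice thickness;
* AP — on the slice where the liver protrudes most ventrally, the
  distance from the ventral liver surface to the posterior landmark (the
  junction of the vertebral lamina and the spinous process); when no
  spine information is available the implementation falls back to the
  posterior-most liver voxel on that slice;
* ML — the maximum transverse liver diameter on that *same* slice.

The index is `CC × AP × ML` and the calibrated volume is `index / 3`
(divisor mode) or `index × 0.346` (regression mode).

**QDSiM** (quadri-dimensional simplified measurement). The liver is split
at the body midline. Per side, CC is the side's liver-containing slice
count × thickness and AP is the maximal per-slice antero-posterior extent
of that side over all slices; ML is the transverse extent on the slice of
maximal whole-liver transverse diameter. The index is
`(LCC·LAP + RCC·RAP) × ML / 2`, calibrated by `/ 2` or `× 0.497`.

Why a divisor near 3 (or 2) works: for an ellipsoidal solid the ratio of
true volume to bounding product is π/6 ≈ 0.524, i.e. the product
overshoots by a factor ≈ 1.91. Measuring AP out to the spine rather than
the liver's own dorsal surface, and CC across cyst-interrupted slices,
inflates the product further, which is how the clinically fitted BASiM
factor reaches ≈ 3. The package treats 0.346/0.497 as fitted slopes of
reference volume on index; divisor mode is the default because it is the
calibration applied in practice.

**Change rate**: `(post − pre) / pre × 100` (%), undefined for `pre ≤ 0`.

Both calibrations are linear and order-preserving, so cohort medians of
calibrated volumes equal calibrated medians of indices (this is asserted
as a property test and used in the worked examples).

## Mask measurements

Masks are binary voxel grids with mm spacing, reoriented at load to
canonical axes (axis 0 left→right, axis 1 posterior→anterior, axis 2
inferior→superior) using the NIfTI header affine. Conventions that matter
numerically:

* coordinates are voxel-center based, 0-based; extents are measured
  between outer voxel faces, `(index span + 1) × spacing`, so a single
  voxel has extent = spacing;
* ties (several slices attaining the ventral-most coordinate, or the
  maximal transverse extent) resolve to the most cranial slice —
  deterministic and independent of traversal order;
* CC counts slices that actually contain liver; slices fully interrupted
  by cysts are not counted (the alternative — bounding-index span — would
  count them; the slice-count reading matches the "count the slices"
  measurement rule);
* the QDSiM midline defaults to the grid center on axis 0 (the *body's*
  median for a centered scan), overridable; a side with no liver voxels
  degrades to zero diameters with a warning and the index collapses to
  the other side's term;
* the reference volume is the foreground voxel count × voxel volume —
  the in-silico equivalent of the traced-region volumetry.

Slice-thickness resampling rebins axis 2 on a shared origin; an output
slice is foreground when ≥ 50% of its source column (overlap-weighted) is
foreground. Thinner-than-source output requires an explicit
`interpolate=True`, since it implies sub-slice information.

## Agreement statistics

Implemented from their defining formulas (libraries are used only for
distribution quantiles and ranking; `pingouin` and
`scipy.stats.spearmanr` serve as independent cross-checks in the tests):

* **ICC(2,1)** — two-way random-effects, single-measure, *absolute
  agreement*: `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` from
  the two-way ANOVA mean squares, with the F-based 95% CI using
  Satterthwaite degrees of freedom. The named model does not by itself
  fix the agreement/consistency variant; absolute agreement is the
  standard reading for method comparison and penalizes systematic rater
  offsets. Negative estimates are reported as computed (with a warning),
  not truncated. An all-identical matrix returns ICC 1 with a degenerate
  CI. Exact CI conventions differ between software packages at the second
  decimal; the interval here follows the Shrout–Fleiss/McGraw–Wong form.
* **Bland–Altman** — differences oriented first − second (stated in every
  report header, since the sign of a mean difference is
  orientation-dependent); limits of agreement are mean ± 1.96·SD with the
  sample SD (n−1). The multiplier 1.96 is a fixed constant, not
  recomputed from n.
* **Spearman** — average ranks for ties, Pearson correlation of the rank
  vectors, two-sided p from the t-approximation on n−2 df.
* **Change-rate summaries** — mean with a Student-t 95% CI (a normal-based
  CI would differ slightly at n ≈ 26; t is the defensible default at this
  sample size).
* Missing data: listwise deletion per analysis with logged counts
  (mirroring patients who lack a follow-up scan).

## The phantom generator

A phantom is the union of two axis-aligned lobe ellipsoids (right
dominating left, as anatomically) plus spherical surface bumps standing
in for exophytic cysts, with mild anisotropic semi-axis jitter,
voxelized at 1×1 mm in plane and 3 mm axial slices. The defaults emulate
the advanced-PLD cohort the methods target: baseline volume lognormal
around a 6.8 L median (log-SD 0.30, so roughly 4–12 L across a cohort),
~29 cm transverse and ~28 cm cranio-caudal extent, 60% of the cyst burden
on the smaller left lobe (left-lobe deformation is what degrades LAP
reproducibility clinically). The 3 mm slice thickness sits inside the
3–5 mm acquisition band of the emulated protocol; 1 mm in-plane pixels
approximate clinical CT reconstruction (sub-millimetre in practice).

Longitudinal change is a *uniform* volume rescale: the same geometry
(same seed) re-voxelized with all linear dimensions scaled by the cube
root of the volume factor. Cohort defaults: 26 cases, three timepoints;
week-24 change rate drawn from N(−6.05, 8²)% and follow-up from
N(−3.35, 12²)% relative to baseline — the means are the published design
points of the emulated trial and the SDs are back-computed from its
reported 95% CIs. Assessors add per-diameter Gaussian noise (default
SD 0.3 cm), whole-slice jitter on the slice-count diameters (so the
CC-is-a-slice-multiple invariant survives), and optional bias. All
randomness flows from explicit seeds; identical spec + seed gives
voxel-identical masks.

What the phantoms do **not** emulate: CT intensities and segmentation
error (masks are inputs here), vasculature, non-uniform regional response
to treatment, breathing/positioning differences between scans, and the
spine (so the default AP falls back to the liver's dorsal surface).
Consequently the phantom family's index/reference ratio is ≈ 2.0 —
between the ellipsoid bound 1.91 and the clinical ≈ 3 — and divisor-mode
BASiM volumes *underestimate* phantom reference volumes even though
rank-based agreement (Spearman, inter-assessor ICC, change-rate ICC) is
high. Passing tests therefore demonstrate correctness of the measurement
rules, calibration algebra and statistics, not clinical accuracy of the
÷3 factor, which is owned by the clinical calibration data.

## Numerical and design choices

* Computation keeps full precision; only reporting rounds (one decimal in
  the worked examples, matching clinical reporting style).
* Exact-agreement matrices: the ANOVA residual sum of squares is computed
  by subtraction and is snapped to zero below 1e-12 of the total sum of
  squares, so identical rater columns yield ICC exactly 1.
* Degenerate inputs: empty masks, landmarks anterior to the liver,
  constant series for rank correlation, and single-assessor tables all
  raise or warn explicitly rather than returning silent numbers.
* The change-rate ICC against reference volumetry is only meaningful when
  change rates vary between cases (an ICC has no subject variance to work
  with if every case shrinks by the same amount); simulation checks of
  that statistic therefore use the cohort's natural between-case rate
  spread, while fixed-shrinkage cohorts are used to verify mean-rate
  recovery and perfect-agreement limits.
* Report assembly sorts all inputs deterministically, so shuffled input
  rows produce byte-identical reports; every report embeds the tool
  version, a config hash and the seed.

## Problem sizes used in the test suite

Simulation tests use a scaled-down phantom family (3×3×5 mm voxels,
~2.8 L livers) for speed; the full-resolution default family is exercised
by the end-to-end pipeline checks (26-case cohorts) and by the
acceptance script, which regenerates everything from scratch at run time.

## Known limitations

* The AP landmark from a spine mask uses the mask's anterior face per
  slice — a simplification of the lamina/spinous-process junction;
  supplying a per-slice coordinate directly is supported and preferred
  when exact landmark geometry matters.
* Orientation handling trusts the NIfTI affine; oblique acquisitions are
  reoriented to the nearest canonical axes, not resampled.
* ICC confidence intervals use the F-based approximation; exact intervals
  for unbalanced designs are out of scope (listwise deletion keeps the
  design balanced).
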