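# Methods

This note documents the models, parameters and design decisions behind
`adiposeg`, and what validation on the synthetic phantoms does and does
not demonstrate.

## Problem setting and assumptions

The pipeline quantifies SAT and VAT areas (cm²) from a single axial
abdominal slice. It assumes: one subject cross-section fully inside the
field of view; calibrated CT intensities (Hounsfield units, air ≈ −1000)
or non-negative fat-only Dixon MR intensities; known pixel spacing; and a
roughly convex body outline whose abdominal wall muscle layer separates a
subcutaneous fat ring from the visceral cavity. Orientation is assumed
axial with posterior toward larger row indices (only the advisory spine
auto-exclusion depends on this). Volumetric integration, fat-fraction
mapping and muscle/bone quantification are out of scope.

## Fat thresholds

* CT: fat window **−190 to −45 HU, inclusive on both ends**. The
  literature uses several nearby windows; the bounds are config-exposed
  (`PipelineConfig.ct_window`) and area is monotone non-increasing as the
  window narrows.
* MR: **0.5 × robust maximum** intensity within the body mask. "Maximum"
  is taken as the 99.5th percentile of body-pixel intensities rather than
  the literal maximum so that isolated hot pixels cannot inflate the
  threshold; the fraction and percentile are both parameters. This makes
  the threshold — and every downstream mask — exactly invariant under
  global intensity scaling, which is the property that lets one pipeline
  treat MR like CT.

## MR bias-field correction

Receive-coil (B1) inhomogeneity multiplies fat-only Dixon images by a
smooth field; without correction, shaded subcutaneous fat falls below the
fraction-of-max threshold. The correction is homomorphic: the field is
`exp(lowpass(log I))`, with the low-pass a normalised (mask-weighted)
Gaussian of scale **60 mm** (default; `bias_smoothing_mm`) computed over
**fat-dominant pixels** (> 30 % of the robust maximum). Restricting the
estimate to fat is essential: over fat, log intensity equals the log
field plus a constant, whereas including water-dominant tissue folds
anatomy (bright subcutaneous ring around a dim interior) into the field
and dims the very fat being corrected. Normalised convolution
extrapolates the field smoothly into fat-free regions; the output is
rescaled to preserve the mean body intensity, making the operation
idempotent to well under 1 %. This is a deliberate single-slice
substitute for iterative volumetric methods (e.g. N4-style B-spline
fitting), adequate because only the threshold decision — not the
intensity values themselves — feeds the downstream pipeline.

## Body mask

Foreground thresholding (CT > −190 HU; MR > 50 % of robust max) with
8-connected labelling. Components touching the inferior border with area
below 20 % of the largest component are discarded (scanner couch). Holes
are filled **before** selecting the component containing the image-centre
seed: on fat-only MR the raw foreground is just the fat, so the unfilled
component under the centre seed can be a single visceral blob rather than
the body; filling first merges the subcutaneous ring with everything
inside it. Largest-component selection is the fallback when the centre is
background. Images whose foreground covers < 1 % of the grid are
rejected as containing no body.

## Two-stage snake

The contour model is the classic energy-minimising closed spline:
internal tension `α|v′|²` and rigidity `β|v″|²`, an external attraction
to an edge map, and a balloon pressure along the inward normal that
carries the contour across featureless regions. The discretisation is
semi-implicit — the internal operator gives a cyclic pentadiagonal system
inverted once, external and balloon forces applied explicitly — with
uniform arc-length resampling each iteration and no randomness, so
results are bit-reproducible.

Defaults (all config-exposed, tuned on phantoms): α = 0.05, β = 0.5,
γ = 1.0 (step), 200 points, max 500 iterations, stop when mean
displacement < 0.05 px; balloon −0.3 and edge weight 4.0 for the outer
stage, −0.5 and 2.0 for the inner.

* **Outer stage**: initialised on the convex hull of the body mask
  dilated 2 px, attracted to the gradient magnitude of the
  Gaussian-smoothed (σ = 2 px) mask. Working on the mask rather than raw
  intensities unifies CT and MR.
* **Inner stage**: initialised at 0.98 × the outer contour (scaled about
  its centroid), attracted to the gradient of a **fat-likelihood image**
  equal to the modality's fat indicator inside the body and 1 outside.
  With a subcutaneous ring present, air→fat at the skin produces no edge,
  so the first transition met travelling inward is fat→muscle — the
  inner abdominal wall. With no subcutaneous fat the body boundary itself
  is the edge and the inner contour degenerates to the outer one rather
  than collapsing.
* **Ridge refinement**: pressure strong enough to cross flat tissue
  leaves the converged equilibrium slightly inside the edge ridge (the
  snake rests where attraction balances pressure, on the ridge flank), a
  radial offset of ~1–2 px that is worth a few percent of enclosed area.
  Each detection therefore ends with a short second pass at one fifth of
  the balloon pressure, letting the contour relax onto the ridge crest.
  A contour that shrinks below 25 px² raises a collapse error.

The snake stops where edge force meets balloon pressure, so weak spurious
edges (noise-scale gradients) are crossed while tissue-interface edges
hold; this tie-break is what makes the inner stage ignore visceral blob
boundaries after it has locked onto the wall.

## Partition and areas

Pixel membership against a contour uses pixel-centre point-in-polygon
with on-edge points counted inside (evaluated with both signs of the
boundary offset so the test is orientation-independent). SAT = fat ∧
inside-outer ∧ ¬inside-inner; VAT = fat ∧ inside-inner; fat outside the
outer contour (skin-surface partial volume) is discarded, keeping SAT
bounded by the annulus. Mask areas are pixel counts × pixel area; contour
areas use the shoelace formula scaled by mm² per pixel.

## Editing

Edits are expressed as data so any front end (or test) can drive them:
exclusion masks only ever remove fat pixels, and contour replacement
re-partitions the already-classified fat. `auto_exclude_spine` is
advisory and never applied automatically: it flags connected fat
components smaller than 0.3 cm² that are either enclosed by bone
(CT > 150 HU on the dilated border) or lie in the posterior midline box,
mirroring the spinal-canal / neural-foramina / paravertebral
false-positive classes a reading radiologist removes. The area guard
keeps genuine visceral depots unflagged.

## Agreement statistics

Bias is `mean(MR − CT)`; limits of agreement are `bias ± 1.96 × SD` of
the paired differences with the sample (n−1) SD; the LOA confidence
half-width uses the standard `SD·√(3/n)` standard error with a t
quantile. Pearson r and the paired two-tailed t-test come from scipy;
normality uses the Lilliefors-corrected one-sample Kolmogorov–Smirnov
test (parameters estimated from the data; for n < 4, where the
Lilliefors table is undefined, a plain KS test against the fitted normal
is substituted). Zero-variance differences yield t p-value 1 by
convention; zero-variance inputs make Pearson r undefined and raise.

## Phantom generator

Phantoms emulate a single axial abdominal slice: nested ellipses (body, SAT ring,
muscle wall, visceral cavity) plus elliptical visceral fat blobs, a
posterior vertebral bone ring with a 2.5 mm fat islet in the canal
(spine confounder, on by default), and optionally a bowel-gas pocket
whose rim renders in the CT fat window only. Default tissue intensities:
fat −100 HU / 1000 a.u., muscle +50 / 150, organ +40 / 120, air −1000 /
5, bone +700 / 80. Noise defaults to σ = 10 HU (CT) and 30 a.u. = 3 % of
fat signal (MR) — the scale of clinical abdominal protocols, small
enough that validation failures indicate pipeline defects rather than
noise. The MR bias field is a random second-order polynomial scaled to a
stated amplitude (cohort default drawn from 0.05–0.25). Cohort sampling
draws body semi-axes (132–205 × 96–150 mm), SAT thickness (10–34 mm),
muscle thickness (8–15 mm) and 3–8 blobs per phantom, spanning outer
areas of roughly 390–990 cm² — the spread reported for adult abdominal
cohorts — so agreement statistics are exercised over a realistic dynamic
range. Truth masks derive from the noiseless geometry; confounder fat is
excluded from SAT/VAT truth by definition.

What the phantoms do **not** model: anatomically realistic mesenteric
fat, organ texture, partial-volume mixing at tissue boundaries, motion,
arms in the field of view, or prone positioning. Two consequences matter
for interpreting results. First, with crisp single-tissue pixels the CT
and MR classifications of the same geometry are typically *identical*,
so cross-modality agreement on phantoms reaches r = 1 and bias = 0
exactly — clinical images, with partial volume and independent
modality-specific artefacts, would show the small residual biases that
motivate Bland–Altman analysis in the first place. Second, recovery
errors of ~1–2 % reflect contour discretisation and boundary
quantisation only; real-data accuracy is additionally limited by the
editing step and acquisition differences, which phantoms cannot measure.

## Problem sizes and runtime

Validation suites use 256 × 320 grids at 1.6 mm pixels, 20-phantom
recovery suites and 21-pair (42-image) agreement cohorts — the cohort
scale at which single-slice abdominal studies are typically reported.
One slice quantifies in ~0.1 s on one CPU; a full 42-image cohort plus
statistics takes a few seconds.

## Known limitations

* Single-slice 2-D only; no volumetric series handling or PACS transport.
* The inner contour tracks the *outer* border of the abdominal-wall
  muscle (the fat/muscle interface inside the subcutaneous ring);
  intramuscular fat therefore falls inside the inner region and relies on
  the editing step for removal, as in expert practice.
* The homomorphic bias correction assumes shading smoother than ~60 mm;
  sharper coil profiles would be under-corrected.
* `auto_exclude_spine`'s posterior-box fallback assumes supine axial
  orientation.
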