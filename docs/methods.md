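# Methods

## Diameter model

A segmented vessel cross-section is a set *D* of pixel coordinates (row,
col; 0-based; pixel centers at integers). Its diameter is defined as the
longest chord between two pixel centers of *D* whose direction is
perpendicular to the region's **long axis**, the principal PCA direction of
the pixel coordinates. "Perpendicular" on a discrete lattice is enforced as
a projection bound: a pair (a, b) is admissible when |(a − b)·**u**| ≤
`tol_px`, default 0.5 px — half the pixel-center spacing. The tolerance is
configurable; 0 keeps only exactly perpendicular lattice pairs and can make
small regions unmeasurable.

Two deliberate conventions:

* **Center-to-center length.** The chord length is the Euclidean distance
  between the extreme pixel *centers*, with no +1 pixel-extent correction.
  The alternative convention (each end contributes half a pixel) is exposed
  as `MeasureConfig(pixel_extent_correction=True)`, default off. The
  convention largely cancels in the PA/Ao ratio; the residual bias is
  discussed under *Phantom scale* below.
* **Chord ⊥ long axis.** The measured segment is perpendicular to the PCA
  long axis. The axis definition itself has a textual ambiguity in the
  field (a chord "perpendicular to a line that maximizes the perpendicular
  segment" is circular); we adopt the operational reading used when the
  measurement is drawn on images: green long axis, chord at right angles to
  it.

PCA is computed from the full pixel set (not boundary samples), so the axis
estimate is essentially noise-free for regions of realistic size; its only
error is rasterization. Near-circular regions (covariance eigenvalue ratio
< 1.05) have an unstable axis direction, which is harmless for the diameter
— chords through a near-disk are direction-insensitive — so measurement
proceeds and the result is flagged `near_circular`.

### Exactness of the sweep

`perpendicular_diameter` sorts pixels by their axis projection *t* and, for
each pixel, evaluates the full squared distance against every pixel in the
sliding window |Δt| ≤ tol. Because the window evaluation maximizes the
complete objective (not a perpendicular-offset surrogate), the sweep is
*exactly* the brute-force maximum — the same floating-point quantities as
the O(n²) oracle `diameter_oracle` — while touching only the thin strip of
admissible partners. The suite asserts bitwise equality on 200 random
connected blobs spanning 5–2000 px.

## Ratio, standard value, screening groups

PA/Ao = d(PA)/d(Ao). Ratios above 3.5 are outliers and are clipped to 3.5
*before* any statistic (band estimation, classification, scoring). A normal
cohort defines the standard value mean ± 2·SD with the sample SD (n − 1
denominator; the population variant differs by < 0.2% at cohort sizes of
interest). Boundary ratios exactly at mean ± 2SD classify as *normal*
("within" the band). The bundled default band, 1.237 ± 0.364 from 270
normal cases, is shipped as configuration data and is never recomputed;
any cohort CSV can replace it via `compute_standard_range`.

Screening uses the deviation score |ratio − mean|: one monotone scale on
which both low-ratio CHD (e.g. tetralogy of Fallot) and high-ratio CHD
(e.g. coarctation) are abnormal. ROC curves sweep the unique scores
descending with tied scores grouped at one threshold, so the trapezoidal
AUC equals the Mann–Whitney pair statistic with ties counted ½ (asserted to
1e-9 against an independent pair-counting oracle). Rater tables are
evaluated per rater, then skill groups take the arithmetic mean of their
raters' AUCs.

Dice is 2TP/(2TP+FP+FN) per class; mDice averages the classes evaluable in
a frame. A class absent from both masks is a 0/0 case and is excluded from
the mean by default (`absent_as_one=True` scores it 1 instead).

## Augmentation

Each variant draws angle ~ U(−15°, 15°), gain α ~ U(0.7, 1.3), offset β ~
U(−30, 30) from one seeded generator. `saturate_cast` rounds half away from
zero then clamps to [0, 255]; with (α, β, angle) = (1, 0, 0) the transform
is a bit-exact identity. Rotation is about the image center on a fixed
canvas, bilinear for images and nearest-neighbor for label masks (class
alphabet preserved), 0-filled outside. `augment_set` keeps the originals
and adds `n_variants` (default 20) variants per image — a 21-fold
expansion — applying the identical angle to a paired mask when given. The
rotate-and-rotate-back fidelity check uses a smoothed noise image: on white
noise, bilinear interpolation decorrelates neighboring pixels and no
interpolation scheme round-trips closely, so smooth imagery is the regime
the property describes.

## Phantom generator

Phantoms stand in for clinical masks: vessel cross-sections are rasterized
ellipses (pixel-center-inside, no anti-aliasing, so counts are exactly
reproducible) whose true perpendicular diameter is the full minor axis 2b.
Cohorts draw a true PA/Ao ratio per case — normal: N(1.237, 0.182), the σ
implied by the 2SD half-width 0.364; CHD: a three-component mixture over
the low/normal/high groups, default weights 0.3/0.4/0.3 with means
0.9/1.25/1.65 and σ 0.15, a fixture choice patterned loosely on published
group statistics, not a clinical estimate — and realize it geometrically:
Ao minor diameter fixed at `ao_px`, PA minor diameter = ratio × `ao_px`,
elongations U(1.05, 1.5), orientations U(0°, 180°), jittered sub-pixel
centers, on a 192 × 384 canvas.

Two generator choices matter for measurement fidelity:

* **Scale.** `ao_px` defaults to 30 px, the clinical-zoom regime (the chest
  filling half to two-thirds of the frame puts the great vessels at tens of
  pixels across). The center-to-center chord convention undershoots the
  continuous diameter by up to ~1.5 px per vessel; because the bias is
  roughly constant in pixels, it inflates the measured ratio by
  ≈ (r − 1)·δ/D_Ao, which at 30 px keeps end-to-end ratio error within
  ±0.075 across seeds. Substantially smaller vessels leave the regime where
  a pixel-based caliper is meaningful.
* **Sub-pixel centers.** Ellipses centered exactly on the lattice are a
  degenerate configuration: at orientations near 45° their point symmetry
  pairs the two extreme-chord pixels with axis projections differing by
  more than the 0.5 px tolerance, excluding the best chord and inflating
  the undershoot past 2 px. All generated centers therefore carry uniform
  sub-pixel offsets, the generic case, where recovery stays within 2 px of
  2b for minor semi-axes ≥ 5 px.

`CohortSpec.separable()` (weights 0.5/0/0.5, means 0.75/1.75, σ 0.08) is
the cohort with CHD group means well outside the normal band used for
screening-recovery checks; the *default* mixture intentionally places 40%
of CHD mass inside the normal band — mirroring the clinical reality that
many CHD cases have normal ratios — and therefore yields deviation-score
AUCs around 0.7, not > 0.9. `CohortSpec.null()` draws CHD from the normal
distribution (chance-level screening). `degrade_mask` perturbs masks per
class: erosion/dilation (8-connected structuring element, integer
iterations), random-direction shift (length in px), and dropout, whose
magnitude is a per-pixel drop probability in [0, 1] — a pixel length does
not parameterize dropout. Magnitude 0 is always the identity.

What the phantoms do *not* emulate: speckle and B-mode texture, acoustic
shadowing, blurred or open vessel boundaries, non-elliptical vessel shapes,
the 3VV/3VTV plane confusion, or segmentation-model error structure.
Passing the recovery checks shows the measurement chain is correct on known
geometry; it does not certify accuracy on clinical ultrasound.

## Frame selection

Detections arrive in the YOLO text dialect (`class cx cy w h conf`,
normalized; the 18-substructure class order puts PA, Ao, SVC at codes 8, 9,
10). A frame is a 3VV candidate iff *each* vessel has at least one box at
or above its class threshold — defaults PA 0.001, Ao 0.1, SVC 0.01; the PA
threshold is deliberately near zero because PA confidence is the limiting
detection — with any-box (not best-box) semantics. Up to
`max_frames_per_video` (default 2) candidates per video are drawn uniformly
without replacement from a seeded generator.

## Numerical and determinism choices

* All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed reproduces cohorts, selections and augmentations bit for bit.
* Pipeline CSV output uses fixed `%.6f` float formatting and JSON output is
  key-sorted, so reruns with identical config echo are byte-identical; the
  resolved configuration and seed are embedded in every summary.
* Component ties in region extraction break on the lexicographically
  smallest (row, col) pixel; eigenvector signs normalize the first nonzero
  component positive.
* Cohort ratio draws are truncated to [0.35, 3.4] so every PA ellipse fits
  the canvas and minor semi-axes stay ≥ 5 px; the bounds sit > 4σ from all
  default mixture components, so the truncation is statistically inert.
* Problem sizes in the test suite and acceptance script (200 blobs ≤ 2000
  px, 100 ellipses, 100 phantom frames, 10⁵ coverage draws, 1000-case
  cohorts) were chosen to make the statistical bounds sharp at
  single-core-friendly cost.

## Known limitations

* The diameter is a pixel-center chord; no sub-pixel contour fitting and no
  physical (mm) calibration — ratios are dimensionless by design.
* The low/normal/high bands ignore gestational age (the ratio varies little
  with it over the screening window, but extreme ages are untested).
* `rater_evaluation` assumes every rater rated the same case set; it does
  not handle missing ratings.
* The PCA long axis can differ from an anatomist's long axis for strongly
  non-elliptical regions (e.g. a PA continuing into the ductus); phantoms
  do not probe this.
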