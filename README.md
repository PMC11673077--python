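# caliper3vv

Automated vessel biometry for the fetal **three-vessel view (3VV)** — the
standardized transverse cardiac ultrasound plane showing the pulmonary artery
(PA), ascending aorta (Ao) and superior vena cava (SVC) in cross-section.
The PA/Ao diameter ratio is a screening biometric for congenital heart
disease (CHD): pulmonary stenosis (e.g. tetralogy of Fallot) depresses it,
aortic narrowing (coarctation) elevates it. Manual caliper placement is
examiner-dependent; this package measures it reproducibly from segmentation
masks.

It is aimed at researchers building or evaluating automated fetal-heart
screening pipelines: it consumes multi-class vessel label masks (from any
segmentation model, or from the bundled phantom generator) and produces
diameters, ratios, cohort statistics, screening groups and evaluation
metrics.

## Method

Given a label mask (0 background, 1 PA, 2 Ao, 3 SVC), for each vessel:

1. **Region extraction** — the largest 8-connected component *D* of the
   class.
2. **Long axis** — the principal PCA direction **u** of the pixel
   coordinates of *D* (eigenvector of the coordinate covariance with the
   larger eigenvalue).
3. **Diameter** — the maximal perpendicular chord

   d(D) = max { ‖a − b‖ : a, b ∈ D, a ≠ b, |(a − b)·**u**| ≤ τ },

   with projection tolerance τ = 0.5 px. A sorted-projection sweep computes
   this exactly; a literal O(n²) enumeration is kept as a reference oracle
   and the two are bitwise-identical by construction and by test.
4. **Ratio** — PA/Ao = d(D_PA) / d(D_Ao), with ratios above 3.5 treated as
   outliers and clipped to 3.5.

A normal cohort defines the **standard value** mean ± 2SD of the ratio (the
bundled default band is 1.237 ± 0.364); cases below / inside / above the band
form the *low* / *normal* / *high* screening groups. Screening performance
uses the deviation score |ratio − mean| (both tails score as abnormal) and
ROC analysis with CHD as the positive class. Segmentation quality is the
per-class Dice coefficient 2TP/(2TP+FP+FN) and its per-frame mean (mDice).
Training-set augmentation applies `dst = saturate_cast(src·α + β)` with
α ∈ [0.7, 1.3], β ∈ [−30, 30] plus rotation within ±15°, expanding a set
21-fold by default (originals + 20 variants each).

## Worked example

Generate a 9-case synthetic phantom cohort, measure it, and estimate the
cohort band:

```sh
caliper phantom --out-dir masks --n-normal 6 --n-chd 3 --seed 42
caliper measure masks --out-dir measured
caliper cohort-stats measured/records.csv --out range.json
```

which prints `measured 9 case(s), 0 failure(s)` and
`standard value: 1.199 +/- 0.658 (n=9)`, and writes `measured/records.csv`:

```
 case_id frame_id cohort_label     pa_px     ao_px    ratio  clipped  group
case0000       f0       normal 38.600518 29.068884 1.327898    False normal
case0003       f0       normal 30.083218 29.206164 1.030030    False normal
case0006       f0       normal 24.000000 29.068884 0.825625    False    low
case0007       f0       normal 51.088159 28.425341 1.797275    False   high
...
```

`pa_px`/`ao_px` are the measured perpendicular-chord diameters in pixels
(true phantom diameters: PA varies, Ao = 30 px), `ratio` their quotient, and
`group` the classification against the bundled 1.237 ± 0.364 band — e.g.
case0007's ratio 1.797 exceeds the upper bound 1.601, so it lands in the
*high* group. The same library surface is available in Python
(`caliper3vv.measure_frame`, `compute_standard_range`, `roc_auc`, …), and
further subcommands cover Dice evaluation (`caliper dice`), augmentation
(`caliper augment`), detection-based 3VV frame selection
(`caliper select-frames`) and rater screening comparison (`caliper screen`).

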