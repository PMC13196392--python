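# Methods

## The screening problem

Osteoporotic fragility is under-diagnosed: most people at elevated fracture
risk never receive a DXA scan, while large numbers of abdominal, spine,
chest and pelvic radiographs that visualise the lumbar spine are acquired
every day for unrelated indications. `osteoscreen` implements an
*opportunistic* screening pipeline over such radiographs: it segments the
lumbar vertebrae (L1–L4) and surgical implants, computes engineered
trabecular-texture features, and classifies whether the patient falls into
the *very high bone fragility* category — osteoporosis (lumbar BMD T-score
≤ −2.5) together with degraded trabecular bone score (TBS < 1.23), both
referenced against paired DXA. The decision rule deliberately prioritises
specificity: the intended use is pre-DXA triage, where false positives
carry the cost of unnecessary confirmatory scans.

## Reference standard

The composite Bone Fragility Index combines bone quantity and quality:

* BMD category (WHO): osteoporosis at t ≤ −2.5 (inclusive), osteopenia for
  −2.5 < t < −1.0, normal at t ≥ −1.0. Whether t exactly −1.0 belongs to
  osteopenia or normal is a genuine boundary convention; this package places
  it in `normal`.
* TBS degradation: strictly below 1.23.
* Zones: `very_high` = osteoporosis ∧ degraded; `high` = osteoporosis ∨
  (osteopenia ∧ degraded); `none` otherwise. The `high ∪ very_high` zone is
  the reference set for *near-miss precision* — the fraction of predicted
  very-high cases whose DXA reference is at least in the high zone.

T-scores and TBS values are consumed as given; vendor normative-curve
computation is out of scope.

## Eligibility

A radiograph enters the pipeline when its in-plane resolution is ≤ 0.2
mm/px, a DXA record exists within 6 months (operationalised as ≤ 183 days
absolute gap — calendar-month arithmetic is locale-dependent), and at least
two of L1–L4 are assessable. Vertebrae whose masks are overlapped by an
implant instance beyond 10% of their area count as non-assessable.

## Experimental variogram and raw TBS

For a grey image I on a pixel grid, the experimental variogram at integer
lag d is

    γ(d) = Σ (I(x_i) − I(x_i + d))² / (2 N(d)),

pooling axis-aligned offsets (0, d) and (d, 0) whose endpoints both lie in
the vertebra mask; N(d) is the pair count. Pooling the two axes (rather
than radial annuli) keeps the estimator exactly equal to brute-force pair
enumeration, which the tests exploit. Images are first histogram-equalised
and resampled to 0.45 mm/px; with the maximum lag of 15 px the profile
spans 6.75 mm, the scale of trabecular structure. The *raw TBS* score is
the ordinary-least-squares slope of log γ(d) against log d over the
available lags, averaged (unweighted) across assessable vertebrae. An OLS
fit was chosen over a point derivative at d = 15 because a point slope on a
noisy empirical variogram is unstable; a two-point `endpoint` estimator
remains available behind a switch. Lags with γ = 0 are excluded from the
fit; an all-zero profile yields NaN with a warning rather than a fabricated
value.

For an isotropic fractional Brownian surface with Hurst exponent H the
variogram scales as d^{2H}, so the log–log slope estimates 2H — smoother
texture (higher H, healthier trabecular architecture) gives a steeper
slope. This is the analytic ground truth the synthetic phantoms provide.

## GLCM descriptors

Grey-level co-occurrence matrices are computed on a 32-level quantisation
of the in-mask intensities (in-mask min–max, hence invariant to affine
intensity shifts), at distances {1, 2, 4} px, accumulated over the four
principal angles, symmetrised and normalised. Four standard descriptors per
distance — contrast, correlation, energy, homogeneity — give a 12-vector,
averaged across vertebrae. Distances for which the mask admits no pair are
reported as missing, not zero. The descriptor set and quantisation are
package choices, kept small and configurable.

## Synthetic phantoms

The phantom generator defines the study conditions for every test:

* Geometry: 768×320 px at 0.143 mm/px; 2–4 (default 4) vertically stacked
  superellipse ("rounded rectangle") vertebrae, widths 25–35% of the image,
  10% inter-vertebral gaps; a vertical soft-tissue background ramp
  (0.25→0.35 in normalised grey); optional bright implant bar
  (p = 0.08) and burned-in text block (p = 0.10); additive Gaussian noise
  sd 0.005.
* Texture: each vertebra is filled with an fBm field of the subject's Hurst
  exponent, amplitude 0.08 — large against the noise floor so the texture,
  not the noise nugget, dominates small-lag variogram behaviour, as it does
  for real trabecular structure at these scales.
* fBm synthesis is spectral (power spectral density ∝ f^−(2H+2)) on a
  4× oversampled grid that is then decimated: without oversampling the
  spectral cutoff at the Nyquist frequency suppresses lag-1 increments and
  biases the measured slope upward for rough fields. With decimation the
  measured slope tracks 2H within ±0.12 across H ∈ [0.2, 0.8].
* Calibration: affine monotone maps take the subject's density offset
  (range 0.10–0.40) to a T-score (midpoint ↦ −1.75, half-range span 2.25
  SD) and the Hurst exponent (range 0.2–0.8) to a TBS (midpoint ↦ 1.23,
  half-range span 0.20). Both anchors sit exactly at the clinical
  thresholds' operating region, making boundary behaviour testable and the
  class mix controllable. A small margin (0.01 grey / 0.02 H) around the
  very-high class boundary is excluded when sampling subjects, so labels
  are separable by construction; the generator is the ground truth, not a
  difficulty dial.
* Demographics: age ~ U(50, 85), sex female with probability 0.85 —
  the typical densitometry-referral population.

What the phantoms do *not* emulate: anatomy (pedicles, endplates, spinous
processes), scatter and beam hardening, vendor post-processing, degenerative
changes, vertebral fractures. Passing tests therefore demonstrate that the
pipeline's machinery recovers known texture/density signal under controlled
conditions — not clinical performance on real radiographs.

## Segmentation stage

The production-scale stage contract is instance segmentation over a
1024×1024 8-bit input (0.5/99.5-percentile windowing, aspect-preserving
resize, zero padding, with an invertible scale record). The desk-scale
default segmenter behind that contract is a pixel-wise shallow MLP over
multi-scale Gaussian, gradient, local-contrast (difference-of-Gaussian) and
local-standard-deviation features computed at half resolution — the
texture-energy channels separate trabecular bone from smooth soft tissue
regardless of the density offset, and two horizontally elongated channels
resolve the narrow dark inter-vertebral gaps. Connected components become
instances; when misclassified gap pixels bridge adjacent bodies, a
watershed on the negated class probability, seeded from high-confidence
cores, restores one instance per body. Training uses the stated
augmentations (horizontal flips, brightness/contrast jitter, ±5°
rotations). The interface is pluggable so heavier architectures can be
swapped in without touching the stage contract.

Levels are assigned purely by mask-centroid row, superior first (L1..L4);
duplicate detections (IoU > 0.5) keep the higher score; extras beyond four
drop lowest-score first; fewer than four sets a `level_uncertain` flag,
since absolute levels cannot be anchored without T12/L5 context.

Metrics: per-level and region Dice/IoU (with the identity
Dice = 2·IoU/(1+IoU) checked numerically) and COCO-style mAP at a single
IoU threshold of 0.75 with greedy score-ordered matching.

## Classifier

The classifier is a pooling-token-mixer (MetaFormer-family) backbone: patch
embedding, then blocks of 3×3 mean-pool-minus-identity token mixing and a
GELU channel MLP, each behind layer norm and a residual connection — no
attention. Global average pooling feeds two parallel fully connected heads
of exactly 16 units, supervised for osteoporosis and for degraded TBS; the
fusion layer concatenates the two 16-unit ReLU activation vectors (the
activations, not the head logits) with the standardised engineered scalars
— age, sex (0 = male, 1 = female), raw TBS, the 12 GLCM descriptors, and
two missingness flags — and a final linear map with softmax yields the
2-way very-high-fragility output.

The network, its backward pass and the optimiser are implemented in numpy
(`osteoscreen.nn`); gradients are verified against finite differences in
the test suite.

Desk-scale input: the classification ROI (union bounding box of assessable
vertebrae + 10% margin, resampled to 0.2 mm/px, globally
histogram-equalised) enters as two 64×64 planes — the whole ROI downscaled
(global bone/soft-tissue contrast) and a 2×2 mosaic of native-resolution
crops centred on the assessable vertebrae. The mosaic exists because
downscaling a ~550-px ROI to 64 px low-passes away exactly the trabecular
texture the degraded-TBS head must see; sampling at native resolution
inside the vertebrae preserves it.

Training: SGD with momentum 0.9 and weight decay 1e-4; total loss is the
softmax cross-entropy plus 0.5-weighted binary cross-entropies on the two
heads. The full-scale defaults are learning rate 1e-4 and batch 128; the
desk profile uses 0.01 (from the standard search grid) with batch 32 and a
cosine learning-rate decay, appropriate for a small from-scratch network on
a few hundred samples. Early stopping monitors validation accuracy: stop
when 40 consecutive epochs fail to beat the best value by 0.005, restoring
the best-epoch weights; the rule is a pure function
(`early_stop_epoch`) unit-tested on synthetic sequences. Splits are 80/10/10,
stratified on the very-high class, one subject per sample.

Decision rule: by default argmax; when a minimum specificity is configured
(default 0.90), the smallest validation threshold on p(very_high) reaching
that specificity is persisted with the model and applied at prediction.
Classifier training and its held-out evaluation use the reference
(annotation-equivalent) masks; the automatic segmenter path is evaluated
separately and used by the CLI's end-to-end run for the test split.

## Evaluation

Accuracy, sensitivity, specificity, precision, balanced accuracy, F1 and
MCC come from the confusion matrix with zero-denominator metrics flagged
`None`, never coerced; AUC is the rank-based (Mann–Whitney) estimator with
ties at 0.5. 95% confidence intervals use the binomial normal approximation
p ± 1.96·√(p(1−p)/n) clipped to [0, 1], with n equal to each metric's own
denominator — a documented convention (printed clinical CIs are generally
not reconstructible from published counts). Prevalences are formatted with
half-up rounding to one decimal. Flow accounting enforces
stage_in − excluded = stage_out at every attrition stage, counting
multi-reason records once.

## Explainability

Attention maps use the gradient-weighted class-activation family on the
final token-mixing stage (the last spatial features before pooling). The
spatially weighted formulation — positive gradients weight activations
element-wise before the channel sum (LayerCAM-style) — is used instead of
channel-averaged weights, which cannot localise at the coarse 8×8 token
grid of the desk backbone. Maps are upsampled to ROI size, min–max
normalised and zeroed outside the vertebra masks. Post-hoc feature
importance fits an XGBoost classifier (fixed seed, 5-fold CV) on the fusion
activations, engineered features and demographics, reporting gain-based
importances normalised to sum 1 with group totals.

## Problem sizes and numerical choices

The reference desk study uses 800 phantoms (very-high fraction 0.2), a
40-phantom segmenter training set, 20 held-out phantoms for segmentation
scoring and the 10% test split (~80 cases) for classification metrics —
sizes chosen so the whole study runs comfortably on a single CPU while
leaving clear margins on the recovery checks. Variogram/GLCM oracles run on
16×16 ROIs where O(n²) enumeration is exact and fast. Ties in threshold
selection resolve to the smallest adequate threshold; degenerate
(constant-intensity) images map to mid-grey and propagate as constants
through equalisation rather than erroring.

## Known limitations

* The phantoms are geometric, not anatomic; clinical performance claims
  cannot be derived from them.
* The desk segmenter's implant handling is intensity-driven; dark or
  composite implants would require the pluggable heavier architectures.
* Level assignment assumes a cranio-caudal image orientation and exactly
  the L1–L4 field of view.
* The numpy training loop is single-threaded and desk-sized by design;
  the full-size backbone profile exists in configuration but is not the
  tested path.
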