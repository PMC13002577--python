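# Methods

This note documents the models, conventions and numerical choices behind
`buscad`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the desk-scale results do and do not show.

## Pipeline overview

An input grayscale image is resized to the network geometry and segmented;
an entirely empty predicted mask issues the verdict *normal* and ends the
analysis (the empty-mask gate, `gate_normal`, strict by default with a
configurable `min_area` tolerance for speckle-induced single-pixel
foreground).  Non-empty masks proceed to morphometry and a linear SVM
verdict of *benign* or *malignant*.  Every sample therefore exits through
exactly one of the three verdicts, and the evaluation report audits that
routing explicitly.

## Segmentation network

A standard U-Net: `depth` resolution levels, each encoder level two 3×3
same-padded convolutions with ReLU followed by 2×2 max-pooling; a two-conv
bottleneck; decoder levels that upsample (nearest-neighbour ×2 + 3×3
convolution), concatenate the matching encoder features, and apply two more
convolutions; a 1×1 convolution produces two per-pixel class scores
normalized by softmax.  Channel widths double per level from `base_filters`.
Weights are He-initialized from a seeded generator, so architecture + seed
fully determine the initial model.

Training minimizes pixel-wise categorical cross-entropy
L = −Σᵢ Σ_c y_ic log ŷ_ic (the summed form is the tested contract; the
optimizer uses the per-pixel mean, which only rescales gradients) with Adam.
Probabilities are floored at 1e-12 inside the log.  Grayscale images are
replicated to three identical channels at the network boundary only —
storage and I/O stay single-channel.  Each epoch runs
`floor(n_train / batch_size)` iterations on a seeded shuffle; the incomplete
trailing batch is dropped (with 624 training images at batch 8 this is
exactly 78 iterations/epoch, 780 over 10 epochs).  Mask prediction is the
per-pixel argmax with ties resolved to background.

The engine is written directly in numpy: im2col patch extraction feeding
BLAS matrix products, explicit backward passes for every layer, float32
parameters.  Analytic gradients are verified against central finite
differences in the test suite.

**Configurations.**  The clinical-scale protocol (the `TrainConfig`
defaults) is Adam at learning rate 1e-4, batch 8, 10 epochs, 256×256×3
inputs, depth 4, base 32 filters.  The *desk benchmark* used throughout the
tests and the acceptance script is 60 training / 20 held-out phantoms at
64×64, depth 3, base 16, batch 8, 10 epochs — about 5×10⁵ parameters and 70
optimizer steps, training in roughly a minute on one CPU core.  At that
step count the desk benchmark uses Adam's conventional default learning
rate 1e-3; the 1e-4 rate belongs to the long 780-iteration schedule.  The
benchmark gate is held-out mean Mask IoU ≥ 80%; typical seeds land at
90–96%.

## Mask morphometry

All measures operate on the largest 8-connected component of the mask (a
multi-region prediction is treated as one lesion plus clutter; a `union`
mode is available).  Conventions, chosen once and used consistently:

* **Area, bounding box** — pixel counts; the box is the tight axis-aligned
  rectangle of foreground pixels.
* **Convex hull area** — the number of pixel *centers* lying in the convex
  hull of the foreground pixel centers (Qhull facets, tolerance 1e-9).
  Numerator and denominator of solidity are thus in the same pixel-count
  currency.  Degenerate (collinear) regions fall back to their own count.
* **Perimeter** — Moore-neighbour boundary trace of the outer contour
  (clockwise, Jacob's stopping criterion) with step weights 1 (orthogonal)
  and √2 (diagonal), scaled by Kulpa's correction π(1+√2)/8 ≈ 0.948.  The
  raw chain length systematically overestimates smooth contours (+5.2% on a
  digital disk of radius 32); the corrected estimator is nearly unbiased
  (−0.3% at r = 32), which keeps the circularity of large rasterized disks
  inside [0.95, 1].  The uncorrected backend remains selectable
  (`perimeter_backend="chain"`), and both the trace and the hull are
  cross-checked in the tests against independently written oracles
  (a from-scratch opposite-orientation walk; gift-wrapping plus
  point-in-polygon) on a thousand random small masks.
* **Axis lengths** — from the normalized second central moments of pixel
  centers with a +1/12 per-pixel variance term (a pixel is the unit square
  around its center): a = 4√λ₁, b = 4√λ₂.  The 1/12 term keeps b > 0 for
  one-pixel-wide regions, so eccentricity is always defined.  A solid n×m
  rectangle gets variances exactly n²/12 and m²/12, hence a 2:1 rectangle
  has eccentricity exactly √3/2.
* **Circularity clamp** — discretization can push 4πA/P² slightly above 1
  for small disks; values are clamped to 1 with a recorded flag.

Expected raster behaviour, used as test tolerances: circularity of a digital
disk converges to 1 (within 0.05 at r = 40, 0.01 at r = 64); extent of a
digital disk converges to π/4 like O(1/r) because the pixel bounding box is
(2r+1) wide; eccentricity of a digitized 2:1 ellipse is within 0.01 of √3/2
at an 80-pixel major axis.

## Classification stage

Labels are fixed as benign = −1, malignant = +1.  Features are standardized
(mean/variance learned on training rows only — the leakage audit asserts
test rows cannot influence them; standardization is toggleable).  The
soft-margin primal min ½‖w‖² + C·Σξᵢ with yᵢ(wᵀxᵢ+b) ≥ 1−ξᵢ is solved by an
SMO backend (`sklearn.svm.SVC`, linear kernel) that optimizes exactly this
objective; the fitted objective value is verified against a brute-force
lattice minimization on small instances in the tests.  Slack diagnostics
ξᵢ = max(0, 1 − yᵢ f(xᵢ)) are stored on the model.  A decision value of
exactly zero resolves to benign.

C is tuned by stratified k-fold (default 5) cross-validated grid search over
{0.1, 1, 10, 100}; ties break toward the smallest C (strongest
regularization), independent of grid order.

**Splits.**  Stratified holdout fixes the overall training size to
round(n·(1−test_fraction)) and apportions it across classes by largest
remainder (floor of each ideal share, leftovers by descending fractional
remainder); class membership is then drawn from a seeded generator.  This
rounding rule reproduces the standard cohort bookkeeping exactly: an 80/20
split of (133, 437, 210) trains on 106/350/168 = 624 images, and a 70/30
split of the 647 tumor-bearing cases trains on 306/147.  k-fold assignment
apportions each class across folds the same way, so class-wise fold sizes
differ by at most one.

**Deployment protocol.**  In the end-to-end pipeline the classifier is
trained on features extracted from the *predicted* masks of tumor-bearing
training images, not the ground-truth masks.  The segmenter smooths fine
boundary detail (spicules a few pixels wide at 64×64), so a classifier
trained on ground-truth morphology faces a shifted feature distribution at
deployment; training on predicted-mask features removes that mismatch (in
the 81-image demo it is the difference between ~56% and ~93% stage-2
accuracy).  `buscad features` supports both sources.  `run-all` falls back
to ground-truth features, with a logged warning, only when the segmenter
yields too few usable masks to fit a classifier (tiny smoke runs).

## Evaluation

Mask IoU = 100·|P∩G|/|P∪G|.  The empty/empty case (a correctly gated normal
image) is undefined by the formula; it is scored 100 with a flag, and mean
IoU is reported both including and excluding flagged cases.  Dice relates to
IoU per image by DSC = 2·IoU/(1+IoU), an exact identity since both derive
from the same intersection and union; the report computes Dice directly and
the tests assert the identity on every evaluated pair.  Accuracy is printed
to 2 decimals, IoU/Dice to 1, matching conventional reporting precision.

The 95% CI on accuracy is the Wald (normal-approximation) interval
p̂ ± z·√(p̂(1−p̂)/n) with z = 1.959964 internally, clipped to [0, 100].
Note the Wald formula on 189 correct of 194 gives 95.19%–99.65%; narrower
intervals sometimes quoted for those counts (94.4%–99.4%) are not
reproducible by this formula, nor by Wilson or Clopper–Pearson — the
implementation exposes exactly the stated formula.

Stratified cross-validation of the classifier re-tunes C inside each
training portion by default (`C_protocol="tune"`); a fixed-C protocol is
available.

## Phantom generator

The generator's job is controllable class-dependent *morphology*, not
acoustic realism.  Lesion boundaries are truncated Fourier perturbations of
an area-preserving ellipse,

r(θ) = r₀·s(θ)·(1 + Σₖ aₖ cos(kθ + φₖ)) [+ spicule bumps],

with s(θ) the polar radius of an ellipse of sampled axis ratio.  Benign
lesions use 3 low-order harmonics with a total amplitude budget of 0.055 and
axis ratios 1.05–1.5; malignant lesions use 8 harmonics with budget 0.20,
axis ratios 1.5–2.2, plus 8 narrow additive Gaussian bumps in angle (height
up to 0.32·r₀, width ≈ 0.07 rad) — the spicules.  Base radii are 10–16% of
the frame; centers are placed so the maximal outline radius stays in frame
(rasterization flags clipping otherwise).  Radii are floored at 1 px,
keeping r(θ) > 0.  These defaults were set once, to realize the standard
radiological contrast — benign: smooth/round/convex; malignant:
spiculated/elongated/concave — with clear margins; with them, median
circularity and solidity of benign masks exceed malignant and median
malignant eccentricity exceeds benign at n = 50/class, and a tuned linear
SVM separates ground-truth-mask features at ≥95% held-out accuracy
(typically 100%) at n = 200/class.

Images are rendered as background_mean·(1 − contrast·support) with the mask
support Gaussian-blurred (σ = 2 px by default), multiplied by unit-mean
gamma speckle (std 0.30, lightly smoothed for grain) and clipped to [0, 1];
defaults: background 0.55, lesion contrast 0.55.  The *easy* preset used by
the segmentation benchmark raises contrast to 0.8 and lowers noise to 0.15
at 64×64.  Datasets are written as 8-bit PNGs ({0, 255} masks) in the public
dataset's dialect, with a CSV manifest; with probability `p_multimask`
(default 0.15) a lesion's mask is split into two overlapping files whose
logical OR restores the full mask, exercising the loader's OR-merge.  The
whole dataset is a pure function of the spec (which includes the seed).

**What passing phantoms does not show.**  No point-spread function,
attenuation, posterior shadowing, operator variability, or intra-tumoral
texture is modeled, and real lesion-shape distributions overlap far more
than the phantom classes do.  Desk-scale results demonstrate correctness of
the machinery (geometry, optimization, routing, bookkeeping), not clinical
performance; headline clinical metrics require the clinical dataset, which
the loader reads but the package does not ship.

## Degenerate inputs and tie-breaks

Empty masks: rejected by morphometry (they belong to the gate), scored
100-with-flag by IoU against an empty ground truth.  Component ties in
`largest_component` go to the earliest first pixel in scan order.  Argmax
ties in mask prediction go to background.  Decision-value 0 goes to benign.
C-grid ties go to the smallest C.  Constant features standardize to scale 1.
Single-pixel regions have perimeter 0 and raise on circularity.  A mask
resize never invents foreground (nearest-neighbour + re-binarize by > 0);
an identity resize is bit-exact.

## Known limitations

The numpy engine is CPU-bound and practical up to roughly 10⁶ parameters at
256×256 inputs; the clinical-scale configuration trains, but slowly.  The
perimeter correction is calibrated for smooth contours and slightly
underestimates polygonal ones.  Phantom class separation is intentionally
generous; reported phantom accuracies should be read as machinery checks,
and the benign/malignant eccentricity ordering observed in real cohorts
varies with lesion orientation and measurement convention — the generator
follows the convention that malignancy raises eccentricity.
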