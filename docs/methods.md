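# Methods

This note records the models, conventions and design choices behind
`mritex`, in the order data flows through the toolkit.

## Synthetic phantoms

Each phantom is a 64×64 (configurable) image in [0, 1]: a fixed
axis-aligned ellipse at 80% of the frame ("brain" support, uniform
background level 0.35) containing one or more disc lesions whose
interiors carry a stationary textured field.  The texture process is
smoothed white noise: a unit-variance Gaussian field convolved with an
isotropic Gaussian kernel of standard deviation `correlation_length`
pixels, renormalised to unit variance, scaled by `contrast_scale` and
shifted by `mean_shift` relative to the background.  This is the
simplest random field whose GLCM correlation is tunable through a
single parameter, which is exactly what the tests need.  Global pixel
noise (σ = 0.02) is added last and intensities are clipped to [0, 1].

Two lesion classes are defined by their texture parameters
(A: correlation length 1 px, contrast 0.08, shift +0.18;
B: 3 px, 0.12, +0.26), so class signal reaches first-order statistics,
co-occurrence structure and zone/run statistics simultaneously.
`default_spec(class_gap=g)` scales the parameter differences about
their midpoint, giving a monotone difficulty dial with `g = 0` meaning
identical classes.  Lesion centres are drawn uniformly among positions
where the disc fits inside the ellipse; discs may overlap.

Determinism: a cohort is a pure function of (spec, master seed).
Per-sample seeds are `SeedSequence((master_seed, index))`, so any
sample can be regenerated in isolation.

What the phantoms do *not* emulate: MR physics (relaxation contrasts,
bias fields, partial volume), anatomy (gyri, ventricles), or
acquisition noise correlations.  Tests passing on phantoms therefore
validate the *computational* pipeline — matrix identities, formula
correctness, protocol calibration, the ability of the network to learn
— not clinical performance on real MRI.

## Quantization

Texture matrices need a discrete alphabet.  In-mask intensities are
binned uniformly between their min and max into L levels (default 16),
bins half-open with the top bin closed, indexed 1..L to match the
matrix summation conventions.  A constant region maps to bin 1.  The
radiomics-standard min–max rule makes every downstream texture feature
invariant to affine intensity rescaling; it also means bins at 2L are
an exact refinement of bins at L (tested as a property).

## Texture matrices

* GLCM: pair counts over offsets {(0,1), (−1,1), (−1,0), (−1,−1)}
  (distance 1, four directions), both pixels in-mask, symmetrised by
  adding the transpose, pooled across offsets into one matrix and
  normalised.  Pooling the four symmetric directions makes the
  features invariant to 90° rotation (tested).  Marginal means and
  standard deviations (φ_y, φ_z, λ_y, λ_z) come from the normalized
  table.
* GLRLM: maximal same-level runs along the same four direction
  families, broken at the mask boundary; each in-mask pixel belongs to
  exactly one run per direction, giving the conservation identity
  ΣΣ r·R(j,r) = m · n_directions.
* GLSZM: connected-component zones per level (8-connectivity by
  default, 4 available); ΣΣ s·Z(j,s) = m.
* MGLSZM: the GLSZM computed at quantization depths {4, 8, 16, 32};
  scalar features are averaged across depths.  This multi-depth
  construction is a documented choice, isolated behind one function so
  it can be swapped.

All three constructions are verified exactly against independent
brute-force oracles (pair enumeration, run scanning, BFS flood fill)
on 200 random images up to 16×16.

## Features

The twelve named operators are listed in the README.  Conventions that
needed a decision:

* `j_std` is the square root of the population variance; the variance
  itself is exposed as `j_variance`.  Kurtosis uses the excess ("−3")
  convention.  A variance below the roundoff floor
  (10⁻¹² · max(1, |mean|))² is treated as zero so numerically constant
  regions reliably hit the NaN sentinels.
* Area is the in-mask pixel count and perimeter the standard digital
  boundary-length estimate (skimage's weighted contour estimator) —
  the only readings that make the circularity 4πA/L² land near 1 for a
  disc.  Digital boundaries slightly exceed smooth ones, so disc
  circularity sits just below 1 (accepted band 0.9–1.05).  Elongation
  uses the second-moment best-fit ellipse axes.  Multi-component masks
  are reduced to their largest component with a warning.
* Entropy uses log base 2 (bits) by default, configurable.
* GLRLM/GLSZM scalar summaries are the five classical ones per matrix;
  run percentage is normalised by m · n_directions so it stays ≤ 1 for
  the pooled matrix.
* `ALL` is the concatenation of every enabled family; a switch
  restricts it to the texture families only.
* Undefined features propagate as NaN and the evaluation module drops
  affected rows (logged), never silently imputing.

## Segmentation

The model is an encoder–decoder with 3×3 stride-1 convolutions, 2×2
max pooling, nearest-neighbour upsampling and ReLU, built on a small
reverse-mode autodiff engine over numpy (`mritex.nn`; its gradients
are finite-difference checked in the test suite).  Config switches:

* **Attention gates** on skips: additive gate (1×1 projections of skip
  and coarser decoder feature, ReLU, 1×1, sigmoid).  The gate bias is
  initialised to +2 so gates start open (α ≈ 0.88) and do not starve
  the skips early in short trainings.
* **Dense dilated center**: 3×3 convolutions at increasing dilation
  rates, each consuming the concatenation of all previous center
  outputs, fused by a 1×1 convolution.
* **Spatial pyramid pooling**: grid average pooling at sizes
  {1, 2, 4}, 1×1 projection, upsampling, concatenation, 1×1 fusion.
* **Deep supervision**: every decoder level except the full-resolution
  one emits a 1×1-conv prediction upsampled to full resolution; the
  total loss is the main loss plus Σ wᵢ · auxᵢ.

With all switches off the model is a plain U-Net, used as the ablation
baseline.

Loss and optimisation: combined soft-Dice (+1 smoothing) plus binary
cross-entropy, minimised with Adam.  Cross-entropy is evaluated on the
logits through a stable log-sigmoid, whose gradient (p − t) does not
vanish when outputs saturate — with the naive ε-clamped log(p) form,
runs that drifted to confident all-background predictions could never
recover.  Heads expose probabilities (`forward`); the logits path
(`forward_logits`) exists only for the loss.

Desk-scale recipe (used by the test suite, the acceptance script and
the CLI): depth 4, 8 base channels, 64×64 inputs, batch 4, learning
rate 3·10⁻³, 10 epochs, auxiliary weights 0.2/0.1/0.05 shallowest to
deepest.  The global `ModelConfig` default keeps the heavier
conventional weights (0.4/0.3/0.2), but at this scale they measurably
cost boundary accuracy: the auxiliary targets are blocky
nearest-upsampled maps, and on 5–12 px lesions over-weighting them
drags held-out Dice by several points.  A 10-seed study at this depth
showed the role deep supervision actually plays here: every variant
segments well when training goes well, but without deep supervision
roughly one run in ten collapses (held-out Dice minima 0.37–0.74
across the ablations vs 0.86 for the deep-supervised model), which is
precisely the shallow-gradient failure deep supervision exists to
prevent.

Cascade: stage k > 1 is a fresh model with a second input channel
carrying the previous stage's probability map; per-stage held-out Dice
is reported (a quarter of the cohort is held out when the caller does
not provide a validation set).  Dice of two empty masks is defined as
1. Everything is deterministic given the config seeds; runs are
single-threaded apart from BLAS matrix products.

## Evaluation protocol

Repeated random subsampling: 100 stratified 70/30 splits (both
defaults configurable), standardisation fitted on the train part only,
a deterministic regularized logistic classifier (linear SVM and LDA
are available), test accuracy and Mann–Whitney AUC per repeat
(ties = ½, computed from average ranks; verified exactly against
all-pairs counting up to n = 200).  Per-repeat seeds are derived from
the master seed and stored in the report, and the summary means/stds
are recomputed from the stored raw scores, so every number is
auditable.  No multiple-testing correction is applied across families
— the report is descriptive, and the raw scores are exposed for users
who want to test.

Two calibration properties anchor the protocol: permuted labels score
0.5 within the binomial sampling band, and a perfectly separated
feature scores exactly 1.0.  Note that with resampled splits on a
finite cohort, a "noise" feature that is spuriously correlated with
labels *in the sample* can score above 0.5 on average; this is a
property of repeated subsampling itself, not leakage (standardisation
and fitting see the train part only).

## Problem sizes

The shipped tests and the acceptance script use: 200 random ≤16×16
images for matrix-oracle equivalence, 100 random ROIs for formula
equivalence, a 100-phantom cohort (50 per class) with 100 repeats for
classification, and 50 phantoms (40 train / 10 held out), 5 seeds, for
the segmentation comparisons — sizes at which the full pipeline runs
in minutes on a single CPU while leaving the sampling bands quoted
above comfortably resolvable.

## Known limitations

* 2-D only; no volumetric (26-neighbourhood) texture matrices.
* Binary segmentation (lesion vs background) only.
* The autodiff engine implements exactly the ops this network needs;
  it is not a general deep-learning framework (no GPU, no stride-2
  convolutions, float64 only).
* Phantom realism is deliberately minimal (see above); reported
  accuracies and Dice values characterise the pipeline on phantoms,
  not any clinical dataset.
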