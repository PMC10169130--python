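# Methods

## Model

The classifier is an attention branch network: a convolutional feature
extractor, an attention branch that produces class-activation maps (CAM)
and a single-channel attention map `M`, and a perception branch whose
logits are the model's final prediction.  The attention map reweights the
extractor features channelwise, `g'_c = (1 + M) ⊙ g_c`, so attention both
explains the model and shapes what the perception branch sees.

The operation branch adds the penalty `L_ope = λ‖M ⊙ W‖²_Fro`, where `W`
is a binary weight map at input resolution (0 over anatomy, 1 outside) and
`M` is bilinearly resized up to `W` before the Hadamard product.  The
training loss is `L = L_att + L_per + L_ope`; both classification losses
are class-weighted cross-entropies (weights ∝ inverse class counts,
normalised to mean 1) in single-label mode and mean per-label binary
cross-entropy, unweighted, in multi-label mode.  The penalty is averaged
over the batch so λ keeps the same meaning at any batch size; within one
image it is the plain sum of squares (the squared Frobenius norm).

### Attention head

The head follows the ABN reference design: a 3×3 convolution on the
extractor output, a 1×1 convolution to K class-score maps (their spatial
means are the attention-branch logits), and a 1×1 convolution collapsing
the class maps to one channel.  Two details matter in practice:

* **Normalization before the sigmoid.**  The collapsed map passes through
  an affine-free batch normalization before the sigmoid.  Without it, the
  penalty is minimised by pushing the whole pre-sigmoid map to −∞ — the
  attention collapses to `M ≡ 0` everywhere, `(1 + M)` degenerates to the
  identity, and no guidance happens.  Pinning the map to zero mean and
  unit variance makes a uniform shift inexpressible, so the only way to
  reduce the penalty is to *relocate* attention into the anatomy.
* **Gain.**  A learnable scalar gain, initialised at 2, multiplies the
  normalized map before the sigmoid.  `sigmoid(±2σ)` spans roughly
  0.12–0.88, so the head can express near-binary masks from the start and
  the amplification contrast between anatomy and background approaches its
  2:1 ceiling; the penalty itself then drives the gain further up, since a
  sharper map has less mass outside the anatomy.

### Resolution

The extractor halves the resolution only while the map side exceeds 14:
224-px inputs give the canonical 14×14 attention map, 64-px inputs give
8×8.  A coarser map (e.g. 4×4 at 64 px) is useless for this penalty: after
bilinear upsampling every cell's support overlaps the outside of the
anatomy, so the penalty hits the whole map indiscriminately and flattens
it instead of steering it.

Backbones: `tiny` (four 3×3 conv blocks, 8–32 channels) and `deep` (double
convs, 16–64 channels).  The perception branch is a two-convolution stack
mirroring the extractor's upper layers, followed by global average pooling
and a linear classifier.  All models are float32 NumPy networks on the
package's reverse-mode autodiff engine (`obnet.nn`); gradient checks
against central finite differences run in float64.

## Weight maps

Three modes: the filled convex hull of the lung mask (which implicitly
covers the mediastinum and heart), the pixelwise lung∪heart union, and
manual maps loaded from PNG.  Hull membership is decided at pixel centres
(a pixel is foreground iff its centre lies in the convex hull of the
foreground pixel centres), which makes the operation exactly idempotent;
the hull is taken jointly over both lungs, producing a single convex
region.  Masks are resized nearest-neighbour so they stay binary, and the
weight map is the inverted anatomy mask.  An empty anatomy mask is
accepted with a warning (the penalty would cover the whole image).

## Segmentation

A small U-Net (single 3×3 conv per level, nearest-upsample + skip-concat
decoder, sigmoid output) is trained with the Combo loss — mean binary
cross-entropy on clipped probabilities plus a soft Dice loss smoothed by 1
in numerator and denominator, equally weighted by default — using Adam
(lr 1e-3, β 0.9/0.999) with batch size 16.  Evaluation uses hard-mask Dice
`2|X∩Y|/(|X|+|Y|)` and IoU `|X∩Y|/|X∪Y|` (both defined as 1 when both
masks are empty, so the metrics are total) plus pixel accuracy; soft Dice
appears only inside the training loss, hard Dice only in evaluation.
k-fold training returns one model per fold; the deployment mask binarizes
each model's probabilities at 0.5, averages the binary maps, and
thresholds the average at 0.5 (a majority vote).  Both binarization
thresholds are exposed; higher ensemble thresholds give subset masks.
A heart model can be warm-started from a lung model's state.

## Attention Index and improvement ratio

`I_A = Σ_A p / Σ_Ω p` uses the raw (continuous, non-negative) Grad-CAM
values; the ratio is invariant to positive rescaling, so no normalization
is applied.  The ROI `A` is the zero set of the weight map.  An all-zero
saliency map has no defined index and raises an error rather than
returning 0.  Grad-CAM weights each channel of a convolutional activation
by the spatial mean of the target-class score gradient and applies a ReLU;
the default layer is the last perception-branch convolution.  The
improvement ratio counts *strict* index increases; ties count as not
improved.

## Synthetic data

`generate_classification_set` emulates the structure the method assumes:
Gaussian background noise (σ 0.05 over a 0.1 base), a brighter (+0.25)
elliptical anatomy with jittered centre and axes (0.26–0.38 of the image
side), a Gaussian signal blob of contrast 0.4 placed strictly inside the
anatomy of positive images, and a square corner marker of contrast 0.8
added with probability 0.9 to positives and 0.1 to negatives — a
label-correlated shortcut outside the anatomy, stronger than the true
signal.  Labels are balanced to within one sample and generation is
bit-identical under a fixed seed.  Every sample carries its anatomy mask
and the paired weight map `W = 1 − anatomy`.

What this does *not* emulate: anatomical texture, projection physics,
inter-patient correlation, multiple disease classes, and realistic
confounder variety.  Passing the guidance experiment shows the penalty
redirects attention under a planted shortcut; it does not certify
behaviour on real radiographs.

## Training protocol

Adam on the three-part loss; a group-disjoint 10% validation split inside
the training data; the checkpoint of the epoch with the highest validation
accuracy is kept (early-stopping model selection over a fixed budget).
Grid search covers λ ∈ {0.1, 0.01, 1e-3} and lr ∈ {1e-5, 1e-4, 1e-3} by
default, selects on validation accuracy, and breaks ties toward the
smaller λ, then the smaller lr.  Cross-validation folds are group-disjoint
(no patient straddles folds), assigned greedily largest-group-first to the
smallest fold.  Classification metrics (accuracy, sensitivity,
specificity at threshold 0.5, ranking AUC) are computed from the
perception-branch probabilities; multi-label mode reports per-label AUCs
and their mean.

## Problem sizes

The guidance experiment runs five seeds of n = 400 64-px images
(320 fit / 80 test), ABN vs OBN (λ = 0.1), 20 epochs, batch 32, lr 1e-3,
tiny backbone, Attention Index over positive test images — about six
minutes on one CPU.  The segmentation benchmark is 40 ellipse pairs,
2 folds, 30 epochs (~35 s).  Formula checks compare against brute-force
loop oracles on 100 random instances up to 16×16.

## Numerical conventions

* Bilinear resampling uses half-pixel sample centres with edge clipping,
  as an explicit linear map whose adjoint is its transpose; at an exact 2×
  downsample it averages 2×2 blocks.  Nearest-neighbour resampling for
  anything binary.
* Padding centres the content with exact-zero bands; rotation and shift
  fill with 0, matching the padding convention.  Augmentation defaults:
  γ ∈ [0.8, 1.25], horizontal flip probability 0.5, rotation ±10°, shift
  ±10 px; gamma applies to the image only, geometric transforms apply
  identically to the paired map (nearest-neighbour).
* Probabilities are clipped to [1e-7, 1 − 1e-7] inside BCE; gradients pass
  through the clip only strictly inside the range.
* With λ = 0 the operation term is skipped entirely, so an OBN run is
  bit-for-bit an ABN run under the same seed.
* All randomness flows through explicit NumPy generators seeded from the
  configuration; two runs with the same seeds are bitwise identical.

## Limitations

The engine is intentionally small: stride-1 convolutions, power-of-two
pooling, no GPU, no ImageNet-pretrained backbones — models are desk-scale
by design.  The guidance effect's size depends on the relative
learnability of signal and confounder; with a much stronger or more
diffuse shortcut the 2:1 amplification ceiling of `(1 + M)` bounds how
hard the penalty can steer the perception branch.  Segmentation-derived
weight maps inherit any segmenter domain shift; manual maps avoid this at
labelling cost.
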