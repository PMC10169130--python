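# obnet

Attention-guided CNN classification with anatomical priors, for
radiograph-like images.

A convolutional classifier can reach high accuracy while looking at the
wrong thing — a ruler next to a skin lesion, a metal marker in a corner of
a chest film.  `obnet` implements the **operation branch network (OBN)**:
an attention branch network (ABN) — feature extractor, attention branch
with a class-activation-mapping (CAM) head, perception branch — augmented
with a regularization term that forces the attention map into an
anatomically plausible region supplied as a binary **weight map**, plus the
**Attention Index**, a scale-free measure of how much of a Grad-CAM
saliency map falls inside a region of interest.

## Model

The attention branch emits a low-resolution attention map
`M(X) ∈ [0, 1]` (14×14 for 224-px inputs) that reweights the extractor's
feature maps channelwise before the perception branch classifies them:

    g'_c(X) = (1 + M(X)) ⊙ g_c(X),        c = 1, …, C

With a binary weight map `W` (0 over anatomy, 1 outside), the operation
branch penalises attention falling outside the anatomy:

    L_ope(X, W) = λ ‖M(X) ⊙ W‖²_Fro

where `M` is bilinearly resized to `W`'s resolution before the Hadamard
product, and the full training loss is

    L = L_att + L_per + L_ope

with `L_att`, `L_per` the (class-weighted) cross-entropy losses of the two
branches.  `λ = 0` recovers the plain ABN exactly.  Weight maps come from
U-Net lung/heart segmentation (convex hull of the lung field, lung∪heart
union) or are loaded from hand-drawn PNGs.

For a saliency map `p` and an ROI pixel set `A ⊆ Ω`, the Attention Index is

    I_A = Σ_{(i,j)∈A} p_ij / Σ_{(i,j)∈Ω} p_ij ∈ [0, 1].

The models run on a small NumPy reverse-mode autodiff engine (`obnet.nn`),
so everything trains on a single CPU at the package's desk scale.

## Worked example

Train an ABN (λ = 0) and an OBN (λ = 0.1) on a synthetic confounded
dataset — 64-px images with an elliptical "anatomy", a class signal of
contrast 0.4 inside it, and a stronger (0.8) label-correlated corner
marker outside it — then compare Grad-CAM Attention Indices on held-out
positives:

```python
import numpy as np
from obnet.synthetic import SynthSpec, generate_classification_set
from obnet.workflow import dataset_from_samples, train, evaluate
from obnet.obn_core import ObnConfig, ObnModel
from obnet.explain import (grad_cam, RoiSet, attention_index,
                           improvement_ratio, IndexPair)

spec = SynthSpec(n=200, seed=0)
data = dataset_from_samples(generate_classification_set(spec))
test, fit = data.subset(np.arange(160, 200)), data.subset(np.arange(160))

pairs = []
for name, lam in (("ABN", 0.0), ("OBN", 0.1)):
    cfg = ObnConfig(input_size=64, lambda_=lam, seed=0)
    run = train(ObnModel(cfg), fit, cfg, lr=1e-3, epochs=15, batch_size=32)
    rep = evaluate(run.model, test)
    ais = []
    for i in np.flatnonzero(test.labels == 1):
        s = grad_cam(run.model, test.images[i], target_class=1)
        ais.append(attention_index(s, RoiSet.from_weight_map(test.weight_maps[i])))
    print(f"{name}: val acc {run.best_val_accuracy:.3f}  test AUC {rep.auc:.3f}  "
          f"mean attention index {np.mean(ais):.3f}")
    pairs.append(ais)
ratio = improvement_ratio([IndexPair(str(i), b, p)
                           for i, (b, p) in enumerate(zip(*pairs))])
print(f"improvement ratio (OBN vs ABN): {ratio:.2f}")
```

Output (a few minutes on one CPU):

```
ABN: val acc 1.000  test AUC 0.987  mean attention index 0.269
OBN: val acc 0.938  test AUC 1.000  mean attention index 0.371
improvement ratio (OBN vs ABN): 1.00
```

The penalty moved the saliency mass into the anatomy for every held-out
positive (improvement ratio 1.00) while the test AUC did not degrade.

A command-line interface wraps the same functionality: `obnet synth`,
`obnet make-weightmaps`, `obnet segment-train`, `obnet train`,
`obnet explain` (see `obnet --help`).

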