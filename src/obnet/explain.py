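"""Grad-CAM saliency, the Attention Index, and paired improvement analysis.

The Attention Index of a saliency map p with respect to a region of
interest A (index set of pixels, A ⊆ Ω) is

    I_A = I(A) / I(Ω),   I(A) = Σ_{(i,j)∈A} p_ij,   I(Ω) = Σ_{(i,j)∈Ω} p_ij,

the fraction of total saliency mass falling inside the ROI.  It is
scale-free (invariant to p → c·p, c > 0), lies in [0, 1], and is undefined
for an all-zero map.  The ROI here is the anatomical region, i.e. the
pixels where the weight map is 0.

For paired model comparison the improvement ratio is the fraction of
images whose index is *strictly* higher under the proposed model; ties
count as not improved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Tensor
from .nn.engine import _interp_matrix

__all__ = [
    "SaliencyMap", "RoiSet", "IndexPair",
    "grad_cam", "attention_index", "improvement_ratio", "export_scatter",
    "save_overlay",
]


@dataclass
class SaliencyMap:
    """Non-negative per-pixel attention degrees at input resolution."""

    p: np.ndarray
    target_class: int = 0
    model_id: str = ""

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.float64)
        if (self.p < 0).any() or not np.all(np.isfinite(self.p)):
            raise ValueError("saliency values must be finite and non-negative")


@dataclass
class RoiSet:
    """Boolean membership mask of the ROI pixel set A within Ω (all pixels)."""

    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=bool)

    @classmethod
    def from_weight_map(cls, W) -> "RoiSet":
        """ROI = anatomy = the pixels where the weight map is zero."""
        vals = np.asarray(W.values if hasattr(W, "values") and not isinstance(W, np.ndarray) else W)
        return cls(vals == 0)


@dataclass
class IndexPair:
    sample_id: str
    baseline_index: float
    proposed_index: float


def grad_cam(model, img, target_class: int, layer: str = "per_conv") -> SaliencyMap:
    """Grad-CAM saliency of one image for a target class.

    Channel weights are the spatial means of ∂score/∂activation at the
    named convolutional stage; the map is ReLU(Σ_c w_c · A_c), bilinearly
    upsampled to input resolution.  ``layer`` names an entry of
    ``model.activations`` (default: the perception-branch convolution,
    whose logits are the final prediction).
    """
    x = np.asarray(img.pixels if hasattr(img, "pixels") else img, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("grad_cam expects a single 2-D image")
    was_training = model.training
    model.eval()
    model.zero_grad()
    # a grad-requiring input guarantees every activation on the path
    # retains its gradient, whatever the model's parameters do
    outs = model.forward(Tensor(x[None], requires_grad=True))
    k = outs.per_logits.shape[1]
    if not 0 <= target_class < k:
        raise ValueError(f"target_class {target_class} out of range for {k} classes")
    if layer not in model.activations:
        raise KeyError(f"unknown layer {layer!r}; available: {sorted(model.activations)}")
    act = model.activations[layer]
    seed = np.zeros_like(outs.per_logits.data)
    seed[0, target_class] = 1.0
    outs.per_logits.backward(seed)
    if was_training:
        model.train()
    grads = act.grad[0]                      # (C, h, w)
    weights = grads.mean(axis=(1, 2))        # spatial mean per channel
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    size = x.shape[0]
    A = _interp_matrix(cam.shape[0], size, np.float64)
    B = _interp_matrix(cam.shape[1], size, np.float64)
    up = A @ cam @ B.T
    return SaliencyMap(np.maximum(up, 0.0), target_class=target_class)


def attention_index(s: SaliencyMap | np.ndarray, roi: RoiSet | np.ndarray) -> float:
    """Fraction of saliency mass inside the ROI: I_A = I(A) / I(Ω)."""
    p = np.asarray(s.p if isinstance(s, SaliencyMap) else s, dtype=np.float64)
    a = np.asarray(roi.A if isinstance(roi, RoiSet) else roi, dtype=bool)
    if a.shape != p.shape:
        raise ValueError("ROI and saliency shapes differ")
    total = p.sum()
    if total <= 0:
        raise ValueError("attention index undefined for an all-zero saliency map")
    return float(p[a].sum() / total)


def improvement_ratio(pairs: list[IndexPair]) -> float:
    """Fraction of pairs with proposed_index strictly above baseline_index."""
    if not pairs:
        raise ValueError("improvement_ratio needs at least one pair")
    improved = sum(1 for p in pairs if p.proposed_index > p.baseline_index)
    return improved / len(pairs)


def export_scatter(pairs: list[IndexPair], path: str | Path) -> pd.DataFrame:
    """Write paired indices as CSV (sample_id, baseline_index, proposed_index)."""
    df = pd.DataFrame(
        [(p.sample_id, p.baseline_index, p.proposed_index) for p in pairs],
        columns=["sample_id", "baseline_index", "proposed_index"],
    )
    df.to_csv(path, index=False)
    return df


def save_overlay(image: np.ndarray, s: SaliencyMap, path: str | Path,
                 alpha: float = 0.4) -> None:
    """Write a jet-colormap saliency overlay on a grayscale image as PNG."""
    import matplotlib
    from PIL import Image

    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    p = s.p
    p = p / p.max() if p.max() > 0 else p
    heat = matplotlib.colormaps["jet"](p)[..., :3]
    base = np.repeat(img[..., None], 3, axis=-1)
    blend = (1 - alpha) * base + alpha * heat
    Image.fromarray((np.clip(blend, 0, 1) * 255 + 0.5).astype(np.uint8)).save(path)
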