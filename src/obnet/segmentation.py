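"""U-Net organ segmentation: Combo loss, Dice/IoU metrics, k-fold training,
and ensemble averaging of binarized predictions.

Training minimises the Combo loss (binary cross-entropy + soft Dice loss)
with Adam (lr 1e-3, betas 0.9/0.999, batch size 16).  Evaluation uses the
hard-mask Dice coefficient 2|X∩Y|/(|X|+|Y|) and IoU |X∩Y|/|X∪Y|, which are
linked by dice = 2·iou/(1 + iou).  For deployment, the k fold models are
combined by binarizing each model's probability map at 0.5, averaging the
binary maps, and thresholding the average (majority vote at the default
threshold 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .nn import Adam, Conv2d, Module, Tensor, concat, functional as F
from .weightmaps import _check_binary

__all__ = [
    "SegPair", "SegModelConfig", "SegMetrics", "UNet",
    "combo_loss", "soft_dice_loss", "dice_coefficient", "iou",
    "seg_metrics", "train_unet", "predict_prob", "ensemble_mask",
]


@dataclass
class SegPair:
    """An image and its ground-truth binary organ mask."""

    image: np.ndarray
    truth_mask: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.truth_mask = _check_binary(self.truth_mask)
        if self.image.shape != self.truth_mask.shape:
            raise ValueError("image and mask shapes differ")


@dataclass
class SegModelConfig:
    depth: int = 2
    base_channels: int = 8
    input_size: int = 64
    seed: int = 0
    epochs: int = 30
    batch_size: int = 16
    lr: float = 1e-3

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")


@dataclass
class SegMetrics:
    accuracy: float
    iou: float
    dice: float


class UNet(Module):
    """A small U-Net: per-level single 3x3 conv encoder, nearest-upsample +
    skip-concat decoder, sigmoid output probability map."""

    def __init__(self, cfg: SegModelConfig, init_state=None):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.base_channels
        self.enc = []
        ch_in = 1
        chans = []
        for d in range(cfg.depth):
            ch_out = c * 2**d
            self.enc.append(Conv2d(ch_in, ch_out, 3, padding=1, rng=rng))
            chans.append(ch_out)
            ch_in = ch_out
        self.bottleneck = Conv2d(ch_in, ch_in * 2, 3, padding=1, rng=rng)
        ch_in = ch_in * 2
        self.dec = []
        for d in reversed(range(cfg.depth)):
            ch_out = chans[d]
            self.dec.append(Conv2d(ch_in + ch_out, ch_out, 3, padding=1, rng=rng))
            ch_in = ch_out
        self.out_conv = Conv2d(ch_in, 1, 1, rng=rng)
        if init_state is not None:
            self.load_state_dict(init_state)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        skips = []
        h = x
        for conv in self.enc:
            h = conv(h).relu()
            skips.append(h)
            h = h.maxpool2d(2)
        h = self.bottleneck(h).relu()
        for conv, skip in zip(self.dec, reversed(skips)):
            h = concat([h.upsample_nearest(2), skip], axis=1)
            h = conv(h).relu()
        return self.out_conv(h).sigmoid()  # (N, 1, H, W) probabilities


def soft_dice_loss(pred, truth, smooth: float = 1.0):
    """1 − soft Dice on probabilities, smoothed by ``smooth`` in both
    numerator and denominator (differentiable surrogate of the hard Dice)."""
    tensor_path = isinstance(pred, Tensor)
    p = pred if tensor_path else Tensor(np.asarray(pred, dtype=np.float64))
    t = np.asarray(truth, dtype=np.float64)
    inter = (p * t).sum()
    dice = (inter * 2.0 + smooth) / (p.sum() + float(t.sum()) + smooth)
    loss = 1.0 - dice
    return loss if tensor_path else loss.item()


def combo_loss(pred, truth, bce_weight: float = 1.0, dice_weight: float = 1.0,
               eps: float = 1e-7):
    """Combo loss: mean BCE (probabilities clipped to [eps, 1−eps]) plus the
    soft Dice loss, equally weighted by default."""
    p_data = pred.data if isinstance(pred, Tensor) else np.asarray(pred)
    t = np.asarray(truth)
    if p_data.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    tensor_path = isinstance(pred, Tensor)
    p = pred if tensor_path else Tensor(p_data.astype(np.float64))
    loss = bce_weight * F.binary_cross_entropy(p, t, eps=eps) \
        + dice_weight * soft_dice_loss(p, t)
    return loss if tensor_path else loss.item()


def dice_coefficient(X, Y) -> float:
    """Hard-mask Dice 2|X∩Y|/(|X|+|Y|); 1 when both masks are empty."""
    x, y = _check_binary(X).astype(bool), _check_binary(Y).astype(bool)
    if x.shape != y.shape:
        raise ValueError("mask shapes differ")
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(x, y).sum() / denom)


def iou(X, Y) -> float:
    """Intersection over union |X∩Y|/|X∪Y|; 1 when both masks are empty."""
    x, y = _check_binary(X).astype(bool), _check_binary(Y).astype(bool)
    if x.shape != y.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(x, y).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(x, y).sum() / union)


def seg_metrics(pred_mask, truth_mask) -> SegMetrics:
    """Pixel accuracy, IoU, and Dice of a binarized prediction."""
    p, t = _check_binary(pred_mask), _check_binary(truth_mask)
    return SegMetrics(
        accuracy=float((p == t).mean()),
        iou=iou(p, t),
        dice=dice_coefficient(p, t),
    )


def predict_prob(model: UNet, images: np.ndarray) -> np.ndarray:
    """Probability maps (N, H, W) for a batch of images, no gradients kept."""
    model.eval()
    out = model.forward(np.asarray(images, dtype=np.float32)).data[:, 0]
    model.train()
    return out


def _fit(model: UNet, images: np.ndarray, masks: np.ndarray,
         cfg: SegModelConfig, rng: np.random.Generator) -> None:
    opt = Adam(model.parameters(), lr=cfg.lr, betas=(0.9, 0.999))
    n = len(images)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = model.forward(images[idx])
            pred = pred.reshape(pred.shape[0], pred.shape[2], pred.shape[3])
            loss = combo_loss(pred, masks[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()


def train_unet(pairs: list[SegPair], cfg: SegModelConfig, folds: int,
               init_state=None) -> tuple[list[UNet], pd.DataFrame]:
    """k-fold cross-validated U-Net training.

    Returns the k trained fold models (usable as an ensemble) and a
    per-fold metrics table (fold, accuracy, iou, dice) computed on each
    held-out fold from predictions binarized at 0.5.  ``init_state`` warm
    starts every fold from an existing model state (e.g. fine-tuning a
    heart segmenter from a lung one).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(pairs) < folds:
        raise ValueError("need at least as many pairs as folds")
    images = np.stack([p.image for p in pairs]).astype(np.float32)
    masks = np.stack([p.truth_mask for p in pairs]).astype(np.float32)
    kf = KFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    models: list[UNet] = []
    rows = []
    for fold, (tr, te) in enumerate(kf.split(images)):
        model = UNet(SegModelConfig(**{**vars(cfg), "seed": cfg.seed + fold}),
                     init_state=init_state)
        rng = np.random.default_rng(cfg.seed + 1000 + fold)
        _fit(model, images[tr], masks[tr], cfg, rng)
        prob = predict_prob(model, images[te])
        ms = [seg_metrics((pr >= 0.5).astype(np.uint8), masks[i].astype(np.uint8))
              for pr, i in zip(prob, te)]
        rows.append({
            "fold": fold,
            "accuracy": float(np.mean([m.accuracy for m in ms])),
            "iou": float(np.mean([m.iou for m in ms])),
            "dice": float(np.mean([m.dice for m in ms])),
        })
        models.append(model)
    return models, pd.DataFrame(rows)


def ensemble_mask(images: np.ndarray, segmenters: list[UNet],
                  threshold: float = 0.5) -> np.ndarray:
    """Average of the models' binarized outputs, thresholded to a mask.

    Each segmenter's probability map is binarized at 0.5, the binary maps
    are averaged across models, and the average is binarized at
    ``threshold`` (majority vote at the 0.5 default).  Output is (N, H, W)
    in {0, 1}; higher thresholds give subset masks.
    """
    if not segmenters:
        raise ValueError("need at least one segmenter")
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    votes = np.zeros(images.shape, dtype=np.float64)
    for m in segmenters:
        votes += predict_prob(m, images) >= 0.5
    votes /= len(segmenters)
    return (votes >= threshold).astype(np.uint8)
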