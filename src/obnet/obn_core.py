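"""The operation branch network (OBN).

An OBN is an attention branch network — feature extractor, attention
branch, perception branch — plus a regularization term ("operation
branch") that penalises attention mass falling outside a supplied
anatomical weight map.

The three pieces:

* attention weighting: the feature map ``g_c`` is reweighted channelwise
  by the attention map ``M`` as ``g'_c = (1 + M) ⊙ g_c``;
* operation loss: ``L_ope = λ ‖M ⊙ W‖²_F``, with the low-resolution
  attention map bilinearly resized to the weight map's (input) resolution
  before the Hadamard product;
* total loss: ``L = L_att + L_per + L_ope``, where ``L_att`` and ``L_per``
  are the classification losses of the attention and perception branches
  (class-weighted cross-entropy, or per-label BCE in multi-label mode).

With ``λ = 0`` the model and its training dynamics are exactly the plain
attention branch network (ABN) baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, Linear, Module, Parameter, Tensor,
                 bilinear_resize, functional as F)

BACKBONES = ("tiny", "deep")

__all__ = [
    "BACKBONES", "ObnConfig", "BranchOutputs", "LossBreakdown", "ObnModel",
    "attend", "operation_loss", "branch_loss", "total_loss",
    "inverse_frequency_weights",
]


@dataclass
class ObnConfig:
    """Configuration of an operation branch network.

    lambda_ is the weight of the operation loss; 0 disables it (ABN
    baseline).  The extractor halves the resolution until the map side is
    at most 14, so the attention map is 14x14 at the 224 default input and
    8x8 at 64.
    """

    backbone: str = "tiny"
    lambda_: float = 0.1
    num_classes: int = 2
    multilabel: bool = False
    input_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be non-negative")
        if self.input_size % 16:
            raise ValueError("input_size must be divisible by 16")


@dataclass
class BranchOutputs:
    """Per-batch outputs of the three structural parts of the network."""

    att_logits: Tensor   # (N, K) attention-branch class scores
    per_logits: Tensor   # (N, K) perception-branch scores: the final prediction
    attention: Tensor    # (N, 1, h, w) attention map in [0, 1]
    features: Tensor     # (N, C, h, w) extractor feature map


@dataclass
class LossBreakdown:
    """The three loss terms and their sum, kept on the autodiff graph."""

    l_att: Tensor
    l_per: Tensor
    l_ope: Tensor
    total: Tensor

    def as_floats(self) -> dict[str, float]:
        return {"l_att": self.l_att.item(), "l_per": self.l_per.item(),
                "l_ope": self.l_ope.item(), "total": self.total.item()}


class _ConvBlock(Module):
    def __init__(self, in_ch, out_ch, rng, extra=False, pool=True):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, rng=rng) if extra else None
        self.pool = pool

    def forward(self, x):
        x = self.conv(x).relu()
        if self.conv2 is not None:
            x = self.conv2(x).relu()
        return x.maxpool2d(2) if self.pool else x


class ObnModel(Module):
    """Attention branch classifier with CAM head and perception branch.

    The feature extractor halves the resolution while the map side exceeds
    14, so the attention map is 14×14 at the 224 default (8×8 at 64).  A
    map much coarser than that cannot separate inside from outside the
    anatomy once bilinearly resized, and the penalty would flatten the
    whole map instead of relocating it.  The attention branch
    produces K class-score maps by 1×1 convolution (class activation
    mapping); their spatial means are the attention-branch logits, and a
    further 1×1 convolution + sigmoid collapses them into the single
    attention map M in [0, 1].  The perception branch classifies
    ``(1 + M) ⊙ g`` and its logits are the model's final prediction.
    """

    def __init__(self, cfg: ObnConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        chans = {"tiny": (8, 16, 32, 32), "deep": (16, 32, 64, 64)}[cfg.backbone]
        extra = cfg.backbone == "deep"
        self.blocks = []
        c_in = 1
        side = cfg.input_size
        # pool only while the map is coarser than the 14-px attention head,
        # so 224 -> 14x14 and 64 -> 8x8
        for c_out in chans:
            pool = side > 14
            self.blocks.append(_ConvBlock(c_in, c_out, rng, extra=extra, pool=pool))
            if pool:
                side //= 2
            c_in = c_out
        self.attention_side = side
        self.n_features = c_in
        k = cfg.num_classes
        # attention branch (CAM head)
        self.att_conv = Conv2d(c_in, c_in, 3, padding=1, rng=rng)
        self.att_cam = Conv2d(c_in, k, 1, rng=rng)
        self.att_collapse = Conv2d(k, 1, 1, rng=rng)
        # normalizing the pre-sigmoid map fixes its overall level, so the
        # operation penalty relocates attention instead of erasing it; the
        # learnable gain lets the penalty sharpen the map toward {0, 1}
        self.att_bn = BatchNorm2d(1, affine=False)
        # gain 2 on the standardized map lets sigmoid express near-binary
        # attention from the start (sigmoid(+-2 sd) ~ 0.12 / 0.88)
        self.att_gain = Parameter(np.full(1, 2.0))
        # perception branch: a small conv stack mirroring the extractor's
        # upper layers, so reliance on attended features can develop
        self.per_conv = Conv2d(c_in, c_in, 3, padding=1, rng=rng)
        self.per_conv2 = Conv2d(c_in, c_in, 3, padding=1, rng=rng)
        self.per_fc = Linear(c_in, k, rng=rng)
        self.activations: dict[str, Tensor] = {}

    def forward(self, x) -> BranchOutputs:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        n, c, h, w = x.shape
        if c != 1 or h != self.cfg.input_size or w != self.cfg.input_size:
            raise ValueError(
                f"expected (N, 1, {self.cfg.input_size}, {self.cfg.input_size}) input, got {x.shape}"
            )
        g = x
        for blk in self.blocks:
            g = blk(g)
        att_h = self.att_conv(g).relu()
        cam = self.att_cam(att_h)                       # (N, K, h, w)
        att_logits = cam.mean(axis=(2, 3))              # spatial average -> (N, K)
        attention = (self.att_bn(self.att_collapse(cam)) * self.att_gain).sigmoid()
        attended = attend(g, attention)                 # (1 + M) ⊙ g
        per_h1 = self.per_conv(attended).relu()
        per_h = self.per_conv2(per_h1).relu()
        per_logits = self.per_fc(per_h.mean(axis=(2, 3)))
        self.activations = {
            "features": g, "att_conv": att_h, "cam": cam,
            "attended": attended, "per_conv1": per_h1, "per_conv": per_h,
        }
        return BranchOutputs(att_logits=att_logits, per_logits=per_logits,
                             attention=attention, features=g)


def save_checkpoint(model: ObnModel, path) -> None:
    """Write model weights with the config embedded alongside."""
    import json

    state = model.state_dict()
    np.savez(path, config=json.dumps(vars(model.cfg)),
             **{f"arr_{i}": a for i, a in enumerate(state)})


def load_checkpoint(path) -> ObnModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path, allow_pickle=False) as z:
        cfg = ObnConfig(**json.loads(str(z["config"])))
        model = ObnModel(cfg)
        n = len(model.state_dict())
        model.load_state_dict([z[f"arr_{i}"] for i in range(n)])
    return model


def attend(g, M):
    """Attention weighting ``g'_c = (1 + M) ⊙ g_c`` (M broadcast over channels).

    Accepts engine tensors (differentiable path) or plain arrays.
    """
    g_data = g.data if isinstance(g, Tensor) else np.asarray(g)
    m_data = M.data if isinstance(M, Tensor) else np.asarray(M)
    if g_data.shape[-2:] != m_data.shape[-2:]:
        raise ValueError(
            f"attention map spatial size {m_data.shape[-2:]} does not match features {g_data.shape[-2:]}"
        )
    if isinstance(g, Tensor) or isinstance(M, Tensor):
        g_t = g if isinstance(g, Tensor) else Tensor(g_data)
        m_t = M if isinstance(M, Tensor) else Tensor(m_data)
        return g_t * (m_t + 1.0)
    return (1.0 + m_data) * g_data


def _weight_values(W) -> np.ndarray:
    # accept WeightMap, array, or batch of either
    if hasattr(W, "values") and not isinstance(W, np.ndarray):
        return np.asarray(W.values)
    return np.asarray(W)


def operation_loss(M, W, lambda_: float):
    """Operation-branch penalty ``λ ‖M ⊙ W‖²_F``, averaged over the batch.

    ``M`` is the attention map, (N, 1, h, w) or a bare (h, w) array; ``W``
    the binary weight map(s) at input resolution, (N, H, W) or (H, W).  When
    the resolutions differ, M is bilinearly resized up to W's before the
    Hadamard product.  Returns an engine scalar on the tensor path, a float
    on the array path.
    """
    lambda_ = float(lambda_)
    if lambda_ < 0:
        raise ValueError("lambda_ must be non-negative")
    w = _weight_values(W).astype(np.float64)
    if w.ndim == 2:
        w = w[None]
    tensor_path = isinstance(M, Tensor)
    m = M if tensor_path else Tensor(np.asarray(M, dtype=np.float64))
    if m.ndim == 2:
        m = m.reshape(1, 1, *m.shape)
    elif m.ndim == 3:
        m = m.reshape(m.shape[0], 1, m.shape[1], m.shape[2])
    n = m.shape[0]
    m_up = bilinear_resize(m, w.shape[-2:])
    prod = m_up * w[:, None, :, :]
    loss = (prod * prod).sum() * (lambda_ / n)
    return loss if tensor_path else loss.item()


def inverse_frequency_weights(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """Class weights proportional to inverse class counts, normalised to mean 1.

    With counts (2002, 1030) this yields a minority/majority weight ratio of
    2002/1030.  A class present in `range(num_classes)` but absent from the
    labels would get an infinite weight, so that is an error.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=num_classes).astype(np.float64)
    if (counts == 0).any():
        raise ValueError("every class must appear at least once to weight by inverse frequency")
    w = 1.0 / counts
    return w / w.mean()


def branch_loss(logits: Tensor, labels: np.ndarray,
                class_weights: np.ndarray | None = None,
                multilabel: bool = False) -> Tensor:
    """Classification loss of one branch.

    Single-label: class-weighted softmax cross-entropy.  Multi-label: mean
    binary cross-entropy over label columns (no class reweighting).
    """
    if multilabel:
        return F.bce_with_logits(logits, labels)
    return F.cross_entropy(logits, labels, class_weights)


def total_loss(outs: BranchOutputs, labels: np.ndarray, W,
               cfg: ObnConfig,
               class_weights: np.ndarray | None = None) -> LossBreakdown:
    """Full training loss ``L = L_att + L_per + L_ope`` with its breakdown.

    With ``cfg.lambda_ == 0`` the operation term is skipped entirely, so the
    loss (and every gradient) is exactly that of the ABN baseline.
    """
    l_att = branch_loss(outs.att_logits, labels, class_weights, cfg.multilabel)
    l_per = branch_loss(outs.per_logits, labels, class_weights, cfg.multilabel)
    if cfg.lambda_ == 0.0 or W is None:
        if cfg.lambda_ > 0.0:
            raise ValueError("weight maps are required when lambda_ > 0")
        l_ope = Tensor(np.zeros((), dtype=l_att.dtype))
        total = l_att + l_per
    else:
        l_ope = operation_loss(outs.attention, W, cfg.lambda_)
        total = l_att + l_per + l_ope
    return LossBreakdown(l_att=l_att, l_per=l_per, l_ope=l_ope, total=total)
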