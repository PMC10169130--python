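"""Layer/module abstractions over the autodiff engine."""

from __future__ import annotations

import numpy as np

from .engine import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: recursive parameter collection and train/eval flags."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self.training = True
        for v in vars(self).values():
            if isinstance(v, Module):
                v.train()

    def eval(self) -> None:
        self.training = False
        for v in vars(self).values():
            if isinstance(v, Module):
                v.eval()

    def _buffer_slots(self) -> list[tuple["Module", str]]:
        slots: list[tuple[Module, str]] = []

        def walk(obj):
            if isinstance(obj, Module):
                for name in getattr(obj, "_buffer_names", ()):
                    slots.append((obj, name))
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return slots

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        state += [getattr(m, n).copy() for m, n in self._buffer_slots()]
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        slots = self._buffer_slots()
        if len(state) != len(params) + len(slots):
            raise ValueError("state does not match model parameters")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.astype(p.data.dtype, copy=True)
        for (m, n), s in zip(slots, state[len(params):]):
            setattr(m, n, s.copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 2-D convolution with He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W).

    Training uses batch statistics and maintains running averages for eval.
    With ``affine=False`` the output is pinned to zero mean / unit variance,
    which forbids a uniform shift of the whole map — useful for attention
    heads that a penalty term would otherwise collapse to a constant.
    """

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 affine: bool = True):
        super().__init__()
        self.gamma = Parameter(np.ones(ch)) if affine else None
        self.beta = Parameter(np.zeros(ch)) if affine else None
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(ch, dtype=np.float64)
        self.running_var = np.ones(ch, dtype=np.float64)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x):
        ch = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, ch, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, ch, 1, 1)
            xhat = (x - mu) * (1.0 / sd)
        if self.gamma is not None:
            xhat = xhat * self.gamma.reshape(1, ch, 1, 1) + self.beta.reshape(1, ch, 1, 1)
        return xhat


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, (in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
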