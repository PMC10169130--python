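"""Image ingestion, square zero-padding, resizing, and training augmentations.

Radiograph-like inputs arrive as grayscale PNGs of arbitrary size.  The
model expects square images of a fixed side (224 by default), so ingestion
is: load -> scale to [0, 1] -> zero-pad to square (content centred) ->
bilinear resize.  Binary companion images (weight maps, masks) go through
the same geometry with nearest-neighbour interpolation so they stay binary.

The resize convention used package-wide is bilinear with half-pixel sample
centres and edge clipping (see :func:`obnet.nn.engine._interp_matrix`); at
an exact 2x downsample it averages 2x2 blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .nn.engine import _interp_matrix

__all__ = [
    "RawImage", "ModelImage", "AugmentSpec",
    "load_image", "save_image", "read_label_csv",
    "pad_to_square", "resize_to_input", "resize_nearest", "augment",
]


@dataclass
class RawImage:
    """A grayscale image as loaded, values in [0, 1]."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("image values must lie in [0, 1]")


@dataclass
class ModelImage:
    """A square image at model input resolution, with transform provenance."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        h, w = self.pixels.shape
        if h != w:
            raise ValueError("model image must be square")


@dataclass
class AugmentSpec:
    """Parameters of the four augmentations: gamma, h-flip, rotation, shift."""

    gamma_range: tuple[float, float] = (0.8, 1.25)
    hflip_prob: float = 0.5
    rotation_range_deg: float = 10.0
    shift_range_px: int = 10
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.gamma_range
        if lo <= 0 or hi <= 0:
            raise ValueError("gamma bounds must be positive")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be a probability")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def load_image(path: str | Path) -> RawImage:
    """Load an 8- or 16-bit grayscale PNG, scaled by the max representable value."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # RGB(A) saved grayscale: take the first channel
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        arr = arr / 255.0
    elif arr.dtype in (np.uint16, np.int32):  # PIL mode "I;16" loads as int32
        arr = arr / 65535.0
    else:
        arr = arr.astype(np.float64)
    return RawImage(np.clip(arr, 0.0, 1.0), source_id=str(path))


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an array in [0, 1] as an 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def read_label_csv(path: str | Path) -> pd.DataFrame:
    """Read a label table: `image_path,label` or `image_path` + binary label columns."""
    df = pd.read_csv(path)
    if "image_path" not in df.columns:
        raise ValueError("label CSV must have an image_path column")
    return df


def _pixels(img) -> np.ndarray:
    if isinstance(img, (RawImage, ModelImage)):
        return img.pixels
    return np.asarray(img)


def pad_to_square(img: RawImage | np.ndarray) -> RawImage | np.ndarray:
    """Zero-pad a 2-D image to a square of side max(H, W), content centred.

    The original pixels occupy a contiguous centred block; equal bands
    (differing by one pixel when the deficit is odd) of exact zeros are
    added on both sides of the short axis.
    """
    px = _pixels(img)
    if px.ndim != 2 or px.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    h, w = px.shape
    side = max(h, w)
    top = (side - h) // 2
    left = (side - w) // 2
    out = np.zeros((side, side), dtype=px.dtype)
    out[top:top + h, left:left + w] = px
    if isinstance(img, RawImage):
        return RawImage(out, source_id=img.source_id)
    return out


def _resize_bilinear(px: np.ndarray, size: int) -> np.ndarray:
    h, w = px.shape
    A = _interp_matrix(h, size, np.float64)
    B = _interp_matrix(w, size, np.float64)
    return A @ px @ B.T


def resize_nearest(px: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize of a 2-D array (binarity-preserving)."""
    h, w = px.shape
    ri = np.minimum((np.arange(size) + 0.5) * h / size, h - 1).astype(int)
    ci = np.minimum((np.arange(size) + 0.5) * w / size, w - 1).astype(int)
    return px[np.ix_(ri, ci)]


def resize_to_input(img: RawImage | np.ndarray, input_size: int = 224) -> ModelImage:
    """Bilinear-resize a square image to the model input side.

    Non-square input is rejected so that callers pad explicitly and the
    content aspect ratio is always preserved.
    """
    px = _pixels(img)
    if px.ndim != 2 or px.shape[0] != px.shape[1]:
        raise ValueError("resize_to_input expects a square image; pad first")
    if px.shape[0] == input_size:
        out = px.astype(np.float64, copy=True)
    else:
        out = np.clip(_resize_bilinear(px.astype(np.float64), input_size), 0.0, 1.0)
    prov = {"original_side": px.shape[0], "input_size": input_size}
    if isinstance(img, RawImage):
        prov["source_id"] = img.source_id
    return ModelImage(out, provenance=prov)


def _int_shift(px: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(px)
    h, w = px.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    yo = slice(max(-dy, 0), max(-dy, 0) + (ys.stop - ys.start))
    xo = slice(max(-dx, 0), max(-dx, 0) + (xs.stop - xs.start))
    out[ys, xs] = px[yo, xo]
    return out


def augment(img: ModelImage | np.ndarray,
            paired_map: np.ndarray | None,
            spec: AugmentSpec,
            rng: np.random.Generator | None = None):
    """Apply gamma correction, horizontal flip, rotation, and pixel shift.

    Gamma acts on the image only; the geometric transforms are applied
    identically to the image (bilinear, zero fill) and the paired binary map
    (nearest neighbour, zero fill).  All random draws come from ``rng`` (or
    a generator seeded from ``spec.seed``), and each of the four draws is
    consumed on every call so sequences stay aligned across samples.
    """
    px = _pixels(img).astype(np.float64)
    if paired_map is not None:
        pm = np.asarray(paired_map)
        if pm.shape != px.shape:
            raise ValueError("image and paired map shapes differ")
        pm = pm.astype(np.float64)
    else:
        pm = None
    if rng is None:
        rng = spec.rng()

    gamma = rng.uniform(*spec.gamma_range)
    do_flip = rng.random() < spec.hflip_prob
    angle = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg)
    s = int(spec.shift_range_px)
    dy, dx = (int(v) for v in rng.integers(-s, s + 1, size=2)) if s > 0 else (0, 0)

    px = px**gamma
    if do_flip:
        px = px[:, ::-1].copy()
        if pm is not None:
            pm = pm[:, ::-1].copy()
    if angle != 0.0:
        px = ndimage.rotate(px, angle, reshape=False, order=1, cval=0.0)
        if pm is not None:
            pm = ndimage.rotate(pm, angle, reshape=False, order=0, cval=0.0)
    if dy or dx:
        px = _int_shift(px, dy, dx)
        if pm is not None:
            pm = _int_shift(pm, dy, dx)
    px = np.clip(px, 0.0, 1.0)
    out = ModelImage(px) if isinstance(img, ModelImage) else px
    return out, pm
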