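"""Binary weight maps defining the support of the attention penalty.

A weight map ``W`` is a binary image at model input resolution with the
convention 0 = anatomical region of interest (no penalty), 1 = outside the
anatomy (penalised).  Three construction modes are supported, mirroring the
three kinds of anatomical prior:

* ``lung_hull`` — filled convex hull of the lung-field mask (the hull
  typically covers the mediastinum and heart implicitly);
* ``lung_heart_union`` — pixelwise union of lung and heart masks;
* ``manual`` — a hand-drawn map loaded from disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay, QhullError
from skimage.morphology import convex_hull_image

from .preprocess import load_image, resize_nearest

MODES = ("lung_hull", "lung_heart_union", "manual")

__all__ = [
    "WeightMap", "MODES",
    "convex_hull_mask", "union_mask", "to_weight_map", "load_manual_weight_map",
]


@dataclass
class WeightMap:
    """Binary penalty-support map: 0 over anatomy, 1 outside."""

    values: np.ndarray
    mode: str
    source_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        h, w = self.values.shape
        if h != w:
            raise ValueError("weight map must be square")
        _check_binary(self.values)


def _check_binary(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary (values in {0, 1})")
    return arr.astype(np.uint8)


def convex_hull_mask(organ_mask: np.ndarray) -> np.ndarray:
    """Filled convex hull of all foreground pixels of a binary mask.

    The hull is taken jointly over all foreground components (both lungs at
    once), producing a single convex region.  Membership is decided at
    pixel centres (a pixel is foreground iff its centre lies in the convex
    hull of the foreground pixel centres), which makes the operation
    exactly idempotent.  Empty input stays empty.
    """
    m = _check_binary(organ_mask)
    pts = np.argwhere(m)
    if len(pts) < 3:
        return m.copy()
    try:
        tri = Delaunay(pts)
    except QhullError:
        # collinear foreground: fall back to the rasterized hull
        return convex_hull_image(m.astype(bool)).astype(np.uint8)
    yy, xx = np.mgrid[0:m.shape[0], 0:m.shape[1]]
    inside = tri.find_simplex(np.c_[yy.ravel(), xx.ravel()]) >= 0
    return inside.reshape(m.shape).astype(np.uint8)


def union_mask(lung: np.ndarray, heart: np.ndarray) -> np.ndarray:
    """Pixelwise OR of two binary organ masks."""
    a, b = _check_binary(lung), _check_binary(heart)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    return (a | b).astype(np.uint8)


def to_weight_map(anatomy_mask: np.ndarray, input_size: int, mode: str,
                  source_id: str = "") -> WeightMap:
    """Resize an anatomy mask (1 = anatomy) to input resolution and invert.

    The result has 0 over anatomy and 1 elsewhere — the penalty support.
    An empty anatomy mask is accepted but warned about, since the penalty
    would then cover the whole image.
    """
    m = _check_binary(anatomy_mask)
    if not m.any():
        warnings.warn("empty anatomy mask: penalty covers the entire image",
                      stacklevel=2)
    if m.shape != (input_size, input_size):
        m = resize_nearest(m, input_size)
    return WeightMap((1 - m).astype(np.uint8), mode=mode, source_id=source_id)


def load_manual_weight_map(path: str | Path, input_size: int) -> WeightMap:
    """Load a hand-drawn weight map PNG (white = penalised, black = anatomy)."""
    img = load_image(path)
    px = img.pixels
    if px.shape[0] != px.shape[1]:
        raise ValueError("manual weight map must be square (draw on the padded image)")
    w = (px >= 0.5 * px.max()).astype(np.uint8) if px.max() > 0 else np.zeros_like(px, dtype=np.uint8)
    if w.shape != (input_size, input_size):
        w = resize_nearest(w, input_size)
    return WeightMap(w, mode="manual", source_id=str(path))
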