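"""Synthetic radiograph-like datasets with a planted shortcut.

Each classification image is Gaussian background noise plus a brighter
elliptical "anatomy" region.  Positive-label images carry a soft blob of
contrast ``signal_strength`` at a random location inside the anatomy — the
legitimate discriminative signal.  Independently, a small square corner
marker of contrast ``confound_strength`` is added with probability
``confound_prob`` to positives and ``1 − confound_prob`` to negatives,
emulating the label-correlated metal markers / ruler lines that CNNs are
known to latch onto.  With ``confound_strength > signal_strength`` an
unconstrained classifier can reach high accuracy from the corners alone,
which is exactly the failure mode the operation branch is meant to fix.

Every sample ships its anatomy mask and the paired weight map
``W = 1 − anatomy`` so that penalty-based training and the Attention Index
have ground truth to work against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import SegPair
from .weightmaps import WeightMap

__all__ = ["SynthSpec", "SynthSample",
           "generate_classification_set", "generate_segmentation_set"]


@dataclass
class SynthSpec:
    """Generation conditions for a synthetic confounded dataset.

    Defaults are the conditions of the package's guidance experiment:
    64 px images, in-anatomy signal contrast 0.4 versus a stronger corner
    confounder at 0.8 co-occurring with the positive label 90% of the time.
    """

    n: int = 400
    image_size: int = 64
    signal_strength: float = 0.4
    confound_strength: float = 0.8
    confound_prob: float = 0.9
    noise_sd: float = 0.05
    blob_radius_frac: float = 0.08
    marker_frac: float = 0.09
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.confound_prob <= 1.0:
            raise ValueError("confound_prob must be a probability")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SynthSample:
    image: np.ndarray
    label: int
    weight_map: WeightMap
    anatomy_mask: np.ndarray
    truth_record: dict = field(default_factory=dict)


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0).astype(np.uint8)


def generate_classification_set(spec: SynthSpec) -> list[SynthSample]:
    """Generate a balanced, confounded binary classification set.

    Labels are balanced to within one sample; generation is bit-identical
    under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    blob_r = max(2.0, spec.blob_radius_frac * size)
    marker = max(3, round(spec.marker_frac * size))
    labels = np.zeros(spec.n, dtype=int)
    labels[: spec.n // 2] = 1
    labels = labels[rng.permutation(spec.n)]
    samples: list[SynthSample] = []
    for i in range(spec.n):
        label = int(labels[i])
        img = 0.1 + spec.noise_sd * rng.standard_normal((size, size))
        # anatomy: a bright ellipse, mildly jittered
        cy, cx = (size / 2) * (1 + 0.1 * rng.uniform(-1, 1, 2))
        a = size * rng.uniform(0.26, 0.34)
        b = size * rng.uniform(0.30, 0.38)
        anatomy = _ellipse_mask(size, cy, cx, a, b)
        img += 0.25 * anatomy
        record: dict = {"anatomy": (cy, cx, a, b)}
        if min(a, b) <= blob_r:
            raise ValueError("signal blob larger than the anatomy region")
        if label == 1 and spec.signal_strength > 0:
            # place the blob strictly inside the ellipse
            margin = blob_r / min(a, b)
            r = np.sqrt(rng.uniform(0, 1)) * (1.0 - margin)
            th = rng.uniform(0, 2 * np.pi)
            sy, sx = cy + r * a * np.sin(th), cx + r * b * np.cos(th)
            yy, xx = np.mgrid[0:size, 0:size]
            img += spec.signal_strength * np.exp(
                -((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * (blob_r / 2) ** 2)
            )
            record["signal_center"] = (sy, sx)
        p_marker = spec.confound_prob if label == 1 else 1.0 - spec.confound_prob
        has_marker = rng.random() < p_marker
        corner = int(rng.integers(4))
        if has_marker and spec.confound_strength > 0:
            y0 = 2 if corner < 2 else size - 2 - marker
            x0 = 2 if corner % 2 == 0 else size - 2 - marker
            img[y0:y0 + marker, x0:x0 + marker] += spec.confound_strength
            record["marker_corner"] = corner
        img = np.clip(img, 0.0, 1.0)
        wm = WeightMap((1 - anatomy).astype(np.uint8), mode="manual",
                       source_id=f"synth-{i}")
        samples.append(SynthSample(image=img.astype(np.float64), label=label,
                                   weight_map=wm, anatomy_mask=anatomy,
                                   truth_record=record))
    return samples


def generate_segmentation_set(spec: SynthSpec) -> list[SegPair]:
    """Random bright ellipses as "organs" with exact rasterized truth masks."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    pairs: list[SegPair] = []
    for _ in range(spec.n):
        cy = size * rng.uniform(0.35, 0.65)
        cx = size * rng.uniform(0.35, 0.65)
        a = size * rng.uniform(0.15, 0.30)
        b = size * rng.uniform(0.15, 0.30)
        mask = _ellipse_mask(size, cy, cx, a, b)
        img = 0.1 + spec.noise_sd * rng.standard_normal((size, size)) + 0.4 * mask
        pairs.append(SegPair(image=np.clip(img, 0.0, 1.0), truth_mask=mask))
    return pairs
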