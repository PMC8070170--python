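"""Offline dataset expansion and online CutMix with soft labels.

Offline expansion multiplies the training set by a per-class factor using
random translation, rotation, and flips; the factors 80 (positive) and 48
(negative) balance the two classes when applied to a 576/976 split. CutMix
replaces a random axis-aligned box of one sample with the corresponding
region of a partner and mixes the labels in proportion to the retained area,
yielding soft labels in [0, 1].
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import Sample2D

__all__ = [
    "AugmentConfig",
    "offline_expand",
    "sample_cut_box",
    "cutmix",
    "online_augment",
    "OFFLINE_FACTOR_POS",
    "OFFLINE_FACTOR_NEG",
]

# Per-class factors implied by the printed expansion counts
# (46,080 / 576 and 46,848 / 976).
OFFLINE_FACTOR_POS = 80
OFFLINE_FACTOR_NEG = 48


@dataclass
class AugmentConfig:
    offline_factor_pos: int = OFFLINE_FACTOR_POS
    offline_factor_neg: int = OFFLINE_FACTOR_NEG
    max_translate_px: int = 4
    rotation_angles: tuple = (90.0, 180.0, 270.0)
    max_random_angle: float = 15.0
    flips: tuple = (0, 1)
    cutmix_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offline_factor_pos < 1 or self.offline_factor_neg < 1:
            raise ValueError("offline factors must be >= 1")
        if not 0.0 <= self.cutmix_prob <= 1.0:
            raise ValueError("cutmix_prob must lie in [0, 1]")


def _planes(sample):
    """View a sample as a list of 2D planes sharing one in-plane geometry."""
    if isinstance(sample, Sample2D):
        return sample.channels, 0  # (3, H, W), plane axis first
    return np.moveaxis(sample.volume, -1, 0), -1  # (D, H, W)


def _transform_sample(sample, rng: np.random.Generator, cfg: AugmentConfig):
    """Random translate/rotate/flip composition applied identically in-plane."""
    planes, axis = _planes(sample)
    out = planes.astype(np.float64, copy=True)

    # Rotation: a right angle or a small random angle, in-plane.
    if rng.random() < 0.5 and cfg.rotation_angles:
        angle = float(rng.choice(cfg.rotation_angles))
    else:
        angle = float(rng.uniform(-cfg.max_random_angle, cfg.max_random_angle))
    if angle % 360 != 0:
        out = ndimage.rotate(
            out, angle, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
        )

    # Integer translation with zero fill.
    t = cfg.max_translate_px
    if t > 0:
        di, dj = rng.integers(-t, t + 1), rng.integers(-t, t + 1)
        out = ndimage.shift(out, (0, di, dj), order=0, mode="constant", cval=0.0)

    for ax in cfg.flips:
        if rng.random() < 0.5:
            out = np.flip(out, axis=1 + ax)

    out = np.clip(out, 0.0, 1.0)
    new = copy.copy(sample)
    if isinstance(sample, Sample2D):
        new.channels = np.ascontiguousarray(out)
    else:
        new.volume = np.ascontiguousarray(np.moveaxis(out, 0, -1))
    return new


def offline_expand(samples, factor: int, rng: np.random.Generator, cfg: AugmentConfig | None = None):
    """Expand ``samples`` by ``factor``; the first copy of each is the original.

    Output count is exactly ``len(samples) * factor``; labels are never
    changed by offline augmentation.
    """
    if factor < 1:
        raise ValueError(f"expansion factor must be >= 1, got {factor}")
    cfg = cfg or AugmentConfig()
    out = []
    for s in samples:
        out.append(s)
        for _ in range(factor - 1):
            out.append(_transform_sample(s, rng, cfg))
    return out


def sample_cut_box(shape_hw: tuple[int, int], rng: np.random.Generator):
    """Draw a CutMix box: area ratio 1-lam with lam ~ U(0,1), uniform center.

    Returns ``(i0, i1, j0, j1)`` half-open bounds, clipped to the patch.
    """
    h, w = shape_hw
    lam = rng.uniform(0.0, 1.0)
    ratio = np.sqrt(1.0 - lam)
    bh, bw = int(round(h * ratio)), int(round(w * ratio))
    ci, cj = int(rng.integers(0, h)), int(rng.integers(0, w))
    i0, i1 = np.clip([ci - bh // 2, ci - bh // 2 + bh], 0, h)
    j0, j1 = np.clip([cj - bw // 2, cj - bw // 2 + bw], 0, w)
    return int(i0), int(i1), int(j0), int(j1)


def cutmix(sample_a, sample_b, rng: np.random.Generator | None = None, box=None):
    """Mix two same-shape samples: paste ``sample_b``'s box into ``sample_a``.

    The box spans all channels (2D) or the full depth extent (3D), so the
    mixed label is ``lam * label_a + (1 - lam) * label_b`` with
    ``lam = 1 - box_area / patch_area``.
    """
    arr_a, _ = _planes(sample_a)
    arr_b, _ = _planes(sample_b)
    if arr_a.shape != arr_b.shape:
        raise ValueError(f"shape mismatch: {arr_a.shape} vs {arr_b.shape}")
    h, w = arr_a.shape[1:]
    if box is None:
        if rng is None:
            raise ValueError("either rng or an explicit box is required")
        box = sample_cut_box((h, w), rng)
    i0, i1, j0, j1 = box
    mixed = arr_a.copy()
    mixed[:, i0:i1, j0:j1] = arr_b[:, i0:i1, j0:j1]
    lam = 1.0 - (i1 - i0) * (j1 - j0) / (h * w)
    new = copy.copy(sample_a)
    label = lam * sample_a.label + (1.0 - lam) * sample_b.label
    if isinstance(sample_a, Sample2D):
        new.channels = mixed
    else:
        new.volume = np.moveaxis(mixed, 0, -1)
    new.label = float(label)
    return new


def online_augment(batch, cutmix_prob: float, rng: np.random.Generator):
    """With probability ``cutmix_prob``, CutMix the whole batch against a
    random within-batch permutation of partners; otherwise pass it through."""
    if rng.random() >= cutmix_prob or len(batch) < 2:
        return list(batch)
    partners = rng.permutation(len(batch))
    return [cutmix(batch[i], batch[int(partners[i])], rng) for i in range(len(batch))]
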