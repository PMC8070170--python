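"""Synthetic phantom nodule cases for end-to-end training without patient data.

The generator emulates the class structure reported for preinvasive lesions
(PILs) versus other nodules in low-dose CT: positives are small, smooth
blobs with uniform interior density; negatives (dominated by invasive
adenocarcinomas) are larger, with speckled interior intensity, lobulated
boundaries, and sometimes an adjacent bright vessel-like tube. Those are
exactly the cues the discussion of misclassified cases attributes to the two
classes, and they exercise the raw/LBP/edge 2D channels and the 3D extent
cue used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import DatasetSplit, NoduleCase, normalize_stack

__all__ = ["PhantomConfig", "generate_case", "generate_dataset"]


@dataclass
class PhantomConfig:
    """Geometry and texture knobs of the phantom generator (pixel units)."""

    volume_shape: tuple[int, int, int] = (64, 64, 16)  # (H, W, n_slices)
    pos_radius_range: tuple[float, float] = (3.0, 6.0)
    neg_radius_range: tuple[float, float] = (7.0, 11.0)
    pos_lobulation: float = 0.05
    neg_lobulation: float = 0.30
    neg_heterogeneity: float = 0.35
    vessel_prob: float = 0.3
    nodule_intensity: float = 0.7
    noise_sd: float = 0.02
    smooth_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w, _ = self.volume_shape
        rmax = self.neg_radius_range[1] * (1.0 + self.neg_lobulation)
        if 2 * rmax + 4 > min(h, w):
            raise ValueError("largest nodule radius does not fit inside the volume")
        for name in ("neg_heterogeneity", "neg_lobulation", "pos_lobulation", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _lobulated_mask(shape_hw, center, r0, rz, ck, depth, lobulation, rng):
    """Boolean (D, H, W) mask of a radius-perturbed ellipsoid."""
    h, w = shape_hw
    n_lobes = int(rng.integers(3, 7))
    phase = rng.uniform(0.0, 2 * np.pi)
    ii, jj = np.mgrid[0:h, 0:w]
    di, dj = ii - center[0], jj - center[1]
    theta = np.arctan2(dj, di)
    r_theta = r0 * (1.0 + lobulation * np.sin(n_lobes * theta + phase))
    rho2 = (di**2 + dj**2) / np.maximum(r_theta, 1e-9) ** 2
    kk = np.arange(depth, dtype=np.float64)
    dz2 = ((kk - ck) / rz) ** 2
    return rho2[None, :, :] + dz2[:, None, None] <= 1.0


def generate_case(class_label: int, config: PhantomConfig, rng: np.random.Generator,
                  case_id: str = "case") -> NoduleCase:
    """Draw one phantom case of the requested class.

    Positive (PIL-like): small ellipsoid, uniform interior, near-circular
    boundary. Negative: larger, speckled interior, lobulated boundary, and an
    adjacent bright tube with probability ``vessel_prob``.
    """
    h, w, depth = config.volume_shape
    if class_label == 1:
        r0 = float(rng.uniform(*config.pos_radius_range))
        lobulation, heterogeneity, vessel = config.pos_lobulation, 0.0, False
    else:
        r0 = float(rng.uniform(*config.neg_radius_range))
        lobulation, heterogeneity = config.neg_lobulation, config.neg_heterogeneity
        vessel = rng.random() < config.vessel_prob
    margin = r0 * (1.0 + lobulation) + 2.0
    rz = max(1.5, r0 / 2.5)
    rz = min(rz, (depth - 2) / 2.0)
    ci = float(rng.uniform(margin, h - margin))
    cj = float(rng.uniform(margin, w - margin))
    ck = float(rng.uniform(rz + 0.5, depth - rz - 1.5))

    mask = _lobulated_mask((h, w), (ci, cj), r0, rz, ck, depth, lobulation, rng)
    vol = np.zeros((depth, h, w), dtype=np.float64)
    interior = np.full(mask.sum(), config.nodule_intensity)
    if heterogeneity > 0:
        speckle = ndimage.gaussian_filter(rng.normal(size=(depth, h, w)), 1.0)
        sd = speckle.std() or 1.0
        interior *= 1.0 + heterogeneity * (speckle[mask] / sd)
    vol[mask] = interior

    if vessel:
        # bright in-plane tube tangent to the nodule
        off = int(round(r0)) + 1
        row = int(np.clip(round(ci) + rng.choice([-off, off]), 1, h - 2))
        k0 = int(np.clip(round(ck), 1, depth - 2))
        vol[k0 - 1 : k0 + 2, row - 1 : row + 2, :] = np.maximum(
            vol[k0 - 1 : k0 + 2, row - 1 : row + 2, :], 0.9 * config.nodule_intensity
        )

    if config.smooth_sigma > 0:
        vol = ndimage.gaussian_filter(vol, config.smooth_sigma)
        # homogeneous nodules stay exactly uniform inside; only the outside
        # halo is softened
        if heterogeneity == 0 and not vessel:
            vol[mask] = config.nodule_intensity
    if config.noise_sd > 0:
        vol += rng.normal(0.0, config.noise_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, 1.0)

    center_slice = int(np.round(ck))
    center_mask = mask[center_slice]
    if not center_mask.any():  # extremely flat ellipsoid; fall back to densest slice
        center_slice = int(mask.sum(axis=(1, 2)).argmax())
        center_mask = mask[center_slice]
    rows = np.flatnonzero(center_mask.any(axis=1))
    cols = np.flatnonzero(center_mask.any(axis=0))
    rect = (int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1]))

    return NoduleCase(
        case_id=case_id,
        slices=normalize_stack(vol),
        rect=rect,
        center_slice=center_slice,
        label=int(class_label),
    )


def generate_dataset(n_pos: int = 97, n_neg: int = 147,
                     config: PhantomConfig | None = None,
                     rng: np.random.Generator | None = None,
                     n_test_per_class: int = 25):
    """Generate a stratified phantom dataset with a held-out test set.

    The defaults give a 72 positive / 122 negative training split with a
    balanced 25 + 25 test set — a 1/8-scale miniature of the published
    576/976 train and 100/100 test composition.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one case per class")
    if min(n_pos, n_neg) <= n_test_per_class:
        raise ValueError("each class needs more cases than the test allocation")
    config = config or PhantomConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cases = []
    for k in range(n_pos):
        cases.append(generate_case(1, config, rng, case_id=f"pos_{k:04d}"))
    for k in range(n_neg):
        cases.append(generate_case(0, config, rng, case_id=f"neg_{k:04d}"))
    split = DatasetSplit()
    for label, ids in ((1, [c.case_id for c in cases if c.label == 1]),
                       (0, [c.case_id for c in cases if c.label == 0])):
        ids = list(ids)
        rng.shuffle(ids)
        split.test_cases.extend(ids[:n_test_per_class])
        split.train_cases.extend(ids[n_test_per_class:])
    return cases, split
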