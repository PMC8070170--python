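"""Build 2D three-channel samples and 3D sub-volumes from a nodule case.

The 2D sample stacks three 32x32 maps centered on the nodule rectangle's
midpoint in the reference center slice: the raw crop, a Local Binary Pattern
texture map, and a binary Canny edge map. The 3D sample is the 32x32x7
sub-volume through the same center (3 slices either side of the reference
slice). Crops falling outside the image or the stack are zero padded — zero
is a common background value in the rescaled CT patches.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import canny

from .core_io import NoduleCase, Sample2D, Sample3D

__all__ = [
    "nodule_center",
    "crop_2d",
    "lbp_map",
    "edge_map",
    "build_sample_2d",
    "build_sample_3d",
]

PATCH_SIZE = 32
DEPTH = 7

# Classic square 8-neighbourhood, ordered E, NE, N, NW, W, SW, S, SE.
_LBP_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def nodule_center(rect: tuple[int, int, int, int]) -> tuple[int, int]:
    """Midpoint of the annotation rectangle; odd sums round down."""
    iL, jL, iR, jR = rect
    return (iL + iR) // 2, (jL + jR) // 2


def crop_2d(slice_image: np.ndarray, center: tuple[int, int], size: int = PATCH_SIZE) -> np.ndarray:
    """Extract a ``size x size`` patch centered at ``center``, zero padded.

    The patch covers rows ``[i_c - size//2, i_c + size//2)`` (half-open), so
    the center pixel sits at patch index ``size//2``.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    half = size // 2
    i_c, j_c = center
    patch = np.zeros((size, size), dtype=np.float64)
    i0, i1 = i_c - half, i_c - half + size
    j0, j1 = j_c - half, j_c - half + size
    si0, sj0 = max(i0, 0), max(j0, 0)
    si1, sj1 = min(i1, img.shape[0]), min(j1, img.shape[1])
    if si0 < si1 and sj0 < sj1:
        patch[si0 - i0 : si1 - i0, sj0 - j0 : sj1 - j0] = img[si0:si1, sj0:sj1]
    return patch


def lbp_map(patch: np.ndarray) -> np.ndarray:
    """Per-pixel 8-neighbour radius-1 Local Binary Pattern map, scaled to [0, 1].

    Bit k of the code is set when the k-th neighbour is >= the center pixel
    (ties count, so a constant patch carries the all-ones code everywhere).
    Border pixels use replicated edges for their missing neighbours. The code
    is divided by 255, the maximum possible value. Adding a constant to the
    patch leaves the map unchanged (gray invariance).
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise ValueError(f"lbp_map needs a 2D patch of at least 3x3, got {patch.shape}")
    padded = np.pad(patch, 1, mode="edge")
    h, w = patch.shape
    code = np.zeros((h, w), dtype=np.float64)
    for bit, (di, dj) in enumerate(_LBP_OFFSETS):
        neigh = padded[1 + di : 1 + di + h, 1 + dj : 1 + dj + w]
        code += (neigh >= patch) * (1 << bit)
    return code / 255.0


def edge_map(
    patch: np.ndarray,
    sigma: float = 1.0,
    low_quantile: float = 0.10,
    high_quantile: float = 0.30,
) -> np.ndarray:
    """Binary Canny edge map (values in {0, 1}).

    Gaussian smoothing at ``sigma`` followed by hysteresis thresholding, with
    the thresholds taken at low quantiles of the gradient magnitude so that as
    many edges as possible survive.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.max() == patch.min():
        return np.zeros_like(patch)
    edges = canny(
        patch,
        sigma=sigma,
        low_threshold=low_quantile,
        high_threshold=high_quantile,
        use_quantiles=True,
    )
    return edges.astype(np.float64)


def build_sample_2d(case: NoduleCase) -> Sample2D:
    """Three-channel planar sample from the reference center slice."""
    center = nodule_center(case.rect)
    crop = crop_2d(case.slices[case.center_slice], center)
    return Sample2D(
        channels=np.stack([crop, lbp_map(crop), edge_map(crop)]),
        label=float(case.label),
        case_id=case.case_id,
    )


def build_sample_3d(case: NoduleCase, depth: int = DEPTH) -> Sample3D:
    """32x32x``depth`` sub-volume centered on the reference slice.

    ``depth // 2`` slices either side of the center slice are cropped at the
    nodule center; planes beyond the ends of the stack are zero padded.
    """
    center = nodule_center(case.rect)
    half = depth // 2
    planes = []
    for k in range(case.center_slice - half, case.center_slice + half + 1):
        if 0 <= k < case.n_slices:
            planes.append(crop_2d(case.slices[k], center))
        else:
            planes.append(np.zeros((PATCH_SIZE, PATCH_SIZE)))
    volume = np.stack(planes, axis=-1)  # (32, 32, depth)
    return Sample3D(volume=volume, label=float(case.label), case_id=case.case_id)
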