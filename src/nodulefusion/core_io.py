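"""Domain types and readers/writers for nodule cases, samples, and feature tables.

A *case* is one patient: an ordered stack of grayscale CT slices (assumed
1 mm spacing), a doctor-drawn bounding rectangle around the nodule, the index
of the reference center slice, and a binary label (1 = preinvasive lesion,
the positive class; 0 = other, i.e. invasive adenocarcinoma or benign).

Coordinates are 0-based ``(row=i, col=j)`` and the rectangle
``(iL, jL, iR, jR)`` is inclusive of both corners.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NoduleCase",
    "Sample2D",
    "Sample3D",
    "DatasetSplit",
    "ValidationError",
    "normalize_stack",
    "read_case",
    "read_annotations",
    "write_annotations",
    "write_stack",
    "write_sample_archive",
    "read_sample_archive",
    "write_feature_table",
    "read_feature_table",
]

ANNOTATION_COLUMNS = ["case_id", "iL", "jL", "iR", "jR", "center_slice", "label"]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(eq=False)
class NoduleCase:
    """One patient case: slice stack, nodule rectangle, center slice, label."""

    case_id: str
    slices: np.ndarray  # (n_slices, H, W), intensities in [0, 1]
    rect: tuple[int, int, int, int]  # (iL, jL, iR, jR), inclusive corners
    center_slice: int
    label: int

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValidationError("slices must be a (n_slices, H, W) stack")
        iL, jL, iR, jR = self.rect
        n, h, w = self.slices.shape
        if iL > iR or jL > jR:
            raise ValidationError(f"rect corners out of order: {self.rect}")
        if not (0 <= self.center_slice < n):
            raise ValidationError(
                f"center_slice out of range: {self.center_slice} not in [0, {n})"
            )
        if iL < 0 or jL < 0 or iR >= h or jR >= w:
            raise ValidationError(f"rect {self.rect} outside slice bounds {(h, w)}")
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label}")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass(eq=False)
class Sample2D:
    """32x32 patch with three feature channels: raw crop, LBP texture, Canny edges."""

    channels: np.ndarray  # (3, 32, 32) in [0, 1]
    label: float  # soft label in [0, 1] after CutMix
    case_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.shape != (3, 32, 32):
            raise ValidationError(
                f"Sample2D channels must be (3, 32, 32), got {self.channels.shape}"
            )
        if not (0.0 <= self.label <= 1.0):
            raise ValidationError(f"label must lie in [0, 1], got {self.label}")


@dataclass(eq=False)
class Sample3D:
    """32x32x7 single-channel sub-volume around the nodule center."""

    volume: np.ndarray  # (32, 32, 7) in [0, 1]
    label: float
    case_id: str = ""

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float64)
        if self.volume.shape != (32, 32, 7):
            raise ValidationError(
                f"Sample3D volume must be (32, 32, 7), got {self.volume.shape}"
            )
        if not (0.0 <= self.label <= 1.0):
            raise ValidationError(f"label must lie in [0, 1], got {self.label}")


@dataclass
class DatasetSplit:
    """Disjoint train/test partition of case ids, stratified by class."""

    train_cases: list[str] = field(default_factory=list)
    test_cases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.train_cases) & set(self.test_cases):
            raise ValidationError("train and test case ids overlap")


def normalize_stack(stack: np.ndarray) -> np.ndarray:
    """Min-max rescale a slice stack to [0, 1]; a constant stack maps to zeros."""
    stack = np.asarray(stack, dtype=np.float64)
    lo, hi = stack.min(), stack.max()
    if hi == lo:
        return np.zeros_like(stack)
    return (stack - lo) / (hi - lo)


def _load_stack(stack_source) -> np.ndarray:
    """Load a slice stack from an array, a NIfTI file, or a directory of images."""
    if isinstance(stack_source, np.ndarray):
        return stack_source
    path = Path(stack_source)
    if not path.exists():
        raise FileNotFoundError(f"stack source not found: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no slice images (.png/.tif) in {path}")
        import imageio.v3 as iio

        return np.stack([np.asarray(iio.imread(f), dtype=np.float64) for f in files])
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        # NIfTI stores (H, W, n_slices); reorder to slice-major.
        return np.moveaxis(vol, -1, 0)
    raise ValueError(f"unrecognized stack source: {path}")


def read_case(stack_source, annotation_record) -> NoduleCase:
    """Build a validated :class:`NoduleCase` from a stack and an annotation row.

    ``annotation_record`` is any mapping with keys ``case_id, iL, jL, iR, jR,
    center_slice, label``. Intensities are min-max rescaled to [0, 1] over the
    whole stack.
    """
    rec = dict(annotation_record)
    stack = normalize_stack(_load_stack(stack_source))
    return NoduleCase(
        case_id=str(rec["case_id"]),
        slices=stack,
        rect=(int(rec["iL"]), int(rec["jL"]), int(rec["iR"]), int(rec["jR"])),
        center_slice=int(rec["center_slice"]),
        label=int(rec["label"]),
    )


def read_annotations(path) -> pd.DataFrame:
    """Read the annotation CSV (header required, one row per case)."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation CSV missing columns: {missing}")
    return df


def write_annotations(cases: Sequence[NoduleCase], path) -> Path:
    rows = [
        {
            "case_id": c.case_id,
            "iL": c.rect[0],
            "jL": c.rect[1],
            "iR": c.rect[2],
            "jR": c.rect[3],
            "center_slice": c.center_slice,
            "label": c.label,
        }
        for c in cases
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)
    return path


def write_stack(case: NoduleCase, directory) -> Path:
    """Write a case's slices as ordered 16-bit PNGs under ``directory/case_id/``."""
    import imageio.v3 as iio

    out = Path(directory) / case.case_id
    out.mkdir(parents=True, exist_ok=True)
    for k, sl in enumerate(case.slices):
        iio.imwrite(out / f"slice_{k:04d}.png", np.round(sl * 65535).astype(np.uint16))
    return out


def write_sample_archive(samples, path) -> Path:
    """Write 2D or 3D samples to a self-describing ``.npz`` archive (lossless)."""
    path = Path(path)
    if samples and isinstance(samples[0], Sample2D):
        kind, arrays = "2d", [s.channels for s in samples]
    elif samples and isinstance(samples[0], Sample3D):
        kind, arrays = "3d", [s.volume for s in samples]
    else:
        kind, arrays = "2d", []
    labels = np.array([s.label for s in samples], dtype=np.float64)
    ids = np.array([s.case_id for s in samples], dtype=object)
    data = np.stack(arrays) if arrays else np.zeros((0,))
    np.savez_compressed(
        path, kind=kind, data=data, labels=labels, case_ids=ids.astype(str)
    )
    return path


def read_sample_archive(path) -> list:
    """Read an archive written by :func:`write_sample_archive`."""
    path = os.fspath(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            kind = str(z["kind"])
            data, labels = z["data"], z["labels"]
            ids = [str(s) for s in z["case_ids"]]
    except Exception as exc:  # noqa: BLE001 - corrupt archives raise zlib/zip errors
        raise ValueError(f"cannot parse sample archive {path}: {exc}") from exc
    cls = Sample2D if kind == "2d" else Sample3D
    if labels.size == 0:
        return []
    return [cls(arr, float(lab), cid) for arr, lab, cid in zip(data, labels, ids)]


def write_feature_table(vectors, labels, path, case_ids=None) -> Path:
    """Write feature vectors + labels to CSV, one row per sample, ``f000..`` columns."""
    vectors = [np.asarray(v, dtype=np.float64) for v in vectors]
    if vectors:
        d = vectors[0].shape
        if any(v.shape != d for v in vectors):
            raise ValidationError("feature vectors have mixed lengths")
    mat = np.stack(vectors) if vectors else np.zeros((0, 0))
    df = pd.DataFrame(mat, columns=[f"f{k:03d}" for k in range(mat.shape[1])])
    df.insert(0, "case_id", list(case_ids) if case_ids is not None else range(len(df)))
    df["label"] = list(labels)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path):
    """Read a feature CSV back into ``(vectors, labels, case_ids)``."""
    df = pd.read_csv(path, float_precision="round_trip")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    vectors = df[feat_cols].to_numpy(dtype=np.float64)
    labels = df["label"].to_numpy()
    return vectors, labels, df["case_id"].astype(str).tolist()
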