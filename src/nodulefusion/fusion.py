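"""Feature extraction, 2D/3D vector fusion, and the gradient-boosted-tree stage.

After the two branch networks are trained, each case is summarized by the
global-average-pooled 256-dim feature vector of each branch. The fused
representation concatenates them, 3D half first:

    v_fused = [v3D(1..256), v2D(1..256)]

An XGBoost classifier (max depth 8, learning rate 0.02, 60 boosting rounds)
is then trained on the fused vectors and produces the final class score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.network import FEATURE_DIM, BranchNetwork

__all__ = [
    "GBTConfig",
    "extract_features",
    "fuse_vectors",
    "train_gbt",
    "predict_fused",
]

FUSED_DIM = 2 * FEATURE_DIM


@dataclass
class GBTConfig:
    max_depth: int = 8
    learning_rate: float = 0.02
    n_rounds: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth <= 0 or self.learning_rate <= 0 or self.n_rounds <= 0:
            raise ValueError("GBT hyperparameters must be positive")


def extract_features(trained_net: BranchNetwork, x: np.ndarray) -> np.ndarray:
    """Inference-mode pooled feature vectors, one 256-vector per sample."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != trained_net.dim + 2 or x.shape[1] != trained_net.in_channels:
        raise ValueError(
            f"input shape {x.shape} does not match a {trained_net.dim}D network "
            f"with {trained_net.in_channels} input channels"
        )
    return trained_net.features(x)


def fuse_vectors(v3d: np.ndarray, v2d: np.ndarray) -> np.ndarray:
    """Concatenate per-case features, 3D part first. Accepts single vectors
    (length 256) or stacked matrices (N x 256)."""
    v3d = np.asarray(v3d, dtype=np.float64)
    v2d = np.asarray(v2d, dtype=np.float64)
    if v3d.shape[-1] != FEATURE_DIM or v2d.shape[-1] != FEATURE_DIM:
        raise ValueError(
            f"feature vectors must have length {FEATURE_DIM}, "
            f"got {v3d.shape[-1]} and {v2d.shape[-1]}"
        )
    if v3d.shape != v2d.shape:
        raise ValueError(f"shape mismatch: {v3d.shape} vs {v2d.shape}")
    return np.concatenate([v3d, v2d], axis=-1)


def train_gbt(fused: np.ndarray, labels: np.ndarray, config: GBTConfig | None = None):
    """Fit the boosted-tree stage on fused vectors with binary labels."""
    from xgboost import XGBClassifier

    config = config or GBTConfig()
    fused = np.asarray(fused, dtype=np.float64)
    labels = np.asarray(labels)
    if len(fused) == 0:
        raise ValueError("empty training set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    model = XGBClassifier(
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        n_estimators=config.n_rounds,
        objective="binary:logistic",
        n_jobs=1,
        random_state=config.seed,
        eval_metric="logloss",
    )
    model.fit(fused, labels.astype(int))
    return model


def predict_fused(model, fused: np.ndarray) -> np.ndarray:
    """Probability score in [0, 1] for each fused vector."""
    fused = np.atleast_2d(np.asarray(fused, dtype=np.float64))
    if fused.shape[1] != FUSED_DIM:
        raise ValueError(f"fused vectors must have length {FUSED_DIM}, got {fused.shape[1]}")
    return model.predict_proba(fused)[:, 1]
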