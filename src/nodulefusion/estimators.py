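"""Scikit-learn style estimators wrapping the branch networks and the fusion stage.

``AttentionCNNClassifier`` trains one branch (2D or 3D) end to end;
``HybridNoduleClassifier`` trains both branches plus the boosted-tree stage
on the concatenated feature vectors. Both follow the sklearn contract
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params``) and so compose
with sklearn model selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .fusion import GBTConfig, extract_features, fuse_vectors, predict_fused, train_gbt
from .nn.network import build_network, kaiming_init
from .training import TrainConfig, train_network

__all__ = ["AttentionCNNClassifier", "HybridNoduleClassifier", "as_network_input"]

DEFAULT_LR = {2: 0.004, 3: 0.02}


def as_network_input(x: np.ndarray, dim: int) -> np.ndarray:
    """Coerce sample-layout arrays into network layout.

    2D: ``(N, 3, 32, 32)`` is passed through. 3D: ``(N, 32, 32, 7)``
    (sample layout, depth last) becomes ``(N, 1, 7, 32, 32)``; a 5D array is
    assumed to be in network layout already.
    """
    x = np.asarray(x, dtype=np.float64)
    if dim == 2:
        if x.ndim != 4:
            raise ValueError(f"2D input must be (N, C, H, W), got {x.shape}")
        return x
    if x.ndim == 5:
        return x
    if x.ndim == 4:
        return np.ascontiguousarray(np.moveaxis(x, -1, 1)[:, None])
    raise ValueError(f"3D input must be (N, H, W, D) or (N, 1, D, H, W), got {x.shape}")


class AttentionCNNClassifier(ClassifierMixin, BaseEstimator):
    """One attention-residual branch network as a binary classifier.

    Parameters mirror the published training settings: SGD with momentum,
    initial learning rate 0.004 (2D) or 0.02 (3D), decay 0.9 every 10
    epochs, L2 coefficient 1e-6, online CutMix with probability 0.5.
    """

    def __init__(self, dim: int = 2, channels=(64, 128, 256), kernel_size: int = 3,
                 initial_lr: float | None = None, decay_rate: float = 0.9,
                 decay_period_epochs: int = 10, alpha_l2: float = 1e-6,
                 momentum: float = 0.9, batch_size: int = 32, epochs: int = 60,
                 cutmix_prob: float = 0.5, random_state: int = 0):
        self.dim = dim
        self.channels = channels
        self.kernel_size = kernel_size
        self.initial_lr = initial_lr
        self.decay_rate = decay_rate
        self.decay_period_epochs = decay_period_epochs
        self.alpha_l2 = alpha_l2
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.cutmix_prob = cutmix_prob
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        lr = self.initial_lr if self.initial_lr is not None else DEFAULT_LR[self.dim]
        return TrainConfig(
            initial_lr=lr, decay_rate=self.decay_rate,
            decay_period_epochs=self.decay_period_epochs, alpha_l2=self.alpha_l2,
            momentum=self.momentum, batch_size=self.batch_size, epochs=self.epochs,
            cutmix_prob=self.cutmix_prob, seed=self.random_state,
        )

    def fit(self, X, y):
        x = as_network_input(X, self.dim)
        y = np.asarray(y, dtype=np.float64)
        self.classes_ = np.array([0, 1])
        rng = np.random.default_rng(self.random_state)
        net = kaiming_init(
            build_network(self.dim, channels=tuple(self.channels),
                          kernel_size=self.kernel_size, in_channels=x.shape[1]),
            rng,
        )
        self.history_ = train_network(net, x, y, self._train_config(), rng)
        self.network_ = net
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        p = self.network_.predict_proba(as_network_input(X, self.dim))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def transform(self, X):
        """256-dim pooled feature vectors (the representation used for fusion)."""
        check_is_fitted(self, "network_")
        return extract_features(self.network_, as_network_input(X, self.dim))


class HybridNoduleClassifier(ClassifierMixin, BaseEstimator):
    """Full hybrid model: 2D branch + 3D branch + XGBoost on fused features.

    ``X`` is a pair ``(X2d, X3d)`` of per-case sample arrays in matching
    order. The boosted-tree stage is trained on the un-augmented per-case
    fused vectors (3D half first).
    """

    def __init__(self, channels=(64, 128, 256), kernel_size: int = 3,
                 lr_2d: float = 0.004, lr_3d: float = 0.02,
                 epochs_2d: int = 60, epochs_3d: int = 60, batch_size: int = 32,
                 alpha_l2: float = 1e-6, momentum: float = 0.9,
                 cutmix_prob: float = 0.5, gbt_max_depth: int = 8,
                 gbt_learning_rate: float = 0.02, gbt_rounds: int = 60,
                 random_state: int = 0):
        self.channels = channels
        self.kernel_size = kernel_size
        self.lr_2d = lr_2d
        self.lr_3d = lr_3d
        self.epochs_2d = epochs_2d
        self.epochs_3d = epochs_3d
        self.batch_size = batch_size
        self.alpha_l2 = alpha_l2
        self.momentum = momentum
        self.cutmix_prob = cutmix_prob
        self.gbt_max_depth = gbt_max_depth
        self.gbt_learning_rate = gbt_learning_rate
        self.gbt_rounds = gbt_rounds
        self.random_state = random_state

    def _branch(self, dim: int, lr: float, epochs: int, seed: int) -> AttentionCNNClassifier:
        return AttentionCNNClassifier(
            dim=dim, channels=self.channels, kernel_size=self.kernel_size,
            initial_lr=lr, alpha_l2=self.alpha_l2, momentum=self.momentum,
            batch_size=self.batch_size, epochs=epochs, cutmix_prob=self.cutmix_prob,
            random_state=seed,
        )

    def fit(self, X, y):
        x2d, x3d = X
        y = np.asarray(y, dtype=np.float64)
        self.classes_ = np.array([0, 1])
        self.cnn2d_ = self._branch(2, self.lr_2d, self.epochs_2d, self.random_state).fit(x2d, y)
        self.cnn3d_ = self._branch(3, self.lr_3d, self.epochs_3d, self.random_state + 1).fit(x3d, y)
        fused = fuse_vectors(self.cnn3d_.transform(x3d), self.cnn2d_.transform(x2d))
        self.gbt_ = train_gbt(
            fused, (y >= 0.5).astype(int),
            GBTConfig(max_depth=self.gbt_max_depth, learning_rate=self.gbt_learning_rate,
                      n_rounds=self.gbt_rounds, seed=self.random_state),
        )
        return self

    def fused_vectors(self, X):
        check_is_fitted(self, "gbt_")
        x2d, x3d = X
        return fuse_vectors(self.cnn3d_.transform(x3d), self.cnn2d_.transform(x2d))

    def predict_proba(self, X):
        p = predict_fused(self.gbt_, self.fused_vectors(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
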