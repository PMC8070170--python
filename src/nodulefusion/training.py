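"""Loss, learning-rate schedule, and the SGD-with-momentum training loop.

The loss is binary cross-entropy over sigmoid outputs (soft labels allowed,
as CutMix produces them) plus an L2 penalty ``alpha * sum ||w||^2`` over
convolution and linear weights. The learning rate decays geometrically:
``lr(epoch) = initial * decay ** floor(epoch / period)`` (0.9 every 10
epochs by default, so an initial 0.02 becomes 0.018 at epoch 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augmentation import sample_cut_box
from .nn.layers import Module

__all__ = ["TrainConfig", "bce_l2_loss", "lr_at_epoch", "train_network", "sigmoid"]

EPS = 1e-7  # prediction clamp so ln(0) never occurs


@dataclass
class TrainConfig:
    """Hyperparameters of one branch-network training run.

    Initial learning rates follow the published settings: 0.004 for the 2D
    branch and 0.02 for the 3D branch.
    """

    initial_lr: float = 0.004
    decay_rate: float = 0.9
    decay_period_epochs: int = 10
    alpha_l2: float = 1e-6
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 60
    cutmix_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.decay_rate <= 1.0):
            raise ValueError("decay_rate must lie in (0, 1]")
        for name in ("initial_lr", "decay_period_epochs", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def bce_l2_loss(predictions, labels, weights=(), alpha: float = 0.0,
                eps: float = EPS) -> float:
    """Mean negative binary cross-entropy plus ``alpha * sum of squared weights``.

    ``predictions`` are probabilities in (0, 1) (clamped to ``[eps, 1-eps]``);
    ``labels`` may be soft, in [0, 1]. The result is >= 0 and minimized when
    predictions equal labels.
    """
    p = np.clip(np.asarray(predictions, dtype=np.float64), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=np.float64)
    bce = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    l2 = alpha * sum(float(np.sum(np.square(w))) for w in weights)
    return float(bce + l2)


def lr_at_epoch(initial: float, decay: float, period: int, epoch: int) -> float:
    """Piecewise-constant geometric decay: ``initial * decay ** (epoch // period)``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return initial * decay ** (epoch // period)


def _cutmix_batch(xb: np.ndarray, yb: np.ndarray, rng: np.random.Generator):
    """CutMix every element of the batch against a random permutation partner.

    The box spans all channels (and the full depth extent in 3D); labels mix
    in proportion to retained in-plane area.
    """
    h, w = xb.shape[-2:]
    partners = rng.permutation(len(xb))
    x_out, y_out = xb.copy(), yb.astype(np.float64).copy()
    for i, j in enumerate(partners):
        i0, i1, j0, j1 = sample_cut_box((h, w), rng)
        x_out[i, ..., i0:i1, j0:j1] = xb[j, ..., i0:i1, j0:j1]
        lam = 1.0 - (i1 - i0) * (j1 - j0) / (h * w)
        y_out[i] = lam * yb[i] + (1.0 - lam) * yb[j]
    return x_out, y_out


def train_network(net: Module, x: np.ndarray, y: np.ndarray, config: TrainConfig,
                  rng: np.random.Generator | None = None):
    """Train a branch network with SGD + momentum; returns per-epoch history.

    ``x`` is in network layout — ``(N, 3, 32, 32)`` for 2D, ``(N, 1, 7, 32,
    32)`` for 3D. Fully reproducible for a fixed config/seed. Raises
    ``RuntimeError`` on divergence (non-finite loss).
    """
    if len(x) == 0:
        raise ValueError("training set is empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    params = list(net.parameters())
    velocity = [np.zeros_like(p.value) for p in params]
    history = []
    for epoch in range(config.epochs):
        lr = lr_at_epoch(config.initial_lr, config.decay_rate,
                         config.decay_period_epochs, epoch)
        net.set_training(True)
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            if len(idx) >= 2 and rng.random() < config.cutmix_prob:
                xb, yb = _cutmix_batch(xb, yb, rng)
            net.zero_grad()
            logit, _ = net.forward(xb)
            p = sigmoid(logit)
            loss = bce_l2_loss(p, yb, (q.value for q in params if q.decay),
                               config.alpha_l2)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss!r}"
                )
            grad_logit = (np.clip(p, EPS, 1 - EPS) - yb) / len(yb)
            net.backward(grad_logit)
            for param, vel in zip(params, velocity):
                if param.decay:
                    param.grad += 2.0 * config.alpha_l2 * param.value
                vel *= config.momentum
                vel -= lr * param.grad
                param.value += vel
            losses.append(loss)
        history.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})
    net.set_training(False)
    return history
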