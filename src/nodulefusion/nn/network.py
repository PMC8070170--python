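"""Assembly of the 2D and 3D branch networks.

Each branch is: stem Conv+BN+ReLU, max pooling, three attention residual
blocks in series (the last always emits 256 channels so the pooled feature
vector has length 256), adaptive (global) average pooling, and a single-logit
fully-connected head for the binary decision. The pooled 256-vector is the
feature representation later fused across branches.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .blocks import AttentionResidualBlock
from .layers import (
    BatchNorm,
    Conv,
    GlobalAvgPool,
    Linear,
    MaxPool,
    Module,
    ReLU,
    kaiming_normal_,
)

__all__ = ["BranchNetwork", "build_network", "kaiming_init", "save_checkpoint", "load_checkpoint"]

FEATURE_DIM = 256


class BranchNetwork(Module):
    """One branch (2D or 3D): forward returns ``(logits, feature_vectors)``."""

    def __init__(self, dim: int = 2, in_channels: int | None = None,
                 channels: tuple[int, int, int] = (64, 128, 256), kernel_size: int = 3):
        super().__init__()
        if dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {dim}")
        if channels[-1] != FEATURE_DIM:
            raise ValueError(f"last block must emit {FEATURE_DIM} channels for fusion")
        self.dim = dim
        self.channels = tuple(channels)
        self.in_channels = in_channels if in_channels is not None else (3 if dim == 2 else 1)
        self.kernel_size = kernel_size
        c0, c1, c2 = channels
        self.stem_conv = Conv(self.in_channels, c0, kernel_size, dim, stride=1, bias=False)
        self.stem_bn = BatchNorm(c0)
        self.stem_relu = ReLU()
        self.pool = MaxPool((2, 2) if dim == 2 else (2, 2, 2))
        self.block1 = AttentionResidualBlock(c0, c0, kernel_size, dim, stride=1)
        self.block2 = AttentionResidualBlock(c0, c1, kernel_size, dim, stride=2)
        self.block3 = AttentionResidualBlock(c1, c2, kernel_size, dim, stride=2)
        self.gap = GlobalAvgPool()
        self.fc = Linear(c2, 1)

    def forward(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != self.dim + 2:
            raise ValueError(
                f"{self.dim}D network expects (N, C{', D' if self.dim == 3 else ''}, H, W) input"
            )
        h = self.pool(self.stem_relu(self.stem_bn(self.stem_conv(x))))
        h = self.block3(self.block2(self.block1(h)))
        feat = self.gap(h)
        logit = self.fc(feat)[:, 0]
        return logit, feat

    def backward(self, grad_logit, grad_feat=None):
        g = self.fc.backward(np.asarray(grad_logit)[:, None])
        if grad_feat is not None:
            g = g + grad_feat
        g = self.gap.backward(g)
        g = self.block1.backward(self.block2.backward(self.block3.backward(g)))
        g = self.pool.backward(g)
        return self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))

    def features(self, x, batch_size: int = 64) -> np.ndarray:
        """Deterministic inference-mode 256-dim feature vectors."""
        self.set_training(False)
        feats = [self.forward(x[i : i + batch_size])[1] for i in range(0, len(x), batch_size)]
        return np.concatenate(feats) if feats else np.zeros((0, self.channels[-1]))

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        self.set_training(False)
        out = []
        for i in range(0, len(x), batch_size):
            logit, _ = self.forward(x[i : i + batch_size])
            out.append(1.0 / (1.0 + np.exp(-logit)))
        return np.concatenate(out) if out else np.zeros(0)


def build_network(dim: int, channels=(64, 128, 256), kernel_size: int = 3,
                  in_channels: int | None = None) -> BranchNetwork:
    """Build the 2D (3x32x32 input) or 3D (1x7x32x32 input) branch network."""
    return BranchNetwork(dim=dim, in_channels=in_channels, channels=channels,
                         kernel_size=kernel_size)


def kaiming_init(net: Module, rng: np.random.Generator) -> Module:
    """He-initialize all conv/linear weights; BN scale 1, shift 0; biases 0."""
    for module in _walk(net):
        if isinstance(module, (Conv, Linear)):
            kaiming_normal_(module.weight, module.fan_in, rng)
            if module.bias is not None:
                module.bias.value[...] = 0.0
        elif isinstance(module, BatchNorm):
            module.gamma.value[...] = 1.0
            module.beta.value[...] = 0.0
    return net


def _walk(module: Module):
    yield module
    for child in module._children:
        yield from _walk(child)


def _state_arrays(net: BranchNetwork):
    arrays = {}
    for i, p in enumerate(net.parameters()):
        arrays[f"param_{i:03d}"] = p.value
    for j, m in enumerate(_walk(net)):
        if isinstance(m, BatchNorm):
            arrays[f"bn_{j:03d}_mean"] = m.running_mean
            arrays[f"bn_{j:03d}_var"] = m.running_var
    return arrays


def save_checkpoint(net: BranchNetwork, path) -> Path:
    """Serialize weights + architecture config to a single ``.npz``."""
    path = Path(path)
    cfg = {
        "dim": net.dim,
        "in_channels": net.in_channels,
        "channels": list(net.channels),
        "kernel_size": net.kernel_size,
    }
    np.savez_compressed(path, config=json.dumps(cfg), **_state_arrays(net))
    return path


def load_checkpoint(path) -> BranchNetwork:
    with np.load(Path(path), allow_pickle=False) as z:
        cfg = json.loads(str(z["config"]))
        net = BranchNetwork(
            dim=cfg["dim"], in_channels=cfg["in_channels"],
            channels=tuple(cfg["channels"]), kernel_size=cfg["kernel_size"],
        )
        for i, p in enumerate(net.parameters()):
            p.value[...] = z[f"param_{i:03d}"]
        for j, m in enumerate(_walk(net)):
            if isinstance(m, BatchNorm):
                m.running_mean[...] = z[f"bn_{j:03d}_mean"]
                m.running_var[...] = z[f"bn_{j:03d}_var"]
    net.set_training(False)
    return net
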