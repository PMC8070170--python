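"""Average-Max attention residual learning block.

The block has three paths:

* **convolution transform** — Conv(ks)+BN+ReLU, Conv(ks)+BN producing the
  feature map ``X_F``;
* **channel attention** — per-channel global max and mean of ``X_F`` are each
  passed through a learned 1x1 convolution (a linear map over channels) with
  ReLU; the sum of the two outputs is the non-negative per-channel weight
  vector that rescales ``X_F``;
* **direct connection** — Conv(1)+BN on the block input, carrying the stride
  so spatial sizes match.

The block output is ``direct(x) + weights * X_F`` with no activation after
the addition.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Conv, Linear, Module, ReLU

__all__ = ["AttentionResidualBlock", "channel_attention_weights"]


class AttentionResidualBlock(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 dim: int = 2, stride: int = 1):
        super().__init__()
        self.dim = dim
        self.out_channels = out_channels
        self.conv1 = Conv(in_channels, out_channels, kernel_size, dim, stride=stride, bias=False)
        self.bn1 = BatchNorm(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv(out_channels, out_channels, kernel_size, dim, stride=1, bias=False)
        self.bn2 = BatchNorm(out_channels)
        # 1x1 convolutions on the pooled C-vectors == linear maps over channels.
        self.f_m = Linear(out_channels, out_channels)
        self.f_a = Linear(out_channels, out_channels)
        self.relu_m = ReLU()
        self.relu_a = ReLU()
        self.direct_conv = Conv(in_channels, out_channels, 1, dim, stride=stride, bias=False)
        self.direct_bn = BatchNorm(out_channels)
        self._cache = None

    # -- attention -----------------------------------------------------------
    def attention_weights(self, x_f: np.ndarray) -> np.ndarray:
        """Per-channel weights f_m[max(X_F)] + f_a[avg(X_F)]; always >= 0."""
        if x_f.shape[1] != self.out_channels:
            raise ValueError(
                f"expected {self.out_channels} channels, got {x_f.shape[1]}"
            )
        axes = tuple(range(2, x_f.ndim))
        m = x_f.max(axis=axes)
        a = x_f.mean(axis=axes)
        return self.relu_m(self.f_m(m)) + self.relu_a(self.f_a(a))

    # -- forward / backward --------------------------------------------------
    def forward(self, x):
        x_f = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        axes = tuple(range(2, x_f.ndim))
        n, c = x_f.shape[:2]
        flat = x_f.reshape(n, c, -1)
        argmax = flat.argmax(axis=-1)
        m = np.take_along_axis(flat, argmax[..., None], axis=-1)[..., 0]
        a = x_f.mean(axis=axes)
        w = self.relu_m(self.f_m(m)) + self.relu_a(self.f_a(a))
        d = self.direct_bn(self.direct_conv(x))
        bshape = (n, c) + (1,) * (x_f.ndim - 2)
        y = d + w.reshape(bshape) * x_f
        self._cache = (x_f, w, argmax, bshape)
        return y

    def backward(self, grad):
        x_f, w, argmax, bshape = self._cache
        n, c = x_f.shape[:2]
        p = int(np.prod(x_f.shape[2:]))
        # direct-connection path
        gx = self.direct_conv.backward(self.direct_bn.backward(grad))
        # attention-scaled feature map
        g_xf = grad * w.reshape(bshape)
        g_w = (grad * x_f).reshape(n, c, -1).sum(axis=-1)
        g_m = self.f_m.backward(self.relu_m.backward(g_w))
        g_a = self.f_a.backward(self.relu_a.backward(g_w))
        # scatter the max-path gradient to the argmax voxels, spread the
        # mean-path gradient uniformly
        g_from_max = np.zeros((n, c, p))
        np.put_along_axis(g_from_max, argmax[..., None], g_m[..., None], axis=-1)
        g_xf = g_xf + g_from_max.reshape(x_f.shape) + (g_a / p).reshape(bshape)
        gx += self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g_xf))))
        )
        return gx


def channel_attention_weights(x_f: np.ndarray, block: AttentionResidualBlock) -> np.ndarray:
    """Functional form of the block's channel-attention weights."""
    return block.attention_weights(np.asarray(x_f, dtype=np.float64))
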