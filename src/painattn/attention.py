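"""Channel and spatial attention blocks (CBAM-style).

Channel attention squeezes each channel plane to two scalar descriptors
(global average and global max), pushes both through a shared two-layer
bottleneck MLP, sums the paths and applies a sigmoid, yielding one gate in
(0, 1) per channel.  Spatial attention stacks the channel-wise mean and max
planes and convolves them with a single kxk filter (sigmoid output),
yielding one gate per pixel.  Both the gates and the reweighted feature map
are returned: the gates themselves drive the downstream core-region
selection and background shielding.
"""

from __future__ import annotations

import numpy as np

from .nn.autograd import Tensor, as_tensor, concat, conv2d
from .nn.layers import Module

__all__ = ["ChannelAttention", "SpatialAttention", "AttentionBlock",
           "channel_attention", "spatial_attention", "compose_attention",
           "ATTENTION_ORDERS"]

ATTENTION_ORDERS = ("ca", "sa", "ca_sa", "sa_ca")


class ChannelAttention(Module):
    """Per-channel gating from pooled descriptors through a shared bottleneck."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        if reduction >= channels and channels > 1:
            raise ValueError(
                f"reduction ratio ({reduction}) must be < channel count ({channels})"
            )
        rng = rng or np.random.default_rng()
        hidden = max(channels // reduction, 1)
        self.w1 = Tensor(rng.normal(0, np.sqrt(2.0 / channels), (channels, hidden)),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(rng.normal(0, np.sqrt(2.0 / hidden), (hidden, channels)),
                         requires_grad=True)
        self.b2 = Tensor(np.zeros(channels), requires_grad=True)

    def _mlp(self, v: Tensor) -> Tensor:
        return (v @ self.w1 + self.b1).relu() @ self.w2 + self.b2

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (weights (N, C), reweighted map (N, C, H, W))."""
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=3).max(axis=2)
        weights = (self._mlp(avg) + self._mlp(mx)).sigmoid()
        n, c = weights.shape
        out = x * weights.reshape(n, c, 1, 1)
        return weights, out


class SpatialAttention(Module):
    """Per-pixel gating from the [channel-mean, channel-max] two-plane stack."""

    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        if kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        rng = rng or np.random.default_rng()
        fan_in = 2 * kernel_size * kernel_size
        self.weight = Tensor(
            rng.normal(0, np.sqrt(2.0 / fan_in), (1, 2, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(1), requires_grad=True)
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (weights (N, H, W), reweighted map (N, C, H, W))."""
        n, c, h, w = x.shape
        mean_plane = x.mean(axis=1, keepdims=True)
        max_plane = x.max(axis=1, keepdims=True)
        stack = concat([mean_plane, max_plane], axis=1)
        logits = conv2d(stack, self.weight, self.bias,
                        padding=self.kernel_size // 2)
        weights = logits.sigmoid().reshape(n, h, w)
        out = x * weights.reshape(n, 1, h, w)
        return weights, out


def channel_attention(fmap, module: ChannelAttention):
    """Functional wrapper accepting (C,H,W) or (N,C,H,W) arrays or Tensors."""
    x, squeeze, is_tensor = _coerce(fmap)
    weights, out = module(x)
    if squeeze:
        weights, out = weights.reshape(*weights.shape[1:]), out.reshape(*out.shape[1:])
    return (weights, out) if is_tensor else (weights.data, out.data)


def spatial_attention(fmap, module: SpatialAttention):
    x, squeeze, is_tensor = _coerce(fmap)
    weights, out = module(x)
    if squeeze:
        weights, out = weights.reshape(*weights.shape[1:]), out.reshape(*out.shape[1:])
    return (weights, out) if is_tensor else (weights.data, out.data)


def _coerce(fmap):
    is_tensor = isinstance(fmap, Tensor)
    x = fmap if is_tensor else as_tensor(np.asarray(fmap, dtype=np.float64))
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape(1, *x.shape)
    return x, squeeze, is_tensor


class AttentionBlock(Module):
    """Serial composition of CA and SA in a configurable order.

    The most recent channel weights (N, C) and spatial weights (N, H, W)
    are captured on ``self.channel_weights`` / ``self.spatial_weights``
    after each forward, for consumption by the regional-masking stage.
    """

    def __init__(self, channels: int, order: str = "ca_sa", reduction: int = 16,
                 spatial_kernel: int = 7, rng: np.random.Generator | None = None):
        if order not in ATTENTION_ORDERS:
            raise ValueError(f"order must be one of {ATTENTION_ORDERS}, got {order!r}")
        rng = rng or np.random.default_rng()
        self.order = order
        self.ca = ChannelAttention(channels, reduction, rng) if "ca" in order else None
        self.sa = SpatialAttention(spatial_kernel, rng) if "sa" in order else None
        self.channel_weights: np.ndarray | None = None
        self.spatial_weights: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        self.channel_weights = None
        self.spatial_weights = None
        for token in self.order.split("_"):
            if token == "ca":
                w, x = self.ca(x)
                self.channel_weights = w.data
            else:
                w, x = self.sa(x)
                self.spatial_weights = w.data
        return x


def compose_attention(fmap, block: AttentionBlock):
    """Apply a CA/SA composition; returns (output, channel_w, spatial_w).

    Weight arrays are None for orders that omit the corresponding module.
    """
    x, squeeze, is_tensor = _coerce(fmap)
    out = block(x)
    cw, sw = block.channel_weights, block.spatial_weights
    if squeeze:
        out = out.reshape(*out.shape[1:])
        cw = None if cw is None else cw[0]
        sw = None if sw is None else sw[0]
    return (out if is_tensor else out.data), cw, sw
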