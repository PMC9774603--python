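"""Anti-aliased downsampling (MaxBlurPool).

Plain strided max pooling ignores the sampling theorem: a one-pixel input
shift can flip which values land on the sampling grid, so downstream
features (and ultimately class scores) jitter under translation.  BlurPool
decomposes pooling into (1) dense max pooling at stride 1, (2) a low-pass
binomial blur, and (3) subsampling, which strongly attenuates the aliased
high frequencies and makes the network far more shift-consistent.
"""

from __future__ import annotations

from math import comb

import numpy as np

from .nn.autograd import Tensor, as_tensor, depthwise_blur, pad_reflect, subsample
from .nn.layers import Module

__all__ = ["blur_kernel", "blur_downsample", "BlurPool"]

_SUPPORTED_SIZES = (2, 3, 5)


def blur_kernel(size: int = 3) -> np.ndarray:
    """Separable binomial blur kernel, normalized to unit sum (DC gain 1)."""
    if size not in _SUPPORTED_SIZES:
        raise ValueError(f"kernel size must be one of {_SUPPORTED_SIZES}, got {size}")
    row = np.array([float(comb(size - 1, k)) for k in range(size)])
    k2 = np.outer(row, row)
    return k2 / k2.sum()


def _validate_kernel(kernel: np.ndarray) -> np.ndarray:
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError(f"blur kernel must be square 2-D, got shape {kernel.shape}")
    if np.any(kernel < 0):
        raise ValueError("blur kernel coefficients must be nonnegative")
    if not np.isclose(kernel.sum(), 1.0, atol=1e-9):
        raise ValueError(f"blur kernel must sum to 1, sums to {kernel.sum():.6g}")
    return kernel


def blur_downsample(fmap, kernel: np.ndarray | None = None, stride: int = 2):
    """Dense max pool, binomial blur, then subsample by ``stride``.

    Accepts a numpy array (C, H, W) or (N, C, H, W) — or a Tensor — and
    returns the same kind.  Output spatial size is ceil(H/stride) x
    ceil(W/stride); reflect padding keeps the unit DC gain at borders.
    """
    if stride < 2:
        raise ValueError(f"stride must be >= 2, got {stride}")
    kernel = _validate_kernel(blur_kernel() if kernel is None else kernel)
    is_tensor = isinstance(fmap, Tensor)
    x = fmap if is_tensor else as_tensor(np.asarray(fmap, dtype=np.float64))
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape(1, *x.shape)
    if x.ndim != 4:
        raise ValueError(f"expected (C,H,W) or (N,C,H,W), got shape {x.shape}")
    out = _max_blur_pool(x, kernel, stride)
    if squeeze:
        out = out.reshape(*out.shape[1:])
    return out if is_tensor else out.data


def _max_blur_pool(x: Tensor, kernel: np.ndarray, stride: int) -> Tensor:
    from .nn.autograd import maxpool2d

    # dense (stride-1) 2x2 max pool at constant size: pad one row/col at the
    # far edge by reflection, so the pooled map stays H x W
    xp = _pad_edge_max(x)
    pooled = maxpool2d(xp, kernel=2, stride=1)
    pad = kernel.shape[0] // 2
    if pad:
        pooled = pad_reflect(pooled, pad)
    blurred = depthwise_blur(pooled, kernel)
    return subsample(blurred, stride)


def _pad_edge_max(x: Tensor) -> Tensor:
    # reflect-pad by 1 then crop the leading row/col, so the dense 2x2 max
    # pool keeps the H x W extent (far edge sees its reflected neighbour)
    xp = pad_reflect(x, 1)
    H, W = x.shape[-2:]

    def bwd(out):
        g = np.zeros_like(xp.data)
        g[..., 1:, 1:] = out.grad
        xp._accum(g)

    return xp._make(xp.data[..., 1:, 1:], (xp,), bwd)


class BlurPool(Module):
    """Layer form of :func:`blur_downsample` with a fixed binomial kernel."""

    def __init__(self, kernel_size: int = 3, stride: int = 2):
        if stride < 2:
            raise ValueError(f"stride must be >= 2, got {stride}")
        self.kernel = blur_kernel(kernel_size)
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return _max_blur_pool(x, self.kernel, self.stride)
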