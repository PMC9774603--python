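"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the pain-estimation networks need:
broadcast arithmetic, matmul, 2-D convolution (im2col), max/avg pooling,
strided subsampling, reflect padding, depthwise blur convolution, sigmoid /
ReLU, reductions, signed square root and L2 normalisation.  Gradients are
accumulated on a dynamically built tape and released after ``backward``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph construction --------------------------------------------------
    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        out = Tensor(data)
        live = tuple(p for p in parents if p.requires_grad)
        if live:
            out.requires_grad = True
            out._parents = live
            out._backward = backward and (lambda: backward(out))
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
                node._backward = None  # release closures promptly

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(out):
            self.requires_grad and self._accum(_unbroadcast(out.grad, self.shape))
            other.requires_grad and other._accum(_unbroadcast(out.grad, other.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        return self._make(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(out):
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        return self._make(self.data @ other.data, (self, other), bwd)

    def __pow__(self, exponent: float):
        def bwd(out):
            self._accum(out.grad * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), bwd)

    # -- shape ops -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(out):
            self._accum(out.grad.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bwd(out):
            self._accum(out.grad.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)

    # -- reductions --------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(out):
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient flows to the (first) argmax entries."""
        idx = np.argmax(self.data, axis=axis)

        def bwd(out):
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            mask = np.zeros_like(self.data)
            np.put_along_axis(mask, np.expand_dims(idx, axis), 1.0, axis=axis)
            self._accum(mask * g)

        return self._make(self.data.max(axis=axis, keepdims=keepdims), (self,), bwd)

    # -- nonlinearities -----------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(out):
            self._accum(out.grad * mask)

        return self._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(out):
            self._accum(out.grad * s * (1.0 - s))

        return self._make(s, (self,), bwd)

    def exp(self):
        e = np.exp(self.data)

        def bwd(out):
            self._accum(out.grad * e)

        return self._make(e, (self,), bwd)

    def log(self):
        def bwd(out):
            self._accum(out.grad / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def signed_sqrt(self, eps: float = 1e-12):
        """sign(x) * sqrt(|x|), with a clipped derivative near zero."""
        y = np.sign(self.data) * np.sqrt(np.abs(self.data))

        def bwd(out):
            self._accum(out.grad * 0.5 / np.sqrt(np.abs(self.data) + eps))

        return self._make(y, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Functional ops on NCHW feature maps


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(out):
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t._accum(g)

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return tensors[0]._make(data, tensors, bwd)


def pad_zero(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the two trailing (spatial) axes."""
    if pad == 0:
        return x
    width = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]

    def bwd(out):
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        x._accum(out.grad[sl])

    return x._make(np.pad(x.data, width), (x,), bwd)


def pad_reflect(x: Tensor, pad: int) -> Tensor:
    """Reflect-pad the two trailing axes (gradient scatter-adds back)."""
    if pad == 0:
        return x
    H, W = x.shape[-2:]
    ih = _reflect_index(H, pad)
    iw = _reflect_index(W, pad)

    def bwd(out):
        g = np.zeros_like(x.data)
        # accumulate along rows then columns to handle duplicated indices
        tmp = np.zeros(x.shape[:-2] + (H, W + 2 * pad))
        np.add.at(tmp, (Ellipsis, ih, slice(None)), out.grad)
        np.add.at(g, (Ellipsis, slice(None), iw), tmp)
        x._accum(g)

    data = x.data[(Ellipsis, ih, slice(None))][(Ellipsis, slice(None), iw)]
    return x._make(data, (x,), bwd)


def _reflect_index(n: int, pad: int) -> np.ndarray:
    idx = np.arange(-pad, n + pad)
    return np.abs(idx) * (idx < 0) + idx * (idx >= 0) * (idx < n) + \
        (2 * n - 2 - idx) * (idx >= n)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW x OIkk -> NOHW."""
    xp = pad_zero(x, padding)
    N, C, H, W = xp.shape
    O, I, kh, kw = weight.shape
    if I != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {I}")
    Ho, Wo = H - kh + 1, W - kw + 1
    cols = np.lib.stride_tricks.sliding_window_view(xp.data, (kh, kw), axis=(2, 3))
    # cols: (N, C, Ho, Wo, kh, kw) -> (N*Ho*Wo, C*kh*kw)
    cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(O, C * kh * kw)
    out_data = (cols2 @ wmat.T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)

    parents = (xp, weight) + ((bias,) if bias is not None else ())

    def bwd(out):
        gout = out.grad.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
        if weight.requires_grad:
            weight._accum((gout.T @ cols2).reshape(O, C, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accum(out.grad.sum(axis=(0, 2, 3)))
        if xp.requires_grad:
            gcols = (gout @ wmat).reshape(N, Ho, Wo, C, kh, kw)
            gx = np.zeros((N, C, H, W))
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + Ho, j:j + Wo] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            xp._accum(gx)

    return x._make(out_data, parents, bwd)


def depthwise_blur(x: Tensor, kernel: np.ndarray) -> Tensor:
    """Per-channel valid correlation with a fixed (non-learned) 2-D kernel."""
    kh, kw = kernel.shape
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    out_data = np.einsum("nchwij,ij->nchw", win, kernel)

    def bwd(out):
        gp = np.pad(out.grad, [(0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)])
        gwin = np.lib.stride_tricks.sliding_window_view(gp, (kh, kw), axis=(2, 3))
        x._accum(np.einsum("nchwij,ij->nchw", gwin, kernel[::-1, ::-1]))

    return x._make(out_data, (x,), bwd)


def maxpool2d(x: Tensor, kernel: int, stride: int) -> Tensor:
    """Max pooling over NCHW; gradient routes to the first argmax per window."""
    N, C, H, W = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(N, C, Ho, Wo, kernel * kernel)
    arg = np.argmax(flat, axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bwd(out):
        gx = np.zeros_like(x.data)
        ki, kj = np.divmod(arg, kernel)
        oi = np.arange(Ho)[:, None] * stride
        oj = np.arange(Wo)[None, :] * stride
        rows = (oi[None, None] + ki).ravel()
        cols = (oj[None, None] + kj).ravel()
        nn = np.repeat(np.arange(N), C * Ho * Wo)
        cc = np.tile(np.repeat(np.arange(C), Ho * Wo), N)
        np.add.at(gx, (nn, cc, rows, cols), out.grad.ravel())
        x._accum(gx)

    return x._make(out_data, (x,), bwd)


def subsample(x: Tensor, stride: int) -> Tensor:
    """Keep every ``stride``-th pixel starting at (0, 0)."""
    def bwd(out):
        g = np.zeros_like(x.data)
        g[..., ::stride, ::stride] = out.grad
        x._accum(g)

    return x._make(np.ascontiguousarray(x.data[..., ::stride, ::stride]), (x,), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    soft = np.exp(out_data)

    def bwd(out):
        x._accum(out.grad - soft * out.grad.sum(axis=axis, keepdims=True))

    return x._make(out_data, (x,), bwd)


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    # eps inside the sqrt keeps the gradient finite on the all-zero vector
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps**2) ** 0.5
    return x / norm
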