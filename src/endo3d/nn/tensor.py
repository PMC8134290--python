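"""A small reverse-mode autodiff engine on numpy arrays.

Only the operations the package's networks need are provided: elementwise
arithmetic, a handful of activations, reductions, channel concatenation,
2-D (transposed) convolution via im2col, nearest-neighbour upsampling and
instance normalization.  Arrays are float32 NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        o = self._wrap(other)
        out_data = self.data + o.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))

        return self._make(out_data, (self, o), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        out_data = self.data * o.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))

        return self._make(out_data, (self, o), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        out_data = self.data / o.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data**2), o.data.shape))

        return self._make(out_data, (self, o), back)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def pow(self, exponent: float):
        out_data = self.data**exponent

        def back(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), back)

    def sqrt(self):
        return self.pow(0.5)

    def abs(self):
        out_data = np.abs(self.data)
        sign = np.sign(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(out_data, (self,), back)

    # -- reductions -----------------------------------------------------
    def mean(self):
        n = self.data.size
        out_data = self.data.mean()

        def back(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g / n))

        return self._make(out_data, (self,), back)

    def sum(self):
        out_data = self.data.sum()

        def back(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g))

        return self._make(out_data, (self,), back)

    # -- activations ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(out_data, (self,), back)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope).astype(np.float32))

        return self._make(out_data, (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), back)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), back)

    # -- shape ops ------------------------------------------------------
    def upsample_nearest(self, scale: int = 2):
        """Nearest-neighbour upsampling of an NCHW tensor."""
        out_data = self.data.repeat(scale, axis=2).repeat(scale, axis=3)

        def back(g):
            if self.requires_grad:
                N, C, H, W = self.data.shape
                gr = g.reshape(N, C, H, scale, W, scale).sum(axis=(3, 5))
                self._accum(gr)

        return self._make(out_data, (self,), back)

    # -- convolution ----------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None", stride: int = 1,
               padding: int = 0):
        y, cols = _conv_fwd(self.data, weight.data, stride, padding)
        if bias is not None:
            y = y + bias.data.reshape(1, -1, 1, 1)
        parents = (self, weight) + ((bias,) if bias is not None else ())

        def back(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                weight._accum(_conv_dw(cols, g, weight.data.shape))
            if self.requires_grad:
                self._accum(_conv_dx(g, weight.data, self.data.shape, stride, padding))

        return self._make(y, parents, back)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None",
                         stride: int = 2, padding: int = 1):
        """Fractionally-strided convolution; weight shape (Cin, Cout, kh, kw)."""
        Cin, Cout, kh, kw = weight.data.shape
        N, C, h, w = self.data.shape
        H = (h - 1) * stride + kh - 2 * padding
        W = (w - 1) * stride + kw - 2 * padding
        y = _conv_dx(self.data, weight.data, (N, Cout, H, W), stride, padding)
        if bias is not None:
            y = y + bias.data.reshape(1, -1, 1, 1)
        parents = (self, weight) + ((bias,) if bias is not None else ())

        def back(g):
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad or self.requires_grad:
                gx, cols_g = _conv_fwd(g, weight.data, stride, padding)
                if weight.requires_grad:
                    weight._accum(_conv_dw(cols_g, self.data, weight.data.shape))
                if self.requires_grad:
                    self._accum(gx)

        return self._make(y, parents, back)

    def instance_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        x = self.data
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        std = np.sqrt(var + eps)
        xhat = (x - mu) / std
        y = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
        M = x.shape[2] * x.shape[3]

        def back(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dxhat = g * gamma.data.reshape(1, -1, 1, 1)
                dvar = (dxhat * (x - mu) * -0.5 * (var + eps) ** -1.5).sum(
                    axis=(2, 3), keepdims=True
                )
                dmu = (-dxhat / std).sum(axis=(2, 3), keepdims=True) + dvar * (
                    -2.0 * (x - mu)
                ).mean(axis=(2, 3), keepdims=True)
                dx = dxhat / std + dvar * 2.0 * (x - mu) / M + dmu / M
                self._accum(dx.astype(np.float32))

        return self._make(y, (self, gamma, beta), back)

    # -- autodiff driver ------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free graph references as we go
                node._backward = None
                node._parents = ()


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def back(g):
            for t, gs in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(gs)

        out._backward = back
    return out


# ----------------------------------------------------------------------
# Convolution primitives (im2col / col2im)
# ----------------------------------------------------------------------

def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    """y = conv(x, w); returns (y, im2col matrix) for the weight gradient."""
    F, C, kh, kw = w.shape
    N = x.shape[0]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    N_, C_, Ho, Wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw
    )
    y = cols @ w.reshape(F, -1).T
    return (
        y.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2).astype(np.float32),
        cols,
    )


def _conv_dw(cols: np.ndarray, dy: np.ndarray, w_shape: tuple) -> np.ndarray:
    F = w_shape[0]
    dyc = dy.transpose(0, 2, 3, 1).reshape(-1, F)
    return (dyc.T @ cols).reshape(w_shape).astype(np.float32)


def _conv_dx(
    dy: np.ndarray, w: np.ndarray, x_shape: tuple, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of _conv_fwd w.r.t. its input (also conv_transpose forward)."""
    F, C, kh, kw = w.shape
    N, _, H, W = x_shape
    _, _, Ho, Wo = dy.shape
    dcols = dy.transpose(0, 2, 3, 1).reshape(-1, F) @ w.reshape(F, -1)
    d6 = dcols.reshape(N, Ho, Wo, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += d6[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp
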