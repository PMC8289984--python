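"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This engine provides exactly the operations the adversarial autoencoder
networks need: dense and convolutional linear maps, leaky-ReLU and tanh
nonlinearities, nearest-neighbor upsampling, 2x2 average pooling, elementwise
arithmetic, reductions, and a numerically stable binary cross-entropy on
logits.  Gradients flow through a dynamically recorded graph; ``backward`` on
a scalar tensor performs a topological sweep and accumulates gradients into
``Tensor.grad``.

Arrays follow the NCHW layout for image-shaped data.  Convolutions are
stride-1 with symmetric zero padding; the input gradient of a convolution is
itself a convolution with the spatially flipped, channel-transposed kernel,
so a single raw correlation routine serves both directions.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """Column buffer (C, kh*kw, N, H', W') in channels-leading layout."""
    n, c, h, w = x.shape
    hp, wp = h + 2 * pad, w + 2 * pad
    xt = np.zeros((c, n, hp, wp), dtype=x.dtype)
    xt[:, :, pad:pad + h, pad:pad + w] = x.transpose(1, 0, 2, 3)
    h_out, w_out = hp - kh + 1, wp - kw + 1
    cols = np.empty((c, kh * kw, n, h_out, w_out), dtype=x.dtype)
    for u in range(kh):
        for v in range(kw):
            cols[:, u * kw + v] = xt[:, :, u:u + h_out, v:v + w_out]
    return cols


def _cols_gemm(cols: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(O, C*kh*kw) x column buffer -> (N, O, H', W')."""
    o = w.shape[0]
    _, _, n, h_out, w_out = cols.shape
    out = w.reshape(o, -1) @ cols.reshape(-1, n * h_out * w_out)
    return np.ascontiguousarray(
        out.reshape(o, n, h_out, w_out).transpose(1, 0, 2, 3))


def _correlate2d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 cross-correlation: x (N,C,H,W) with w (O,C,kh,kw) -> (N,O,H',W')."""
    if w.shape[2] == 1 and w.shape[3] == 1 and not pad:
        out = np.tensordot(w[:, :, 0, 0], x, axes=([1], [1]))
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3))
    return _cols_gemm(_im2col(x, w.shape[2], w.shape[3], pad), w)


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- basic properties ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data + other.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        data = self.data * other.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        data = self.data @ other.data

        def backward(g: np.ndarray) -> None:
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor._make(data, (self, other), backward)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------------

    @staticmethod
    def cat(tensors: "Sequence[Tensor]") -> "Tensor":
        """Concatenate along the leading (batch) axis."""
        tensors = list(tensors)
        data = np.concatenate([t.data for t in tensors], axis=0)
        sizes = [t.data.shape[0] for t in tensors]

        def backward(g: np.ndarray) -> None:
            offset = 0
            for t, size in zip(tensors, sizes):
                t._accumulate(g[offset:offset + size])
                offset += size

        return Tensor._make(data, tensors, backward)

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape
        data = self.data.reshape(shape)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.reshape(orig))

        return Tensor._make(data, (self,), backward)

    # -- nonlinearities ----------------------------------------------------------

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data >= 0
        scale = np.where(mask, 1.0, slope).astype(self.data.dtype)
        data = self.data * scale

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * scale)

        return Tensor._make(data, (self,), backward)

    def tanh(self) -> "Tensor":
        data = np.tanh(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * (1.0 - data * data))

        return Tensor._make(data, (self,), backward)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data).astype(self.data.dtype)
        data = np.abs(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * sign)

        return Tensor._make(data, (self,), backward)

    # -- reductions ----------------------------------------------------------------

    def sum(self) -> "Tensor":
        data = self.data.sum()

        def backward(g: np.ndarray) -> None:
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._make(np.asarray(data), (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size
        data = self.data.mean()

        def backward(g: np.ndarray) -> None:
            self._accumulate(np.broadcast_to(g / n, self.data.shape))

        return Tensor._make(np.asarray(data), (self,), backward)

    # -- image ops ------------------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               pad: int = 0) -> "Tensor":
        """Stride-1 2-D convolution (cross-correlation), NCHW x OIHW."""
        x, w = self.data, weight.data
        if x.ndim != 4 or w.ndim != 4 or x.shape[1] != w.shape[1]:
            raise ValueError(
                f"conv2d shape mismatch: input {x.shape}, weight {w.shape}")
        kh, kw = w.shape[2], w.shape[3]
        is_1x1 = kh == 1 and kw == 1 and not pad
        if is_1x1:
            cols = None
            out = np.ascontiguousarray(
                np.tensordot(w[:, :, 0, 0], x,
                             axes=([1], [1])).transpose(1, 0, 2, 3))
        else:
            cols = _im2col(x, kh, kw, pad)  # cached for the weight gradient
            out = _cols_gemm(cols, w)
        if bias is not None:
            out = out + bias.data.reshape(1, -1, 1, 1)
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g: np.ndarray) -> None:
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if weight.requires_grad:
                if is_1x1:
                    gw = np.tensordot(g, x, axes=([0, 2, 3], [0, 2, 3]))
                    gw = gw[:, :, None, None]
                else:
                    gt = g.transpose(1, 0, 2, 3).reshape(g.shape[1], -1)
                    gw = (gt @ cols.reshape(cols.shape[0] * kh * kw, -1).T
                          ).reshape(g.shape[1], x.shape[1], kh, kw)
                weight._accumulate(gw)
            if self.requires_grad:
                w_rot = np.ascontiguousarray(
                    w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
                self._accumulate(_correlate2d(g, w_rot, kh - 1 - pad))

        return Tensor._make(out, parents, backward)

    def upsample2x(self) -> "Tensor":
        """Nearest-neighbor x2 upsampling of an NCHW tensor."""
        data = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g: np.ndarray) -> None:
            n, c, h, w = g.shape
            self._accumulate(
                g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))

        return Tensor._make(data, (self,), backward)

    def avgpool2x(self) -> "Tensor":
        """2x2 average pooling of an NCHW tensor."""
        n, c, h, w = self.data.shape
        data = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def backward(g: np.ndarray) -> None:
            up = g.repeat(2, axis=2).repeat(2, axis=3) * np.asarray(
                0.25, dtype=g.dtype)
            self._accumulate(up)

        return Tensor._make(data, (self,), backward)

    # -- losses ------------------------------------------------------------------------

    def bce_with_logits(self, target: float | np.ndarray) -> "Tensor":
        """Mean binary cross-entropy of logits against constant targets.

        Stable form: softplus(z) - t*z with softplus(z) = max(z,0) + log1p(exp(-|z|)).
        """
        z = self.data
        t = np.broadcast_to(np.asarray(target, dtype=z.dtype), z.shape)
        loss = np.maximum(z, 0) - t * z + np.log1p(np.exp(-np.abs(z)))
        n = z.size

        def backward(g: np.ndarray) -> None:
            # numerically stable logistic
            ez = np.exp(-np.abs(z))
            sig = np.where(z >= 0, 1.0 / (1.0 + ez), ez / (1.0 + ez))
            self._accumulate(g * (sig - t) / n)

        return Tensor._make(np.asarray(loss.mean()), (self,), backward)

    # -- backward pass -------------------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this scalar through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the graph as we go; parameters keep their grads
                node._backward = None
                node._parents = ()


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)
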