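"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` on a scalar output accumulates gradients into every upstream
tensor created with ``requires_grad=True``.  Only the operations needed by the
quantification models are implemented: broadcast arithmetic, (batched) matmul,
elementwise nonlinearities, reductions, shape manipulation, softmax, and
dedicated 1-D convolution/pooling kernels.

Gradients follow the dtype of the data; float32 is used for model training,
float64 for finite-difference verification in the test-suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "maxpool1d", "avgpool1d", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = cls(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deeper than the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            # scalar fast path: a python float promotes weakly, preserving float32
            other = float(other)

            def backward_s(g):
                self._accumulate(g)

            return Tensor._from_op(self.data + other, (self,), backward_s)
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            other = float(other)

            def backward_s(g):
                self._accumulate(g * other)

            return Tensor._from_op(self.data * other, (self,), backward_s)
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g / (2.0 * out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor._from_op(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._from_op(np.abs(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def leaky_relu(self, alpha: float = 0.01):
        mask = self.data > 0
        slope = np.where(mask, 1.0, alpha)

        def backward(g):
            self._accumulate(g * slope)

        return Tensor._from_op(self.data * slope, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)

        def backward(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, neg + alpha))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            inner = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - inner))

        return Tensor._from_op(s, (self,), backward)

    # -- shape ----------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._from_op(self.data[idx], (self,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# -- dedicated 1-D convolution / pooling kernels -------------------------------


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, L) -> (B, C, L_out, k) strided view of sliding windows."""
    w = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    return w[:, :, ::stride, :]


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1) -> Tensor:
    """Valid-mode 1-D convolution: x (B, C, L), weight (O, C, K) -> (B, O, L_out)."""
    B, C, L = x.data.shape
    O, C2, K = weight.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, weight {C2}")
    L_out = (L - K) // stride + 1
    if L_out < 1:
        raise ValueError(f"kernel {K} with stride {stride} does not fit input length {L}")
    win = _windows(x.data, K, stride)  # (B, C, L_out, K)
    out_data = np.einsum("bclk,ock->bol", win, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[:, None]

    def backward(g):
        if weight.requires_grad:
            gw = np.einsum("bol,bclk->ock", g, win, optimize=True)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            pos = stride * np.arange(L_out)
            for k in range(K):
                # each kernel tap k contributes to input positions pos + k
                contrib = np.einsum("bol,oc->bcl", g, weight.data[:, :, k], optimize=True)
                gx[:, :, pos + k] += contrib
            x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._from_op(out_data, parents, backward)


def maxpool1d(x: Tensor, size: int, stride: int | None = None) -> Tensor:
    """Max pooling over the last axis of (B, C, L)."""
    stride = stride or size
    B, C, L = x.data.shape
    L_out = (L - size) // stride + 1
    if L_out < 1:
        raise ValueError(f"pool size {size} does not fit input length {L}")
    win = _windows(x.data, size, stride)  # (B, C, L_out, size)
    arg = win.argmax(axis=3)
    out_data = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]

    def backward(g):
        gx = np.zeros_like(x.data)
        pos = stride * np.arange(L_out)[None, None, :] + arg  # (B, C, L_out) input indices
        b_idx = np.arange(B)[:, None, None]
        c_idx = np.arange(C)[None, :, None]
        np.add.at(gx, (b_idx, c_idx, pos), g)
        x._accumulate(gx)

    return Tensor._from_op(out_data, (x,), backward)


def avgpool1d(x: Tensor, size: int, stride: int | None = None) -> Tensor:
    """Average pooling over the last axis of (B, C, L)."""
    stride = stride or size
    B, C, L = x.data.shape
    L_out = (L - size) // stride + 1
    if L_out < 1:
        raise ValueError(f"pool size {size} does not fit input length {L}")
    win = _windows(x.data, size, stride)
    out_data = win.mean(axis=3)

    def backward(g):
        gx = np.zeros_like(x.data)
        pos = stride * np.arange(L_out)
        for k in range(size):
            gx[:, :, pos + k] += g / size
        x._accumulate(gx)

    return Tensor._from_op(out_data, (x,), backward)
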