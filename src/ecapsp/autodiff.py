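"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the micrograd style, but operating on whole
arrays: each :class:`Tensor` wraps an ``ndarray``, records its parents and a
closure that accumulates gradients into them, and ``backward()`` replays the
tape in reverse topological order.  Only the operations the capsule network
needs are implemented (broadcasting arithmetic, matmul, two-operand einsum,
reductions, reshaping, padding and 1-D sliding-window extraction for
convolutions).  Every op is validated against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "einsum", "unfold1d", "pad", "band_sum",
           "conv1d", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape*, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # remove leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray, fresh: bool = False) -> None:
        # ``fresh`` marks g as a newly allocated array owned by the caller,
        # which may then be adopted without a defensive copy.
        if self.grad is None:
            if fresh and g.shape == self.data.shape:
                self.grad = g
            else:
                self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                     dtype=np.result_type(self.data, g))
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; the tape can be deep
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
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
        # single-shot tape: release intermediate gradients and closures so
        # memory is reclaimed by reference counting, not the cycle collector
        for node in topo:
            if node._parents:
                node._backward = None
                node._parents = ()
                node.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g, fresh=True)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape), fresh=True)
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape), fresh=True)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0), fresh=True)
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape), fresh=True)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape), fresh=True)
        out._backward = bwd
        return out

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        # closures capture the array, not the output Tensor: a reference to
        # the Tensor would form a cycle that pins the whole tape until gc
        out = Tensor(out_data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data, fresh=True)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data, fresh=True)
        out._backward = bwd
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)
        out = Tensor(out_data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data, fresh=True)
        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0), fresh=True)
        out._backward = bwd
        return out

    # -- reductions & shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy(), fresh=True)
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, self.shape).copy(), fresh=True)
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))
        out._backward = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = bwd
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full, fresh=True)
        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def einsum(equation: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with explicit output indices (no ellipsis/traces)."""
    a, b = as_tensor(a), as_tensor(b)
    lhs, out_idx = equation.split("->")
    ia, ib = lhs.split(",")
    out = Tensor(np.einsum(equation, a.data, b.data),
                 a.requires_grad or b.requires_grad, (a, b))

    def bwd(g):
        if a.requires_grad:
            ga = np.einsum(f"{out_idx},{ib}->{ia}", g, b.data)
            a._accumulate(ga, fresh=True)
        if b.requires_grad:
            gb = np.einsum(f"{out_idx},{ia}->{ib}", g, a.data)
            b._accumulate(gb, fresh=True)
    out._backward = bwd
    return out


def pad(t: Tensor, pad_width) -> Tensor:
    """Zero-pad; *pad_width* as for ``np.pad``."""
    t = as_tensor(t)
    out = Tensor(np.pad(t.data, pad_width), t.requires_grad, (t,))
    slices = tuple(slice(p[0], p[0] + s) for p, s in zip(pad_width, t.shape))

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g[slices])
    out._backward = bwd
    return out


def unfold1d(t: Tensor, size: int, stride: int = 1) -> Tensor:
    """Sliding windows along axis 1 of a (batch, length, channels) tensor.

    Returns shape (batch, n_windows, size, channels); the backward pass
    scatter-adds window gradients back onto the overlapping input positions.
    """
    t = as_tensor(t)
    B, L, C = t.shape
    n_out = (L - size) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(t.data, size, axis=1)
    # view: (B, L-size+1, C, size) -> stride subsample, reorder to (B,n,size,C)
    win = view[:, ::stride].transpose(0, 1, 3, 2)[:, :n_out]
    out = Tensor(np.ascontiguousarray(win), t.requires_grad, (t,))

    def bwd(g):
        if not t.requires_grad:
            return
        gin = np.zeros_like(t.data)
        for j in range(size):
            stop = j + (n_out - 1) * stride + 1
            gin[:, j:stop:stride, :] += g[:, :, j, :]
        t._accumulate(gin, fresh=True)
    out._backward = bwd
    return out


def band_sum(z: Tensor, n_out: int) -> Tensor:
    """Banded diagonal sum used by the shift-GEMM convolution:
    out[b, t, f] = sum_j z[b, t+j, j, f] for a (batch, L, k, F) input.

    Together with a single (B*L, C) x (C, k*F) matmul this computes a
    stride-1 1-D convolution without materialising im2col patch copies.
    """
    z = as_tensor(z)
    B, L, k, F = z.shape
    out_data = np.zeros((B, n_out, F), dtype=z.data.dtype)
    for j in range(k):
        out_data += z.data[:, j:j + n_out, j, :]
    out = Tensor(out_data, z.requires_grad, (z,))

    def bwd(g):
        if not z.requires_grad:
            return
        gz = np.zeros_like(z.data)
        for j in range(k):
            gz[:, j:j + n_out, j, :] = g
        z._accumulate(gz, fresh=True)
    out._backward = bwd
    return out


def conv1d(x: Tensor, w: Tensor, kernel: int) -> Tensor:
    """Fused stride-1 1-D convolution (valid mode, no bias).

    ``x`` is (batch, L, C_in); ``w`` is (C_in, kernel*F) with tap *j* in
    columns [j*F, (j+1)*F).  Output is (batch, L-kernel+1, F) with
    ``out[b,t,f] = sum_{j,c} x[b,t+j,c] * w[c, j*F+f]``.

    Fusing the shift-GEMM and the banded diagonal sum into one tape node
    avoids materialising the (batch, L, kernel, F) intermediate and its
    gradient; backward runs one BLAS GEMM per kernel tap.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, L, C = x.shape
    k = kernel
    F = w.shape[1] // k
    n = L - k + 1
    z = (x.data.reshape(B * L, C) @ w.data).reshape(B, L, k, F)
    out_data = np.zeros((B, n, F), dtype=z.dtype)
    for j in range(k):
        out_data += z[:, j:j + n, j, :]
    out = Tensor(out_data, x.requires_grad or w.requires_grad, (x, w))

    def bwd(g):
        g2 = g.reshape(B * n, F)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for j in range(k):
                wj = w.data[:, j * F:(j + 1) * F]
                gx[:, j:j + n, :] += (g2 @ wj.T).reshape(B, n, C)
            x._accumulate(gx, fresh=True)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for j in range(k):
                xj = x.data[:, j:j + n, :].reshape(B * n, C)
                gw[:, j * F:(j + 1) * F] = xj.T @ g2
            w._accumulate(gw, fresh=True)
    out._backward = bwd
    return out


def logsumexp(t: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp (the max shift is treated as constant,
    which yields the exact gradient)."""
    m = np.max(t.data, axis=axis, keepdims=True)
    shifted = t - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(tuple(s for i, s in enumerate(out.shape) if i != axis % t.ndim))
    return out
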