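"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The encoder needs ordinary dense tensor ops (matmul, slicing, gather/scatter,
softmax, elementwise nonlinearities) with gradients.  This module provides a
small tape-based :class:`Tensor` in the micrograd style, float64 throughout:
each op records its parents and a closure that accumulates gradients into
them; ``Tensor.backward()`` runs the tape in reverse topological order.

Only what the model uses is implemented.  Gradient correctness is checked by
finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference paths)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, np.ndarray) and data.dtype == np.float64:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: Optional[np.ndarray] = None
        self._backward: Optional[Callable[[], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        topo: List[Tensor] = []
        visited = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            # nodes on dead branches receive no gradient; skip them
            if node._backward is not None and node.grad is not None:
                node._backward()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            def backward():
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(out.grad, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(out.grad, other.data.shape))
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            def backward():
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._parents:
            def backward():
                if self.requires_grad or self._parents:
                    self._accumulate(_unbroadcast(out.grad / other.data, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accumulate(_unbroadcast(-out.grad * self.data / other.data ** 2, other.data.shape))
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = _make(self.data ** exponent, (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(out.grad * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            def backward():
                if self.requires_grad or self._parents:
                    self._accumulate(out.grad @ other.data.T)
                if other.requires_grad or other._parents:
                    other._accumulate(self.data.T @ out.grad)
            out._backward = backward
        return out

    # -- shape ops ---------------------------------------------------------
    @property
    def T(self):
        out = _make(self.data.T, (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(out.grad.T)
        return out

    def reshape(self, *shape):
        old = self.data.shape
        out = _make(self.data.reshape(*shape), (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(out.grad.reshape(old))
        return out

    def __getitem__(self, key):
        out = _make(self.data[key], (self,))
        if out._parents:
            def backward():
                g = np.zeros_like(self.data)
                g[key] = out.grad
                self._accumulate(g)
            out._backward = backward
        return out

    def take_rows(self, indices: np.ndarray):
        """Gather rows (repeats allowed); backward scatter-adds."""
        indices = np.asarray(indices, dtype=int)
        out = _make(self.data[indices], (self,))
        if out._parents:
            def backward():
                g = np.zeros_like(self.data)
                np.add.at(g, indices, out.grad)
                self._accumulate(g)
            out._backward = backward
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def backward():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(out.grad * (self.data > 0))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = _make(s, (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(out.grad * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = _make(t, (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(out.grad * (1.0 - t ** 2))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(out.grad * e)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(out.grad / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = _make(r, (self,))
        if out._parents:
            out._backward = lambda: self._accumulate(out.grad * 0.5 / r)
        return out

    def softmax(self, axis=-1):
        """Row-wise softmax (fused op with the standard Jacobian-vector rule)."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = _make(s, (self,))
        if out._parents:
            def backward():
                g = out.grad
                self._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))
            out._backward = backward
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED[-1] and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward():
            for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad or t._parents:
                    idx = [slice(None)] * out.grad.ndim
                    idx[axis] = slice(start, stop)
                    t._accumulate(out.grad[tuple(idx)])
        out._backward = backward
    return out


def segment_sum(data: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """out[k] = sum of data rows whose segment id is k (scatter-add)."""
    segment_ids = np.asarray(segment_ids, dtype=int)
    res = np.zeros((num_segments,) + data.data.shape[1:])
    np.add.at(res, segment_ids, data.data)
    out = _make(res, (data,))
    if out._parents:
        out._backward = lambda: data._accumulate(out.grad[segment_ids])
    return out


def linear(x: Tensor, W: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Fused affine map x @ W (+ b)."""
    data = x.data @ W.data
    if b is not None:
        data = data + b.data
    parents = (x, W) if b is None else (x, W, b)
    out = _make(data, parents)
    if out._parents:
        def backward():
            g = out.grad
            if x.requires_grad or x._parents:
                x._accumulate(g @ W.data.T)
            if W.requires_grad or W._parents:
                W._accumulate(x.data.T @ g)
            if b is not None and (b.requires_grad or b._parents):
                b._accumulate(_unbroadcast(g, b.data.shape))
        out._backward = backward
    return out


def gcn_conv(H: Tensor, A_hat: np.ndarray, W: Tensor, relu: bool = True) -> Tensor:
    """Fused graph convolution activation(Â H W); Â is a constant."""
    pre = A_hat @ (H.data @ W.data)
    data = np.maximum(pre, 0.0) if relu else pre
    out = _make(data, (H, W))
    if out._parents:
        def backward():
            g = out.grad * (pre > 0) if relu else out.grad
            ag = A_hat.T @ g
            if H.requires_grad or H._parents:
                H._accumulate(ag @ W.data.T)
            if W.requires_grad or W._parents:
                W._accumulate(H.data.T @ ag)
        out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = _make(xhat * gamma.data + beta.data, (x, gamma, beta))
    if out._parents:
        def backward():
            g = out.grad
            if gamma.requires_grad or gamma._parents:
                gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
            if beta.requires_grad or beta._parents:
                beta._accumulate(_unbroadcast(g, beta.data.shape))
            if x.requires_grad or x._parents:
                gx = g * gamma.data
                x._accumulate(inv * (
                    gx
                    - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                ))
        out._backward = backward
    return out


def multi_head_attention(Q: Tensor, K: Tensor, V: Tensor, heads: int) -> Tuple[Tensor, np.ndarray]:
    """Fused scaled dot-product attention over `heads` column blocks.

    Inputs are (n, hidden) projections; returns the concatenated head outputs
    (n, hidden) and the detached attention weights (heads, n, n).
    """
    n, hidden = Q.data.shape
    d_k = hidden // heads

    def split(a: np.ndarray) -> np.ndarray:  # (n, hidden) -> (heads, n, d_k)
        return a.reshape(n, heads, d_k).transpose(1, 0, 2)

    Qh, Kh, Vh = split(Q.data), split(K.data), split(V.data)
    scale = 1.0 / np.sqrt(d_k)
    S = np.matmul(Qh, Kh.transpose(0, 2, 1)) * scale
    S -= S.max(axis=-1, keepdims=True)
    P = np.exp(S)
    P /= P.sum(axis=-1, keepdims=True)
    O = np.matmul(P, Vh)                                  # (heads, n, d_k)
    out = _make(O.transpose(1, 0, 2).reshape(n, hidden), (Q, K, V))
    if out._parents:
        def backward():
            gO = out.grad.reshape(n, heads, d_k).transpose(1, 0, 2)
            gP = np.matmul(gO, Vh.transpose(0, 2, 1))
            gS = P * (gP - (gP * P).sum(axis=-1, keepdims=True))
            def merge(a: np.ndarray) -> np.ndarray:
                return a.transpose(1, 0, 2).reshape(n, hidden)
            if Q.requires_grad or Q._parents:
                Q._accumulate(merge(np.matmul(gS, Kh) * scale))
            if K.requires_grad or K._parents:
                K._accumulate(merge(np.matmul(gS.transpose(0, 2, 1), Qh) * scale))
            if V.requires_grad or V._parents:
                V._accumulate(merge(np.matmul(P.transpose(0, 2, 1), gO)))
        out._backward = backward
    return out, P.copy()


def bce_with_logits(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Masked binary cross-entropy on logits; stable softplus form.

    ``targets``/``mask`` are constants; returns the sum of per-entry losses
    over mask==1 (caller divides by the mask count)."""
    z = logits.data
    y = np.asarray(targets, dtype=float)
    m = np.asarray(mask, dtype=float)
    y0 = np.where(m > 0, y, 0.0)
    loss = np.maximum(z, 0) - z * y0 + np.log1p(np.exp(-np.abs(z)))
    out = _make(np.array((loss * m).sum()), (logits,))
    if out._parents:
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

        def backward():
            logits._accumulate(out.grad * m * (sig - y0))
        out._backward = backward
    return out
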