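"""Neural building blocks: linear/MLP, GCN layer, E(3)-equivariant layer,
multi-head self-attention with residual + layer norm, dropout, Adam.

All parameters are float64 :class:`~molfuse.nn.autograd.Tensor` leaves,
initialized from an explicit ``numpy.random.Generator`` so whole-model
training is bit-reproducible from a single seed.
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import numpy as np

from .autograd import (
    Tensor,
    concat,
    gcn_conv,
    layer_norm,
    linear,
    multi_head_attention,
    segment_sum,
)


class Module:
    """Parameter container with recursive collection (registration order)."""

    def __init__(self):
        self._params: List[Tensor] = []
        self._modules: List["Module"] = []

    def add_param(self, array: np.ndarray) -> Tensor:
        p = Tensor(array, requires_grad=True)
        self._params.append(p)
        return p

    def add_module(self, module: "Module") -> "Module":
        self._modules.append(module)
        return module

    def parameters(self) -> List[Tensor]:
        out = list(self._params)
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int, bias: bool = True):
        super().__init__()
        self.W = self.add_param(_xavier(rng, in_dim, out_dim))
        self.b = self.add_param(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.W, self.b)


class MLP(Module):
    """Feed-forward stack with ReLU between layers (none after the last)."""

    def __init__(self, rng, dims: List[int], bias: bool = True):
        super().__init__()
        self.layers = [self.add_module(Linear(rng, a, b, bias)) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class GCNLayer(Module):
    """H' = ReLU(Â H W); Â is the symmetric-normalized adjacency, no bias."""

    def __init__(self, rng, in_dim: int, out_dim: int):
        super().__init__()
        self.W = self.add_param(_xavier(rng, in_dim, out_dim))

    def __call__(self, H: Tensor, A_hat: np.ndarray, activation: str = "relu") -> Tensor:
        return gcn_conv(H, A_hat, self.W, relu=activation == "relu")


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param(np.ones(dim))
        self.beta = self.add_param(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout:
    """Inverted dropout; a no-op when not training or p == 0."""

    def __init__(self, p: float):
        self.p = float(p)

    def __call__(self, x: Tensor, rng: Optional[np.random.Generator], training: bool) -> Tensor:
        if not training or self.p <= 0.0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over node rows + the CLS row.

    weights = softmax(QKᵀ/√d_k) per head; heads are concatenated and linearly
    projected; the caller wraps the output in residual + layer norm.  The
    attention-weight tensor of the latest call is kept (detached) on
    ``last_weights`` with shape (heads, n_rows, n_rows) for interpretability.
    """

    def __init__(self, rng, hidden: int, heads: int):
        super().__init__()
        if hidden % heads:
            raise ValueError(f"attention heads ({heads}) must divide hidden dim ({hidden})")
        self.heads = heads
        self.d_k = hidden // heads
        self.Wq = self.add_module(Linear(rng, hidden, hidden))
        self.Wk = self.add_module(Linear(rng, hidden, hidden))
        self.Wv = self.add_module(Linear(rng, hidden, hidden))
        self.Wo = self.add_module(Linear(rng, hidden, hidden))
        self.last_weights: Optional[np.ndarray] = None

    def __call__(self, H: Tensor) -> Tensor:
        Q, K, V = self.Wq(H), self.Wk(H), self.Wv(H)
        out, weights = multi_head_attention(Q, K, V, self.heads)
        self.last_weights = weights
        return self.Wo(out)


class EGNNLayer(Module):
    """One equivariant graph operation on (node features H, coordinates X).

    Messages m_ij = φ_e(h_i, h_j, ‖x_i−x_j‖²) over j ∈ N(i);
    h_i' = h_i + φ_h(h_i, Σ_j m_ij);
    x_i' = x_i + c_i Σ_j w_ij (x_j − x_i) with scalar w_ij = φ_x(m_ij),
    where c_i = 1/|N(i)| ("mean", default) or 1 ("sum").

    Feature updates depend on coordinates only through squared distances, so
    H' is E(3)-invariant and X' is E(3)-equivariant.  Isolated nodes (empty
    N(i)) keep their coordinates.
    """

    _D2_SCALE = 0.1  # squared Angstroms are O(10); keep φ_e inputs O(1)

    def __init__(self, rng, hidden: int, coord_update: str = "mean"):
        super().__init__()
        self.phi_e = self.add_module(MLP(rng, [2 * hidden + 1, hidden, hidden]))
        self.phi_h = self.add_module(MLP(rng, [2 * hidden, hidden, hidden]))
        self.phi_x = self.add_module(Linear(rng, hidden, 1))
        self.coord_update = coord_update

    def __call__(self, H: Tensor, X: Tensor, edge_src: np.ndarray, edge_dst: np.ndarray) -> Tuple[Tensor, Tensor]:
        n = H.shape[0]
        if len(edge_src) == 0:
            return H, X
        hi = H.take_rows(edge_src)
        hj = H.take_rows(edge_dst)
        rel = X.take_rows(edge_dst) - X.take_rows(edge_src)  # x_j - x_i
        d2 = (rel * rel).sum(axis=1, keepdims=True)
        m = self.phi_e(concat([hi, hj, d2 * self._D2_SCALE], axis=1)).relu()
        agg = segment_sum(m, edge_src, n)
        H_out = H + self.phi_h(concat([H, agg], axis=1))
        w = self.phi_x(m).tanh()
        delta = segment_sum(w * rel, edge_src, n)
        if self.coord_update == "mean":
            deg = np.maximum(np.bincount(edge_src, minlength=n), 1).reshape(-1, 1)
            delta = delta / Tensor(deg.astype(float))
        X_out = X + delta
        return H_out, X_out


class Adam:
    """Adaptive-moment optimizer (the training default, lr 1e-3)."""

    def __init__(self, params: List[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
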