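"""Minimal numpy neural-network layers with explicit backward passes.

A compact, dependency-free implementation of the pieces the sequence
regressor needs: dense layers, layer normalization, multi-head
self-attention with key padding masks, and a position-wise feed-forward
block, each caching its forward activations and implementing the exact
analytic gradient. Correctness is pinned by a finite-difference gradient
check in the test suite.

All computation is float64 and deterministic: identical inputs, parameters
and seeds give bit-identical outputs and gradients.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: recursive parameter collection and grad clearing."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Dense(Module):
    """Affine map on the last axis: y = x W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.W = Parameter(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return grad @ self.W.value.T


class LayerNorm(Module):
    """Normalization over the last axis with learned scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._xhat, self._inv_std = xhat, inv_std
        return xhat * self.gamma.value + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        axes = tuple(range(grad.ndim - 1))
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gx = grad * self.gamma.value
        mean_gx = gx.mean(axis=-1, keepdims=True)
        mean_gx_xhat = (gx * xhat).mean(axis=-1, keepdims=True)
        return inv_std * (gx - mean_gx - xhat * mean_gx_xhat)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with a key padding mask.

    Padded key positions are excluded from every query's softmax; padded
    query positions still produce (unused) outputs, which the pooling
    layer downstream ignores.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError("embed dim must be divisible by the head count")
        self.dim = dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.q_proj = Dense(dim, dim, rng)
        self.k_proj = Dense(dim, dim, rng)
        self.v_proj = Dense(dim, dim, rng)
        self.out_proj = Dense(dim, dim, rng)
        self._cache: tuple | None = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, H, T, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        q = self._split(self.q_proj.forward(x))
        k = self._split(self.k_proj.forward(x))
        v = self._split(self.v_proj.forward(x))
        scale = 1.0 / np.sqrt(self.d_head)
        scores = np.einsum("bhqd,bhkd->bhqk", q, k) * scale
        # mask: (B, T) True for real residues; hide padded keys
        neg = np.where(mask[:, None, None, :], 0.0, -1e9)
        scores = scores + neg
        scores -= scores.max(axis=-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=-1, keepdims=True)
        ctx = np.einsum("bhqk,bhkd->bhqd", attn, v)
        out = self.out_proj.forward(self._merge(ctx))
        self._cache = (q, k, v, attn, scale)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        q, k, v, attn, scale = self._cache
        g_ctx = self._split(self.out_proj.backward(grad))
        g_attn = np.einsum("bhqd,bhkd->bhqk", g_ctx, v)
        g_v = np.einsum("bhqk,bhqd->bhkd", attn, g_ctx)
        # softmax backward: dS = A * (dA - sum_k dA*A)
        g_scores = attn * (g_attn - (g_attn * attn).sum(axis=-1, keepdims=True))
        g_scores *= scale
        g_q = np.einsum("bhqk,bhkd->bhqd", g_scores, k)
        g_k = np.einsum("bhqk,bhqd->bhkd", g_scores, q)
        gx = self.q_proj.backward(self._merge(g_q))
        gx += self.k_proj.backward(self._merge(g_k))
        gx += self.v_proj.backward(self._merge(g_v))
        return gx


class FeedForward(Module):
    """Position-wise two-layer perceptron with ReLU."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.lin1 = Dense(dim, hidden, rng)
        self.lin2 = Dense(hidden, dim, rng)
        self._relu_mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.lin1.forward(x)
        self._relu_mask = h > 0
        return self.lin2.forward(h * self._relu_mask)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gh = self.lin2.backward(grad) * self._relu_mask
        return self.lin1.backward(gh)


class Dropout(Module):
    """Inverted dropout; identity when p = 0 or in inference mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.training = False
        self._mask: np.ndarray | float = 1.0
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.p == 0.0 or not self.training:
            self._mask = 1.0
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class EncoderLayer(Module):
    """Pre-norm transformer encoder block: attention then feed-forward,
    each behind a residual connection."""

    def __init__(self, dim: int, n_heads: int, hidden: int, dropout: float,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.drop1 = Dropout(dropout)
        self.norm2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, hidden, rng)
        self.drop2 = Dropout(dropout)

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        x = x + self.drop1.forward(self.attn.forward(self.norm1.forward(x), mask))
        x = x + self.drop2.forward(self.ffn.forward(self.norm2.forward(x)))
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad + self.norm2.backward(
            self.ffn.backward(self.drop2.backward(grad))
        )
        g = g + self.norm1.backward(
            self.attn.backward(self.drop1.backward(g))
        )
        return g


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
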