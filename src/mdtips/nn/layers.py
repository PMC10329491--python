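"""Neural-network building blocks: modules, layers, and the Adam optimizer.

Parameter initialization is driven by an explicit ``numpy.random.Generator``
so that every model in the package is bit-reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module", "Linear", "Embedding", "LayerNorm", "GRUCell", "Dropout",
    "MultiHeadSelfAttention", "Adam", "softmax_lastaxis", "bce_with_logits",
]


class Module:
    """Base class: tracks parameters and sub-modules, torch-style."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=np.float64).reshape(p.data.shape)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.1, padding_idx: int | None = None):
        super().__init__()
        w = rng.normal(0.0, scale, size=(n_rows, dim))
        if padding_idx is not None:
            w[padding_idx] = 0.0
        self.weight = Tensor(w, requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        idx = np.asarray(indices, dtype=np.intp)
        flat = self.weight[idx.reshape(-1)]
        return flat.reshape(idx.shape + (self.weight.data.shape[1],))


class LayerNorm(Module):
    """Normalization over the last axis with learnable gain and bias."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc / ((var + self.eps) ** 0.5)
        return y * self.gamma + self.beta


class GRUCell(Module):
    """Standard gated recurrent unit: h' = (1-z) * n + z * h."""

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w_ir = Linear(in_dim, hidden_dim, rng)
        self.w_hr = Linear(hidden_dim, hidden_dim, rng, bias=False)
        self.w_iz = Linear(in_dim, hidden_dim, rng)
        self.w_hz = Linear(hidden_dim, hidden_dim, rng, bias=False)
        self.w_in = Linear(in_dim, hidden_dim, rng)
        self.w_hn = Linear(hidden_dim, hidden_dim, rng, bias=False)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        r = (self.w_ir(x) + self.w_hr(h)).sigmoid()
        z = (self.w_iz(x) + self.w_hz(h)).sigmoid()
        n = (self.w_in(x) + r * self.w_hn(h)).tanh()
        return (1.0 - z) * n + z * h


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask drawn from ``rng``."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


def softmax_lastaxis(x: Tensor) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=-1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Masked multi-head self-attention over (batch, length, dim) inputs."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(dim, dim, rng)
        self.w_v = Linear(dim, dim, rng)
        self.w_o = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """``mask``: (batch, length) with 1 on real tokens, 0 on padding."""
        b, m, d = x.shape
        if not mask.any(axis=1).all():
            raise ValueError("attention received an all-padding sequence")

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(b, m, self.n_heads, self.d_head).swapaxes(1, 2)

        q, k, v = split_heads(self.w_q(x)), split_heads(self.w_k(x)), split_heads(self.w_v(x))
        scores = (q @ k.transpose()) * (1.0 / np.sqrt(self.d_head))
        # additive mask: padded keys never receive attention
        neg = np.where(mask[:, None, None, :] > 0, 0.0, -1e9)
        attn = softmax_lastaxis(scores + Tensor(neg))
        out = (attn @ v).swapaxes(1, 2).reshape(b, m, d)
        return self.w_o(out)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable binary cross-entropy, mean-reduced."""
    y = Tensor(np.asarray(targets, dtype=np.float64))
    per = logits.relu() - logits * y + (1.0 + (-logits.abs()).exp()).log()
    if weights is not None:
        per = per * Tensor(weights)
    return per.mean()


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
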