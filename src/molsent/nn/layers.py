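"""Neural-network building blocks on the autograd engine.

Initialisation draws from a caller-supplied :class:`numpy.random.Generator`,
so an entire model is reproducible from one seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, embedding


class Module:
    """Base class: parameter registry plus train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for mod in self._modules.values():
            out.extend(mod.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + name: p for name, p in self._params.items()}
        for mod_name, mod in self._modules.items():
            out.update(mod.named_parameters(prefix + mod_name + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> None:
        self.training = True
        for mod in self._modules.values():
            mod.train()

    def eval(self) -> None:
        self.training = False
        for mod in self._modules.values():
            mod.eval()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(p.data.dtype).copy()

    def checksum(self) -> float:
        """Order-stable scalar digest of all parameters (frozen-ness checks)."""
        return float(
            sum(np.abs(p).sum() for _, p in sorted(self.state_dict().items()))
        )


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (n_in + n_out))
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(n_in, n_out)).astype(np.float32), requires_grad=True
        )
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            rng.normal(0.0, 0.02, size=(n_tokens, dim)).astype(np.float32), requires_grad=True
        )

    def __call__(self, indices: np.ndarray) -> Tensor:
        return embedding(self.weight, indices)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.shift = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = centered.pow(2.0).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return centered * inv * self.gain + self.shift


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode or at rate 0."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with an additive key mask."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("n_heads must divide the hidden size")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, attention_mask: np.ndarray) -> Tensor:
        batch, length, dim = x.shape
        qkv = self.qkv(x).reshape(batch, length, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, heads, L, head_dim)
        q = qkv.narrow(0, 0, 1).reshape(batch, self.n_heads, length, self.head_dim)
        k = qkv.narrow(0, 1, 1).reshape(batch, self.n_heads, length, self.head_dim)
        v = qkv.narrow(0, 2, 1).reshape(batch, self.n_heads, length, self.head_dim)
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / math.sqrt(self.head_dim))
        # padded keys are pushed to -inf so they receive zero attention weight
        bias = np.where(attention_mask[:, None, None, :] > 0, 0.0, -1e9).astype(
            np.float32
        )
        weights = (scores + Tensor(bias)).softmax(axis=-1)
        ctx = weights @ v  # (B, heads, L, head_dim)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(batch, length, dim)
        return self.out(ctx)


class TransformerBlock(Module):
    """Post-norm encoder block: attention and feed-forward sublayers with
    residual connections and layer normalisation."""

    def __init__(
        self, dim: int, n_heads: int, ff_dim: int, dropout: float, rng
    ):
        super().__init__()
        self.attention = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.dropout = Dropout(dropout)

    def __call__(self, x: Tensor, attention_mask: np.ndarray, rng) -> Tensor:
        x = self.norm1(x + self.dropout(self.attention(x, attention_mask), rng))
        ff = self.ff2(self.ff1(x).gelu())
        return self.norm2(x + self.dropout(ff, rng))


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
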