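"""Neural-network layers on top of the autodiff tensor.

Initialization is fan-in scaled and fully determined by the generator each
layer is constructed with; ``state_dict``/``load_state_dict`` give flat
name -> array access for checkpointing.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, cat, softmax, take_rows, unfold1d


class Module:
    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
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

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats)."""
        out = {}
        for name, m in self._modules.items():
            out.update(m.buffers(prefix + name + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.data.copy() for k, v in self.named_parameters().items()}
        d.update({"buffer:" + k: v.copy() for k, v in self.buffers().items()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        bufs = self.buffers()
        for k, v in d.items():
            if k.startswith("buffer:"):
                bufs[k[len("buffer:"):]][...] = v
            else:
                params[k].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 1.0 / math.sqrt(n_in), (n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 1.0 / math.sqrt(dim), (n_rows, dim)),
                             requires_grad=True)

    def forward(self, ids: np.ndarray) -> Tensor:
        return take_rows(self.weight, np.asarray(ids, dtype=np.int64))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class BatchNorm1d(Module):
    """Per-channel normalization of (B, C, L) signals with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {prefix + "running_mean": self.running_mean,
                prefix + "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True).mean(axis=2, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True).mean(axis=2, keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
        else:
            mu = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return (x - mu) / ((var + self.eps) ** 0.5) * g + b


class Conv1d(Module):
    """Same-padded, stride-1 1-D convolution on (B, C_in, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = c_in * kernel
        self.weight = Tensor(
            rng.normal(0.0, 1.0 / math.sqrt(fan_in), (c_in * kernel, c_out)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.kernel = kernel
        self.pad = (kernel - 1) // 2

    def forward(self, x: Tensor) -> Tensor:
        B, C, L = x.shape
        win = unfold1d(x, self.kernel, self.pad)           # (B, C, L, K)
        win = win.transpose(0, 2, 1, 3).reshape(B, L, C * self.kernel)
        out = win @ self.weight                             # (B, L, C_out)
        if self.bias is not None:
            out = out + self.bias
        return out.transpose(0, 2, 1)                       # (B, C_out, L)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(B, L, 3, H, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                    # (B, H, L, dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        if mask is not None:
            bias = np.where(mask[:, None, None, :], 0.0, -1e9)
            scores = scores + Tensor(bias)
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer block with a ReLU feed-forward."""

    def __init__(self, dim: int, n_heads: int, ffn_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, dim, rng)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), mask)
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Standard sin/cos timestep features, shape (len(t), dim)."""
    t = np.asarray(t, dtype=float).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t * freqs[None, :]
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    if emb.shape[1] < dim:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], dim - emb.shape[1]))], axis=1)
    return emb


def avg_pool2(x: Tensor) -> Tensor:
    """Halve the last axis of (B, C, L) by mean-pooling pairs (L even)."""
    B, C, L = x.shape
    return x.reshape(B, C, L // 2, 2).mean(axis=3)


def upsample2(x: Tensor) -> Tensor:
    """Double the last axis of (B, C, L) by nearest-neighbour repetition."""
    B, C, L = x.shape
    return (x.reshape(B, C, L, 1) * Tensor(np.ones((1, 1, 1, 2)))).reshape(B, C, 2 * L)
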