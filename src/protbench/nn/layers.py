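"""Neural-network building blocks on top of the autodiff core.

Weights use a seeded uniform fan-in initialization, U(-1/sqrt(fan_in),
+1/sqrt(fan_in)).  Modules carry a ``training`` flag (dropout and batch-norm
statistics switch on it) and a per-run RNG installed by the trainer so every
stochastic forward pass is reproducible.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Minimal module base: named parameters, submodules, train/eval mode."""

    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._modules: Dict[str, "Module"] = {}
        self.training = False
        self.rng: Optional[np.random.Generator] = None

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, ModuleList):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for k, p in self._params.items():
            yield (prefix + k, p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def set_training(self, mode: bool, rng: Optional[np.random.Generator] = None):
        self.training = mode
        self.rng = rng
        for m in self._modules.values():
            m.set_training(mode, rng)
        return self

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            p.data[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules: List[Module]):
        super().__init__()
        self.items = list(modules)
        for i, m in enumerate(modules):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)


def uniform_init(rng: np.random.Generator, shape, fan_in: int,
                 dtype=np.float32) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(dtype),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.weight = uniform_init(rng, (in_dim, out_dim), in_dim, dtype)
        self.bias = uniform_init(rng, (out_dim,), in_dim, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return T.matmul(x, self.weight) + self.bias


class Embedding(Module):
    def __init__(self, n_symbols: int, dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.weight = uniform_init(rng, (n_symbols, dim), dim, dtype)

    def forward(self, idx: np.ndarray) -> Tensor:
        return T.take_rows(self.weight, np.asarray(idx).ravel()).reshape(
            tuple(np.asarray(idx).shape) + (self.weight.shape[1],))


class Conv1d(Module):
    """1-D convolution over (B, L, C_in) with same/valid padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, padding: str = "same",
                 dtype=np.float32):
        super().__init__()
        self.padding = padding
        fan_in = in_ch * kernel
        self.weight = uniform_init(rng, (kernel, in_ch, out_ch), fan_in, dtype)
        self.bias = uniform_init(rng, (out_ch,), fan_in, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return T.conv1d(x, self.weight, self.bias, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gain = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.shift = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = T.tmean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = T.tmean(xc * xc, axis=-1, keepdims=True)
        inv = T.power(var + self.eps, -0.5)
        return xc * inv * self.gain + self.shift


class BatchNorm1d(Module):
    """Batch normalization over the leading (batch) axis of (B, D) inputs."""

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gain = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.shift = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(dim, dtype=dtype)
        self.running_var = np.ones(dim, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = T.tmean(x, axis=0, keepdims=True)
            xc = x - mu
            var = T.tmean(xc * xc, axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            inv = T.power(var + self.eps, -0.5)
            return xc * inv * self.gain + self.shift
        xc = x - Tensor(self.running_mean)
        inv = (self.running_var + self.eps) ** -0.5
        return xc * Tensor(inv) * self.gain + self.shift


class Dropout(Module):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x: Tensor) -> Tensor:
        if self.training and self.rate > 0.0 and self.rng is not None:
            return T.dropout(x, self.rate, self.rng)
        return x


class GRU(Module):
    """Single-direction GRU layer over (B, L, D) with a 0/1 step mask.

    Masked (padding) steps carry the previous hidden state through, so
    trailing padding never influences real positions.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False, dtype=np.float32):
        super().__init__()
        self.hidden = hidden
        self.reverse = reverse
        self.w = uniform_init(rng, (in_dim, 3 * hidden), in_dim, dtype)
        self.u = uniform_init(rng, (hidden, 3 * hidden), hidden, dtype)
        self.b = uniform_init(rng, (3 * hidden,), in_dim, dtype)

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H), dtype=x.dtype))
        xw = T.matmul(x, self.w) + self.b  # (B, L, 3H), precomputed
        steps = range(L - 1, -1, -1) if self.reverse else range(L)
        outs: List[Tensor] = [None] * L
        for t in steps:
            xt = xw[:, t, :]
            uh = T.matmul(h, self.u)
            zr = T.sigmoid(xt[:, : 2 * H] + uh[:, : 2 * H])
            z, r = zr[:, :H], zr[:, H:]
            n = T.tanh(xt[:, 2 * H:] + r * uh[:, 2 * H:])
            h_new = (1.0 - z) * n + z * h
            mt = Tensor(mask[:, t:t + 1].astype(x.data.dtype))
            h = mt * h_new + (1.0 - mt) * h
            outs[t] = h
        stacked = T.concat([T.reshape(o, (B, 1, H)) for o in outs], axis=1)
        return stacked


class BiGRU(Module):
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.fwd = GRU(in_dim, hidden, rng, reverse=False, dtype=dtype)
        self.bwd = GRU(in_dim, hidden, rng, reverse=True, dtype=dtype)

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return T.concat([self.fwd(x, mask), self.bwd(x, mask)], axis=-1)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (B, L, D) with key masking."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        assert dim % n_heads == 0, "embedding dim must divide the head count"
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng, dtype)
        self.wk = Linear(dim, dim, rng, dtype)
        self.wv = Linear(dim, dim, rng, dtype)
        self.wo = Linear(dim, dim, rng, dtype)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return T.transpose(T.reshape(x, (B, L, self.n_heads, self.d_head)),
                           (0, 2, 1, 3))

    def forward(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        q = self._split(self.wq(x), B, L)
        k = self._split(self.wk(x), B, L)
        v = self._split(self.wv(x), B, L)
        logits = T.matmul(q, T.transpose(k, (0, 1, 3, 2)))
        logits = logits * (1.0 / np.sqrt(self.d_head))
        key_mask = np.broadcast_to(mask[:, None, None, :], logits.shape)
        att = T.softmax(logits, axis=-1, mask=key_mask)
        out = T.matmul(att, v)  # (B, H, L, dh)
        out = T.reshape(T.transpose(out, (0, 2, 1, 3)), (B, L, D))
        return self.wo(out)
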