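"""Neural building blocks: modules, attention, regularizers and optimizers.

All parameters are float64 numpy arrays wrapped in autograd tensors; every
source of randomness (init, dropout, drop-path) is driven by an explicit
``numpy.random.Generator`` so that fixed-seed runs are bitwise reproducible.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import numpy as np

from ._tensor import Tensor, concatenate


class Module:
    """Base class with recursive parameter collection and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = _param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = _param(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        shape = x.shape
        if x.ndim > 2:      # flatten leading axes: one large BLAS call
            x = x.reshape(-1, shape[-1])
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        if len(shape) > 2:
            y = y.reshape(*shape[:-1], self.W.shape[1])
        return y


class LayerNorm(Module):
    """Layer norm over the last axis with learned affine (gamma=1, beta=0)."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = _param(np.ones(d))
        self.beta = _param(np.zeros(d))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.eps) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float64) / keep
        return x * mask


class DropPath(Module):
    """Stochastic depth: zero a residual branch per sample during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        # one mask entry per leading-batch element, broadcast over features
        shape = (x.shape[0],) + (1,) * (x.ndim - 1) if x.ndim > 1 else x.shape
        mask = (self.rng.random(shape) < keep).astype(np.float64) / keep
        return x * mask


class MLPStack(Module):
    """Stack of [linear -> layer-norm -> GELU] stages (the projector motif)."""

    def __init__(self, widths: Iterable[int], rng: np.random.Generator):
        super().__init__()
        widths = list(widths)
        self.layers = ModuleList(
            Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:]))
        self.norms = ModuleList(LayerNorm(b) for b in widths[1:])

    def forward(self, x: Tensor) -> Tensor:
        for lin, ln in zip(self.layers, self.norms):
            x = ln(lin(x)).gelu()
        return x


class ModuleList(Module):
    def __init__(self, mods: Iterable[Module] = ()):
        super().__init__()
        self._items: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._items))] = m
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class MultiHeadAttention(Module):
    """Scaled dot-product multi-head attention (queries vs. keys/values).

    When ``record`` is enabled the post-softmax weights of the last call are
    kept on ``last_attention`` (heads leading), and ``op_counter`` — a mutable
    dict — is incremented by the number of score-matrix entries, which is how
    the fusion-complexity accounting is instrumented.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        if d % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide width {d}")
        self.d = d
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.Wq = Linear(d, d, rng)
        self.Wk = Linear(d, d, rng)
        self.Wv = Linear(d, d, rng)
        self.Wo = Linear(d, d, rng)
        self.drop = Dropout(dropout, rng)
        self.record = False
        self.last_attention: Optional[np.ndarray] = None
        self.op_counter: Optional[dict] = None

    def _split_heads(self, x: Tensor) -> Tensor:
        *lead, n, _ = x.shape
        x = x.reshape(*lead, n, self.n_heads, self.d_head)
        return x.swapaxes(-3, -2)          # (..., heads, n, d_head)

    def _merge_heads(self, x: Tensor) -> Tensor:
        x = x.swapaxes(-3, -2)
        *lead, n, _, _ = x.shape
        return x.reshape(*lead, n, self.d)

    def forward(self, query: Tensor, key_value: Tensor) -> Tensor:
        q = self._split_heads(self.Wq(query))
        k = self._split_heads(self.Wk(key_value))
        v = self._split_heads(self.Wv(key_value))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        if self.record:
            self.last_attention = attn.data.copy()
        if self.op_counter is not None:
            nq, nk = query.shape[-2], key_value.shape[-2]
            self.op_counter["score_entries"] = (
                self.op_counter.get("score_entries", 0) + nq * nk)
        out = self._merge_heads(self.drop(attn) @ v)
        return self.Wo(out)


class FeedForward(Module):
    """Position-wise FFN: linear -> GELU -> dropout -> linear."""

    def __init__(self, d: int, ratio: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.fc1 = Linear(d, ratio * d, rng)
        self.fc2 = Linear(ratio * d, d, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).gelu()))


class SwiGLU(Module):
    """Gated FFN: (SiLU(x W_g) * x W_v) W_out."""

    def __init__(self, d: int, d_inner: int, rng: np.random.Generator):
        super().__init__()
        self.gate = Linear(d, d_inner, rng)
        self.value = Linear(d, d_inner, rng)
        self.out = Linear(d_inner, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.gate(x).silu() * self.value(x))


class AdamW:
    """Decoupled weight-decay Adam (the package's default optimizer)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.wd:
                p.data *= 1 - self.lr * self.wd
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class SGD:
    """Plain SGD with optional momentum; kept as a pluggable alternative."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-2,
                 momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            if self.momentum:
                b *= self.momentum
                b += p.grad
                p.data -= self.lr * b
            else:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


OPTIMIZERS = {"adamw": AdamW, "sgd": SGD}


def make_optimizer(name: str, params, **kwargs):
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; available: {sorted(OPTIMIZERS)}")
    return cls(params, **kwargs)
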