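"""Bridge-token fusion.

A fixed set of N_b bridge tokens, generated from global poolings of the two
projected drug sequences and the compressed cell-line sequence, mediates all
cross-modal exchange.  Each fusion layer applies four Bridge Attention Units
(BAUs) in parallel: the drug and cell sequences each attend to the bridge
tokens, and the bridge tokens attend to the concatenation of all three
sequences.  Because every sequence only ever attends to (or alongside) the
N_b bridge tokens, per-layer attention cost is O(N_b * D * (N_d + N_c))
instead of the quadratic cost of full concatenated self-attention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from ._tensor import Tensor, concatenate
from .io_data import ContractError


@dataclass
class FusionConfig:
    n_bridge_tokens: int = 8
    n_layers: int = 3          # number of stacked fusion layers (BAU depth)
    n_heads: int = 8
    ffn_ratio: int = 4
    dropout: float = 0.2
    mode: str = "bridge"       # "bridge" or "plain" (concatenated transformer)
    learned_tokens: bool = False   # constant learned bridge tokens (ablation)

    def __post_init__(self):
        if self.n_layers < 1 or self.n_bridge_tokens < 1:
            raise ValueError("n_layers and n_bridge_tokens must be >= 1")
        if self.mode not in ("bridge", "plain"):
            raise ValueError(f"invalid fusion mode {self.mode!r}")


@dataclass
class FusionState:
    """The four evolving sequences at one fusion layer (widths all D)."""

    H_d1: Tensor
    H_d2: Tensor
    H_c: Tensor
    B: Optional[Tensor]
    layer_index: int = 0


def _check_width(*tensors: Tensor) -> int:
    widths = {t.shape[-1] for t in tensors if t is not None}
    if len(widths) != 1:
        raise ContractError(f"inconsistent feature widths {sorted(widths)}")
    return widths.pop()


class AttentionPool(nn.Module):
    """Softmax-weighted pooling with a learned per-token scalar score."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.score = nn.Linear(d, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        w = self.score(x).swapaxes(-1, -2).softmax(axis=-1).swapaxes(-1, -2)
        return (x * w).sum(axis=-2)


class BridgeTokenGenerator(nn.Module):
    """Condense global max / mean / attention poolings of the three
    sequences into N_b data-dependent bridge tokens via a learned linear map."""

    def __init__(self, d: int, n_tokens: int, rng: np.random.Generator,
                 learned_tokens: bool = False):
        super().__init__()
        self.d = d
        self.n_tokens = n_tokens
        self.learned_tokens = learned_tokens
        if learned_tokens:
            self.tokens = Tensor(rng.normal(0, 0.02, size=(n_tokens, d)),
                                 requires_grad=True)
        else:
            self.pools = nn.ModuleList(AttentionPool(d, rng) for _ in range(3))
            self.condense = nn.Linear(9 * d, n_tokens * d, rng)

    def forward(self, H_d1: Tensor, H_d2: Tensor, H_c: Tensor) -> Tensor:
        for h in (H_d1, H_d2, H_c):
            if h.shape[-2] < 1:
                raise ContractError("cannot pool an empty token sequence")
        if self.learned_tokens:
            if H_d1.ndim == 3:   # broadcast the constant tokens over the batch
                ones = Tensor(np.ones((H_d1.shape[0], 1, 1)))
                return ones * self.tokens
            return self.tokens
        pooled = []
        for h, apool in zip((H_d1, H_d2, H_c), self.pools):
            pooled.extend([h.max(axis=-2), h.mean(axis=-2), apool(h)])
        flat = concatenate(pooled, axis=-1)            # (..., 9D)
        out = self.condense(flat)                      # (..., N_b * D)
        return out.reshape(*out.shape[:-1], self.n_tokens, self.d)


class BAU(nn.Module):
    """Bridge Attention Unit.

    ``forward(H_m, H_n)`` enhances the query sequence H_m with context H_n:
    pre-norm multi-head cross-attention whose keys/values are the
    concatenation [H_n, H_m], a residual, then a pre-norm FFN residual.
    With H_n=None the unit degenerates to plain self-attention over H_m.
    """

    def __init__(self, d: int, n_heads: int, ffn_ratio: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.ln_q = nn.LayerNorm(d)
        self.ln_kv = nn.LayerNorm(d)
        self.ln_ffn = nn.LayerNorm(d)
        self.mhca = nn.MultiHeadAttention(d, n_heads, rng, dropout=dropout)
        self.ffn = nn.FeedForward(d, ffn_ratio, rng, dropout=dropout)

    def forward(self, H_m: Tensor, H_n: Optional[Tensor]) -> Tensor:
        _check_width(H_m, H_n)
        kv = H_m if H_n is None else concatenate([H_n, H_m], axis=-2)
        h = self.mhca(self.ln_q(H_m), self.ln_kv(kv)) + H_m
        return self.ffn(self.ln_ffn(h)) + h


class FusionLayer(nn.Module):
    """Four parallel BAU updates; every update reads only layer-i inputs."""

    def __init__(self, d: int, config: FusionConfig, rng: np.random.Generator):
        super().__init__()
        kw = dict(n_heads=config.n_heads, ffn_ratio=config.ffn_ratio,
                  dropout=config.dropout)
        self.to_d1 = BAU(d, rng=rng, **kw)
        self.to_d2 = BAU(d, rng=rng, **kw)
        self.to_c = BAU(d, rng=rng, **kw)
        self.to_b = BAU(d, rng=rng, **kw)

    def forward(self, state: FusionState) -> FusionState:
        H_d1, H_d2, H_c, B = state.H_d1, state.H_d2, state.H_c, state.B
        new_d1 = self.to_d1(H_d1, B)
        new_d2 = self.to_d2(H_d2, B)
        new_c = self.to_c(H_c, B)
        context = concatenate([H_c, H_d2, H_d1], axis=-2)
        new_b = self.to_b(B, context)
        return FusionState(new_d1, new_d2, new_c, new_b,
                           layer_index=state.layer_index + 1)


class BridgeFusion(nn.Module):
    """Token generation plus L_f stacked fusion layers (distinct params)."""

    def __init__(self, d: int, config: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.generator = BridgeTokenGenerator(
            d, config.n_bridge_tokens, rng, learned_tokens=config.learned_tokens)
        self.layers = nn.ModuleList(
            FusionLayer(d, config, rng) for _ in range(config.n_layers))

    def forward(self, H_d1: Tensor, H_d2: Tensor, H_c: Tensor) -> FusionState:
        B = self.generator(H_d1, H_d2, H_c)
        state = FusionState(H_d1, H_d2, H_c, B, layer_index=0)
        for layer in self.layers:
            state = layer(state)
        return state


class PlainTransformerFusion(nn.Module):
    """Ablation: a pre-norm self-attention encoder over the concatenated
    [H_d1, H_d2, H_c] sequence, re-split afterwards; no bridge tokens."""

    def __init__(self, d: int, config: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.layers = nn.ModuleList(
            BAU(d, config.n_heads, config.ffn_ratio, rng, dropout=config.dropout)
            for _ in range(config.n_layers))

    def forward(self, H_d1: Tensor, H_d2: Tensor, H_c: Tensor) -> FusionState:
        n1, n2 = H_d1.shape[-2], H_d2.shape[-2]
        x = concatenate([H_d1, H_d2, H_c], axis=-2)
        for layer in self.layers:
            x = layer(x, None)
        lead = (slice(None),) * (x.ndim - 2)
        return FusionState(x[lead + (slice(0, n1),)],
                           x[lead + (slice(n1, n1 + n2),)],
                           x[lead + (slice(n1 + n2, x.shape[-2]),)],
                           B=None, layer_index=self.config.n_layers)


def make_fusion(d: int, config: FusionConfig, rng: np.random.Generator):
    if config.mode == "plain":
        return PlainTransformerFusion(d, config, rng)
    return BridgeFusion(d, config, rng)


# ---------------------------------------------------------------------------
# instrumentation
# ---------------------------------------------------------------------------

def _attention_modules(module: nn.Module):
    if isinstance(module, nn.MultiHeadAttention):
        yield module
    for sub in module._modules.values():
        yield from _attention_modules(sub)


def instrument(module: nn.Module, counter: dict | None = None,
               record: bool = False) -> dict:
    """Attach a score-entry counter (and optionally weight recording) to
    every attention submodule; returns the counter dict."""
    counter = counter if counter is not None else {}
    for att in _attention_modules(module):
        att.op_counter = counter
        att.record = record
    return counter


def recorded_attention(module: nn.Module) -> list[np.ndarray]:
    return [att.last_attention for att in _attention_modules(module)
            if att.last_attention is not None]


def configure_identity(module: nn.Module) -> None:
    """Zero every residual branch (attention output projection and FFN final
    layer) so each BAU — hence the whole fusion — becomes the identity map."""
    for att in _attention_modules(module):
        att.Wo.W.data[...] = 0.0
        att.Wo.b.data[...] = 0.0

    def _zero_ffn(m: nn.Module):
        if isinstance(m, nn.FeedForward):
            m.fc2.W.data[...] = 0.0
            m.fc2.b.data[...] = 0.0
        for sub in m._modules.values():
            _zero_ffn(sub)

    _zero_ffn(module)


def expected_score_entries(n_d1: int, n_d2: int, n_c: int, n_b: int,
                           n_layers: int) -> int:
    """Analytic per-run count of attention score-matrix entries for the
    bridge fusion: each sequence queries [B, itself]; the bridge queries
    [H_c, H_d2, H_d1, B].  Linear in N_b and in (N_d + N_c)."""
    per_layer = (n_d1 * (n_b + n_d1) + n_d2 * (n_b + n_d2)
                 + n_c * (n_b + n_c) + n_b * (n_c + n_d2 + n_d1 + n_b))
    return n_layers * per_layer
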