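"""Dual-path synergy prediction head.

The fused sequences are mean-pooled into a 3D-wide entity vector (drug A,
drug B, cell line concatenated) and a D-wide bridge vector.  Each passes
through a Global Representation Refiner (GRR) — stacked residual blocks of
channel mixing plus a SwiGLU feed-forward branch with LayerScale and
DropPath — and the two refined vectors are summed into a linear head that
emits the scalar synergy prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from ._tensor import Tensor, concatenate
from .fusion import FusionState
from .io_data import ContractError


@dataclass
class GRRConfig:
    n_blocks: int = 2
    layerscale_init: float = 1e-4
    droppath_rate: float = 0.1
    inner_ratio: int = 4       # SwiGLU inner width as a multiple of D

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.droppath_rate < 1.0:
            raise ValueError("droppath_rate must be in [0, 1)")


@dataclass
class HeadState:
    g_entity: Tensor           # width 3D
    g_bridge: Optional[Tensor]  # width D, or None under plain fusion


def pool_entities(state: FusionState) -> HeadState:
    """Mean-pool each fused sequence; concatenate the three entity vectors
    in (drug1, drug2, cell) order."""
    g_entity = concatenate([state.H_d1.mean(axis=-2),
                            state.H_d2.mean(axis=-2),
                            state.H_c.mean(axis=-2)], axis=-1)
    g_bridge = state.B.mean(axis=-2) if state.B is not None else None
    return HeadState(g_entity=g_entity, g_bridge=g_bridge)


class GRRBlock(nn.Module):
    """One refiner block.

    x1  = x + Mix(LN(x))                       (channel mixing, residual)
    out = x1 + DropPath(gamma * SwiGLU(LN(x1)))  (gated FFN, LayerScale)
    """

    def __init__(self, width: int, config: GRRConfig, rng: np.random.Generator):
        super().__init__()
        self.ln_mix = nn.LayerNorm(width)
        self.mix = nn.Linear(width, width, rng)
        self.ln_ffn = nn.LayerNorm(width)
        self.ffn = nn.SwiGLU(width, config.inner_ratio * width, rng)
        self.gamma = Tensor(np.full(width, config.layerscale_init),
                            requires_grad=True)
        self.drop_path = nn.DropPath(config.droppath_rate, rng)

    def forward(self, x: Tensor) -> Tensor:
        x1 = x + self.mix(self.ln_mix(x))
        return x1 + self.drop_path(self.ffn(self.ln_ffn(x1)) * self.gamma)


class GRR(nn.Module):
    """A stack of GRR blocks at fixed width."""

    def __init__(self, width: int, config: GRRConfig, rng: np.random.Generator):
        super().__init__()
        self.blocks = nn.ModuleList(
            GRRBlock(width, config, rng) for _ in range(config.n_blocks))

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class PredictionHead(nn.Module):
    """Entity branch (3D -> D projection, then GRR) plus bridge branch (GRR),
    summed into a linear scalar head."""

    def __init__(self, d: int, config: GRRConfig, rng: np.random.Generator):
        super().__init__()
        self.d = d
        self.entity_proj = nn.Linear(3 * d, d, rng)
        self.entity_grr = GRR(d, config, rng)
        self.bridge_grr = GRR(d, config, rng)
        self.out = nn.Linear(d, 1, rng)

    def forward(self, head: HeadState) -> Tensor:
        if head.g_entity.shape[-1] != 3 * self.d:
            raise ContractError(
                f"entity vector width {head.g_entity.shape[-1]} != 3*{self.d}")
        z = self.entity_grr(self.entity_proj(head.g_entity))
        if head.g_bridge is not None:
            z = z + self.bridge_grr(head.g_bridge)
        y = self.out(z)
        return y.reshape(*y.shape[:-1]) if y.shape[-1] == 1 else y
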