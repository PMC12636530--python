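"""Weight-shared drug projector.

Each drug's token matrix (n_tokens x D_in) is mapped token-wise through
three [linear -> layer-norm -> GELU] stages into the shared fusion width D.
One parameter set serves both drugs of a pair, so the two branches are the
same function applied to each drug individually.
"""

from __future__ import annotations

import numpy as np

from . import nn
from ._tensor import Tensor
from .io_data import ContractError


class DrugProjector(nn.Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.d_in = d_in
        # intermediate widths equal the output width
        self.stack = nn.MLPStack([d_in, d_out, d_out, d_out], rng)

    def forward(self, tokens: Tensor) -> Tensor:
        if tokens.shape[-1] != self.d_in:
            raise ContractError(
                f"drug tokens have width {tokens.shape[-1]}, projector "
                f"expects {self.d_in}")
        return self.stack(tokens)
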