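"""Drug and cell-line featurization, including the ablation fallbacks.

The full model consumes precomputed drug token embeddings (from any
pretrained molecular encoder) and per-gene protein-sequence embeddings.  The
fallback paths — per-character one-hot SMILES for drugs and raw expression
for cell lines — exist so the contribution of the pretrained features can be
measured by switching them off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_data import ContractError, ValidationError

#: characters that cover the synthetic SMILES alphabet plus common organics
DEFAULT_SMILES_VOCAB = list("CNOSPFIcnos()[]=#-+123456789%@/\\.")
#: optional two-character element tokens recognised before single characters
TWO_CHAR_TOKENS = ("Cl", "Br")


class FeaturizationError(ValidationError):
    """A structure could not be converted to features."""


@dataclass
class FeatureConfig:
    """Which featurization path each modality uses.

    drug_mode: ``precomputed`` (pretrained token embeddings) or
        ``onehot_smiles`` (per-character one-hot of the SMILES string).
    cell_mode: ``enriched`` (expression x protein embedding) or
        ``expression_only`` (raw expression as a width-1 matrix).
    """

    drug_mode: str = "precomputed"
    cell_mode: str = "enriched"
    smiles_vocab: list[str] = field(default_factory=lambda: list(DEFAULT_SMILES_VOCAB))
    two_char_tokens: bool = False
    max_smiles_len: int = 128
    allow_unknown: bool = False

    def __post_init__(self):
        if self.drug_mode not in ("precomputed", "onehot_smiles"):
            raise ValueError(f"invalid drug_mode {self.drug_mode!r}")
        if self.cell_mode not in ("enriched", "expression_only"):
            raise ValueError(f"invalid cell_mode {self.cell_mode!r}")
        if len(set(self.smiles_vocab)) != len(self.smiles_vocab):
            raise ValueError("smiles_vocab contains duplicates")


def enrich_expression(expression: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Scale each gene's protein embedding by its expression value.

    Gene i's enriched vector is ``g_i = E_i * P_i`` where ``E_i`` is the
    scalar expression value and ``P_i`` the protein-sequence embedding row;
    the result is the L x D_P matrix G representing the cell line.
    """
    expression = np.asarray(expression, dtype=np.float64).ravel()
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != expression.shape[0]:
        raise ContractError(
            f"P has shape {P.shape} but expression has length "
            f"{expression.shape[0]}")
    return expression[:, None] * P


def expression_only_features(expression: np.ndarray) -> np.ndarray:
    """Raw expression as an L x 1 matrix (degenerate enrichment with P = 1).

    Used by the ablation that drops the protein language-model features."""
    expression = np.asarray(expression, dtype=np.float64).ravel()
    if not np.all(np.isfinite(expression)):
        raise ValidationError("non-finite expression values")
    return expression[:, None].copy()


def tokenize_smiles(smiles: str, two_char_tokens: bool = False) -> list[str]:
    if not two_char_tokens:
        return list(smiles)
    tokens, i = [], 0
    while i < len(smiles):
        if smiles[i:i + 2] in TWO_CHAR_TOKENS:
            tokens.append(smiles[i:i + 2])
            i += 2
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


def one_hot_smiles(smiles: str, config: FeatureConfig | None = None) -> np.ndarray:
    """Per-character one-hot encoding of a SMILES string.

    Returns an N x V matrix where N is the token count (truncated to
    ``max_smiles_len``) and V the vocabulary size (+1 UNK column when
    ``allow_unknown``).  Each row has exactly one 1.
    """
    config = config or FeatureConfig(drug_mode="onehot_smiles")
    if not smiles:
        raise FeaturizationError("empty SMILES string (need >= 1 token)")
    vocab = config.smiles_vocab + (TWO_CHAR_TOKENS and config.two_char_tokens
                                   and list(TWO_CHAR_TOKENS) or [])
    index = {c: i for i, c in enumerate(vocab)}
    width = len(vocab) + (1 if config.allow_unknown else 0)
    tokens = tokenize_smiles(smiles, config.two_char_tokens)[:config.max_smiles_len]
    out = np.zeros((len(tokens), width), dtype=np.float64)
    for pos, tok in enumerate(tokens):
        col = index.get(tok)
        if col is None:
            if not config.allow_unknown:
                raise FeaturizationError(
                    f"unknown SMILES token {tok!r} at position {pos}")
            col = width - 1
        out[pos, col] = 1.0
    return out
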