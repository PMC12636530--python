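"""End-to-end synergy model and the feature pipeline feeding it.

``BridgeSynModel`` wires the weight-shared drug projector, the CCF cell-line
encoder's MLP projector, the fusion module (bridge or plain transformer) and
the dual-path GRR prediction head into a single trainable module.

``FeaturePipeline`` resolves triplets to batched arrays: drug token matrices
(precomputed embeddings or one-hot SMILES, zero-padded to a common length)
and per-cell compressed cluster matrices G_c (computed once per cell line
and cached, since clustering depends only on the cell line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from ._tensor import Tensor
from .ccf import CCFConfig, CellLineProjector, comparator_clusterings, dpc_knn
from .drug_projector import DrugProjector
from .featurization import (FeatureConfig, expression_only_features,
                            one_hot_smiles)
from .fusion import FusionConfig, make_fusion
from .head import GRRConfig, PredictionHead, pool_entities
from .io_data import ContractError, Dataset, SynergyTriplet


@dataclass
class ModelConfig:
    d: int = 1024              # shared fusion width (Table-1-scale default)
    d_in_drug: int = 512       # incoming drug token embedding width
    d_p_cell: int = 32         # protein-embedding width D_P
    fusion: FusionConfig = field(default_factory=FusionConfig)
    grr: GRRConfig = field(default_factory=GRRConfig)
    ccf: CCFConfig = field(default_factory=CCFConfig)
    seed: int = 0

    @staticmethod
    def small(d_in_drug: int, d_p_cell: int, seed: int = 0,
              mode: str = "bridge") -> "ModelConfig":
        """A desk-scale configuration (D=64, 4 bridge tokens, 2 layers)."""
        return ModelConfig(
            d=64, d_in_drug=d_in_drug, d_p_cell=d_p_cell, seed=seed,
            fusion=FusionConfig(n_bridge_tokens=4, n_layers=2, n_heads=4,
                                ffn_ratio=2, dropout=0.1, mode=mode),
            grr=GRRConfig(n_blocks=2, droppath_rate=0.0),
            ccf=CCFConfig(k=4, n_clusters=8))


class BridgeSynModel(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d
        self.drug_proj = DrugProjector(config.d_in_drug, d, rng)
        self.cell_proj = CellLineProjector(config.d_p_cell, d, rng,
                                           hidden=config.ccf.hidden)
        self.fusion = make_fusion(d, config.fusion, rng)
        self.head = PredictionHead(d, config.grr, rng)

    def forward(self, da_tokens: Tensor, db_tokens: Tensor,
                gc: Tensor) -> Tensor:
        """Predict synergy for a batch: token tensors (B, N_d, D_in) for each
        drug and compressed cell matrices (B, |C|, D_P); returns (B,)."""
        h_d1 = self.drug_proj(da_tokens)
        h_d2 = self.drug_proj(db_tokens)   # same projector: shared weights
        h_c = self.cell_proj(gc)
        state = self.fusion(h_d1, h_d2, h_c)
        return self.head(pool_entities(state))


class FeaturePipeline:
    """Resolve triplets to model-ready arrays, with per-cell-line caching."""

    def __init__(self, dataset: Dataset,
                 features: FeatureConfig | None = None,
                 ccf: CCFConfig | None = None,
                 cluster_method: str = "dpc",
                 cluster_seed: int = 0):
        self.dataset = dataset
        self.features = features or FeatureConfig()
        self.ccf = ccf or CCFConfig()
        self.cluster_method = cluster_method
        self.cluster_seed = cluster_seed
        self._drug_cache: dict[str, np.ndarray] = {}
        self._cell_cache: dict[str, np.ndarray] = {}
        self._build_drugs()

    # -- drugs --------------------------------------------------------------
    def _build_drugs(self) -> None:
        raw: dict[str, np.ndarray] = {}
        for did, rec in self.dataset.drugs.items():
            if self.features.drug_mode == "precomputed":
                raw[did] = rec.tokens
            else:
                if rec.smiles is None:
                    raise ContractError(
                        f"drug {did!r} has no SMILES but drug_mode is "
                        "onehot_smiles")
                raw[did] = one_hot_smiles(rec.smiles, self.features)
        n_max = max(m.shape[0] for m in raw.values())
        width = {m.shape[1] for m in raw.values()}
        if len(width) != 1:
            raise ContractError(f"inconsistent drug token widths {sorted(width)}")
        self.drug_width = width.pop()
        for did, m in raw.items():
            padded = np.zeros((n_max, self.drug_width))
            padded[:m.shape[0]] = m
            self._drug_cache[did] = padded
        self.n_drug_tokens = n_max

    # -- cells --------------------------------------------------------------
    def _cell_matrix(self, cid: str) -> np.ndarray:
        if cid not in self._cell_cache:
            rec = self.dataset.cells[cid]
            if self.features.cell_mode == "expression_only":
                G = expression_only_features(rec.expression)
            else:
                G = rec.G
            n_clusters = min(self.ccf.n_clusters, G.shape[0])
            if self.cluster_method == "dpc":
                cfg = CCFConfig(k=min(self.ccf.k, G.shape[0] - 1),
                                n_clusters=n_clusters,
                                representative=self.ccf.representative)
                result = dpc_knn(G, cfg)
            else:
                result = comparator_clusterings(
                    G, self.cluster_method, n_clusters, seed=self.cluster_seed,
                    representative=self.ccf.representative)
            self._cell_cache[cid] = result.G_c
        return self._cell_cache[cid]

    @property
    def cell_width(self) -> int:
        return 1 if self.features.cell_mode == "expression_only" \
            else next(iter(self.dataset.cells.values())).G.shape[1]

    # -- batching -----------------------------------------------------------
    def batch(self, triplets: Sequence[SynergyTriplet],
              swap_drugs: bool = False, swap_mask: np.ndarray | None = None):
        """Stack features for a list of triplets.

        Returns (da, db, gc, y) float64 arrays.  ``swap_drugs`` feeds every
        pair in (B, A) order (used by the order-sensitivity analysis);
        ``swap_mask`` swaps a per-triplet subset (used by the training
        loop's order augmentation).
        """
        if swap_mask is None:
            swap_mask = np.full(len(triplets), swap_drugs)
        da = np.stack([self._drug_cache[t.drug_b if s else t.drug_a]
                       for t, s in zip(triplets, swap_mask)])
        db = np.stack([self._drug_cache[t.drug_a if s else t.drug_b]
                       for t, s in zip(triplets, swap_mask)])
        gc = np.stack([self._cell_matrix(t.cell_line) for t in triplets])
        y = np.array([t.y for t in triplets], dtype=np.float64)
        return da, db, gc, y


def save_model(model: BridgeSynModel, path) -> None:
    """Serialize config + parameters to a single .npz archive."""
    import dataclasses
    import json

    meta = json.dumps(dataclasses.asdict(model.config))
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(path, __config__=np.frombuffer(
        meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> BridgeSynModel:
    import json

    from .ccf import CCFConfig
    from .fusion import FusionConfig
    from .head import GRRConfig

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__config__"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    config = ModelConfig(
        d=meta["d"], d_in_drug=meta["d_in_drug"], d_p_cell=meta["d_p_cell"],
        fusion=FusionConfig(**meta["fusion"]), grr=GRRConfig(**meta["grr"]),
        ccf=CCFConfig(**meta["ccf"]), seed=meta["seed"])
    model = BridgeSynModel(config)
    model.load_state_dict(state)
    model.eval()
    return model


def predict(model: BridgeSynModel, pipeline: FeaturePipeline,
            triplets: Sequence[SynergyTriplet], batch_size: int = 256,
            swap_drugs: bool = False) -> np.ndarray:
    """Evaluation-mode predictions for a triplet list."""
    was_training = model.training
    model.eval()
    out = np.empty(len(triplets))
    for start in range(0, len(triplets), batch_size):
        chunk = triplets[start:start + batch_size]
        da, db, gc, _ = pipeline.batch(chunk, swap_drugs=swap_drugs)
        pred = model(Tensor(da), Tensor(db), Tensor(gc))
        out[start:start + len(chunk)] = pred.data
    if was_training:
        model.train()
    return out
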