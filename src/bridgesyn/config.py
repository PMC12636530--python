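"""Run configuration: YAML-backed blocks plus the ablation-variant matrix.

A run config bundles every tunable block (features, CCF encoder, fusion,
GRR head, training, splitting, synthetic generator).  The ``variant`` field
applies the ablation matrix:

=======  ==========================================================
full     precomputed drug embeddings, enriched cells, bridge fusion
a        bridge fusion replaced by a plain concatenated transformer
b        protein embeddings dropped (expression-only cells)
c        drug embeddings dropped (one-hot SMILES)
d        (b) + (c) with bridge fusion kept
e        (b) + (c) + plain transformer — both contributions removed
=======  ==========================================================
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .ccf import CCFConfig, ConfigError
from .featurization import FeatureConfig
from .fusion import FusionConfig
from .head import GRRConfig
from .model import ModelConfig
from .synthetic import SynthConfig
from .training import SplitSpec, TrainConfig

VARIANTS = ("full", "a", "b", "c", "d", "e")

#: settings each variant forces: (block, field) -> value
_VARIANT_MATRIX: dict[str, dict[tuple[str, str], Any]] = {
    "full": {},
    "a": {("fusion", "mode"): "plain"},
    "b": {("features", "cell_mode"): "expression_only"},
    "c": {("features", "drug_mode"): "onehot_smiles"},
    "d": {("features", "drug_mode"): "onehot_smiles",
          ("features", "cell_mode"): "expression_only"},
    "e": {("features", "drug_mode"): "onehot_smiles",
          ("features", "cell_mode"): "expression_only",
          ("fusion", "mode"): "plain"},
}


@dataclass
class RunConfig:
    variant: str = "full"
    d: int = 1024
    features: FeatureConfig = field(default_factory=FeatureConfig)
    ccf: CCFConfig = field(default_factory=CCFConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    grr: GRRConfig = field(default_factory=GRRConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0

    def model_config(self, d_in_drug: int, d_p_cell: int) -> ModelConfig:
        return ModelConfig(d=self.d, d_in_drug=d_in_drug, d_p_cell=d_p_cell,
                           fusion=self.fusion, grr=self.grr, ccf=self.ccf,
                           seed=self.seed)


_BLOCKS = {
    "features": FeatureConfig, "ccf": CCFConfig, "fusion": FusionConfig,
    "grr": GRRConfig, "train": TrainConfig, "split": SplitSpec,
    "synth": SynthConfig,
}


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown field(s) {sorted(unknown)}")
    return cls(**data)


def load_config(source: str | Path | dict | None) -> RunConfig:
    """Build a RunConfig from a YAML file (or an already-parsed mapping) and
    apply the variant matrix; explicit settings that contradict the chosen
    variant raise."""
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}

    kwargs: dict = {}
    for key in ("variant", "d", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    for block, cls in _BLOCKS.items():
        if block in raw:
            kwargs[block] = _from_dict(cls, raw[block] or {})
    config = RunConfig(**kwargs)
    return resolve_variant(config, raw)


def resolve_variant(config: RunConfig, raw: dict | None = None) -> RunConfig:
    """Force the sub-block settings the variant implies.

    ``raw`` is the original mapping (when loaded from YAML): an explicit
    value there that contradicts the variant is a configuration error rather
    than being silently overridden."""
    if config.variant not in VARIANTS:
        raise ConfigError(f"unknown variant {config.variant!r}; one of {VARIANTS}")
    forced = _VARIANT_MATRIX[config.variant]
    for (block, fname), value in forced.items():
        if raw and block in (raw or {}) and fname in (raw[block] or {}):
            explicit = raw[block][fname]
            if explicit != value:
                raise ConfigError(
                    f"variant {config.variant!r} forces {block}.{fname}="
                    f"{value!r} but config sets {explicit!r}")
        setattr(getattr(config, block), fname, value)
    return config


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully-resolved config beside a run's outputs (provenance)."""
    out = {"variant": config.variant, "d": config.d, "seed": config.seed}
    for block in _BLOCKS:
        out[block] = dataclasses.asdict(getattr(config, block))
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(out)), fh, sort_keys=False)
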