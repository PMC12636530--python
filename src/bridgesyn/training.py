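"""Training loop, split protocols and evaluation metrics.

The model is fit end-to-end by minimizing mean squared error with early
stopping on a validation split.  Three cross-validation protocols are
provided: random (triplet-level folds), leave-cell-out (entire cell lines
withheld) and leave-combination-out (entire unordered drug pairs withheld);
a 10% triplet-level hold-out is always drawn first and never enters any fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._tensor import Tensor
from .ccf import ConfigError
from .io_data import ContractError, SynergyTriplet
from .model import BridgeSynModel, FeaturePipeline
from .nn import make_optimizer

logger = logging.getLogger(__name__)


def mse_loss(y, y_hat):
    """Mean squared error; differentiable when given autograd tensors."""
    if isinstance(y, Tensor) or isinstance(y_hat, Tensor):
        y = y if isinstance(y, Tensor) else Tensor(y)
        y_hat = y_hat if isinstance(y_hat, Tensor) else Tensor(y_hat)
        if y.shape != y_hat.shape:
            raise ContractError(f"shape mismatch {y.shape} vs {y_hat.shape}")
        diff = y - y_hat
        return (diff * diff).mean()
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ContractError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return float(np.mean((y - y_hat) ** 2))


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

SCHEMES = ("random", "leave_cell_out", "leave_combination_out")


@dataclass
class SplitSpec:
    scheme: str = "random"
    n_folds: int = 5
    holdout_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}; one of {SCHEMES}")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")


@dataclass
class Splits:
    holdout: list[SynergyTriplet]
    folds: list[tuple[list[SynergyTriplet], list[SynergyTriplet]]]


def _group_key(triplet: SynergyTriplet, scheme: str):
    if scheme == "leave_cell_out":
        return triplet.cell_line
    if scheme == "leave_combination_out":
        return triplet.pair_key
    return None


def make_splits(triplets: Sequence[SynergyTriplet], spec: SplitSpec) -> Splits:
    """Draw the hold-out, then partition the rest into n_folds test folds at
    the protocol's grouping level."""
    rng = np.random.default_rng(spec.seed)
    n = len(triplets)
    n_hold = int(round(spec.holdout_fraction * n))
    perm = rng.permutation(n)
    holdout = [triplets[i] for i in perm[:n_hold]]
    rest = [triplets[i] for i in perm[n_hold:]]

    if spec.scheme == "random":
        idx = rng.permutation(len(rest))
        parts = np.array_split(idx, spec.n_folds)
        folds = []
        for part in parts:
            test_set = set(int(i) for i in part)
            folds.append(([rest[i] for i in range(len(rest)) if i not in test_set],
                          [rest[int(i)] for i in part]))
        return Splits(holdout=holdout, folds=folds)

    groups = sorted({_group_key(t, spec.scheme) for t in rest})
    if len(groups) < spec.n_folds:
        raise ConfigError(
            f"{spec.scheme}: only {len(groups)} groups for {spec.n_folds} folds")
    order = rng.permutation(len(groups))
    parts = np.array_split(order, spec.n_folds)
    folds = []
    for part in parts:
        test_groups = {groups[int(i)] for i in part}
        test = [t for t in rest if _group_key(t, spec.scheme) in test_groups]
        train = [t for t in rest if _group_key(t, spec.scheme) not in test_groups]
        folds.append((train, test))
    return Splits(holdout=holdout, folds=folds)


def split_validation(triplets: Sequence[SynergyTriplet], scheme: str,
                     fraction: float = 0.10, seed: int = 0
                     ) -> tuple[list[SynergyTriplet], list[SynergyTriplet]]:
    """Carve a validation set out of a training fold at the fold's own
    grouping level (whole cell lines / pairs for the group-wise schemes)."""
    rng = np.random.default_rng(seed)
    if scheme == "random":
        perm = rng.permutation(len(triplets))
        n_val = max(1, int(round(fraction * len(triplets))))
        val_idx = set(int(i) for i in perm[:n_val])
        return ([t for i, t in enumerate(triplets) if i not in val_idx],
                [t for i, t in enumerate(triplets) if i in val_idx])
    groups = sorted({_group_key(t, scheme) for t in triplets})
    n_val = max(1, int(round(fraction * len(groups))))
    chosen = {groups[int(i)] for i in rng.permutation(len(groups))[:n_val]}
    return ([t for t in triplets if _group_key(t, scheme) not in chosen],
            [t for t in triplets if _group_key(t, scheme) in chosen])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class Metrics:
    rmse: float
    r2: Optional[float]        # None when the observed vector is constant
    pcc: Optional[float]       # None when either vector is constant
    n: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r2, "pcc": self.pcc, "n": self.n}


def compute_metrics(y, y_hat) -> Metrics:
    """RMSE, coefficient of determination and Pearson correlation.

    R² is 1 - SS_res/SS_tot; PCC is the sample Pearson correlation.  Both
    are reported as missing (None) rather than a silent 0 when undefined."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ContractError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    n = y.shape[0]
    if n < 2:
        raise ContractError("metrics need n >= 2")
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0.0 else 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot
    if np.std(y) == 0.0 or np.std(y_hat) == 0.0:
        pcc = None
    else:
        pcc = float(np.corrcoef(y, y_hat)[0, 1])
    return Metrics(rmse=rmse, r2=r2, pcc=pcc, n=n)


def aggregate_by_group(triplets: Sequence[SynergyTriplet], y, y_hat,
                       group: str = "cell_line") -> dict:
    """Per-group metrics plus per-tissue mean and SD of cell-line PCCs.

    Groups with fewer than two members are flagged (metrics None)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    keys = [getattr(t, group) for t in triplets]
    per_group: dict = {}
    for key in sorted(set(keys)):
        idx = [i for i, k in enumerate(keys) if k == key]
        per_group[key] = (compute_metrics(y[idx], y_hat[idx])
                          if len(idx) >= 2 else None)
    per_tissue: dict = {}
    if group == "cell_line":
        tissue_of = {t.cell_line: t.tissue for t in triplets}
        tissues = sorted({v for v in tissue_of.values() if v is not None})
        for tissue in tissues:
            pccs = [m.pcc for cl, m in per_group.items()
                    if tissue_of.get(cl) == tissue and m is not None
                    and m.pcc is not None]
            per_tissue[tissue] = {
                "n_cell_lines": len(pccs),
                "mean_pcc": float(np.mean(pccs)) if pccs else None,
                "sd_pcc": float(np.std(pccs, ddof=1)) if len(pccs) >= 2 else None,
            }
    return {"per_group": per_group, "per_tissue": per_tissue}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 256
    patience: int = 25         # early-stopping patience in epochs
    optimizer: str = "adamw"
    weight_decay: float = 0.0
    max_epochs: int = 200
    seed: int = 0
    # randomly swap the drug order of half of each batch: synergy is
    # order-symmetric, but tables often list each pair in one canonical
    # order, so without augmentation the swapped order is never seen
    swap_augment: bool = True

    def __post_init__(self):
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.learning_rate < 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("learning_rate must be >= 0; batch_size and "
                              "max_epochs must be positive")


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    best_valid: float = float("inf")


def train(model: BridgeSynModel, pipeline: FeaturePipeline,
          train_set: Sequence[SynergyTriplet],
          valid_set: Sequence[SynergyTriplet],
          config: TrainConfig) -> TrainLog:
    """Fit by mini-batch MSE with early stopping on validation MSE; the
    parameters at the best validation epoch are restored before returning."""
    overlap = {(t.pair_key, t.cell_line) for t in train_set} & \
              {(t.pair_key, t.cell_line) for t in valid_set}
    if overlap:
        raise ContractError(f"train/validation overlap on {len(overlap)} combinations")

    opt = make_optimizer(config.optimizer, model.parameters(),
                         lr=config.learning_rate,
                         **({"weight_decay": config.weight_decay}
                            if config.optimizer == "adamw" else {}))
    rng = np.random.default_rng(config.seed)
    log = TrainLog()
    best_state = model.state_dict()
    bad_epochs = 0

    va_da, va_db, va_gc, va_y = pipeline.batch(valid_set)
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            chunk = [train_set[int(i)] for i in order[start:start + config.batch_size]]
            mask = rng.random(len(chunk)) < 0.5 if config.swap_augment else None
            da, db, gc, yb = pipeline.batch(chunk, swap_mask=mask)
            pred = model(Tensor(da), Tensor(db), Tensor(gc))
            loss = mse_loss(Tensor(yb), pred)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch starting {start}); try a lower learning rate")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(chunk)
            n_seen += len(chunk)
        log.train_loss.append(epoch_loss / n_seen)

        model.eval()
        val_pred = model(Tensor(va_da), Tensor(va_db), Tensor(va_gc))
        val_mse = mse_loss(va_y, val_pred.data)
        log.valid_loss.append(val_mse)
        logger.debug("epoch %d train_mse=%.5f valid_mse=%.5f",
                     epoch, log.train_loss[-1], val_mse)

        if val_mse < log.best_valid:
            log.best_valid = val_mse
            log.best_epoch = epoch
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                log.stopped_epoch = epoch
                break
    else:
        log.stopped_epoch = config.max_epochs

    model.load_state_dict(best_state)
    model.eval()
    return log
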