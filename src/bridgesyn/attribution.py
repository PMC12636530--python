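"""Interpretability: per-drug contributions and order sensitivity.

Two complementary probes of a trained model:

* perturbation contributions — the drop in predicted synergy when one drug
  is replaced by a null baseline (zero or dataset-mean token matrix):
  dS_a = S(d_a, d_b, c) - S(baseline, d_b, c), and symmetrically dS_b;
* integrated gradients (IG) — token-level attributions along a straight
  path from the baseline to the input, aggregated per drug.

A third analysis swaps the drug order of every triplet and correlates the
two prediction sets, quantifying how symmetric the learned function is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._tensor import Tensor
from .io_data import ContractError, SynergyTriplet
from .model import BridgeSynModel, FeaturePipeline, predict

BASELINES = ("zero", "mean")


@dataclass
class AttributionResult:
    triplet: SynergyTriplet
    delta_a: float
    delta_b: float
    baseline_kind: str
    ig_a: Optional[float] = None
    ig_b: Optional[float] = None
    ig_tokens_a: Optional[np.ndarray] = None
    ig_tokens_b: Optional[np.ndarray] = None


@dataclass
class OrderSensitivityReport:
    triplets: list[SynergyTriplet]
    y_ab: np.ndarray
    y_ba: np.ndarray
    pcc_between_orders: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "drug_a": [t.drug_a for t in self.triplets],
            "drug_b": [t.drug_b for t in self.triplets],
            "cell_line": [t.cell_line for t in self.triplets],
            "y_hat_ab": self.y_ab,
            "y_hat_ba": self.y_ba,
        })


def _baseline_tokens(pipeline: FeaturePipeline, kind: str) -> np.ndarray:
    if kind == "zero":
        return np.zeros((pipeline.n_drug_tokens, pipeline.drug_width))
    if kind == "mean":
        # token-averaged mean drug across the dataset, broadcast to all rows
        means = np.stack([m.mean(axis=0)
                          for m in pipeline._drug_cache.values()])
        return np.broadcast_to(means.mean(axis=0),
                               (pipeline.n_drug_tokens, pipeline.drug_width)).copy()
    raise ContractError(f"unknown baseline_kind {kind!r}; one of {BASELINES}")


def _forward_scalar(model: BridgeSynModel, da: np.ndarray, db: np.ndarray,
                    gc: np.ndarray) -> float:
    out = model(Tensor(da[None]), Tensor(db[None]), Tensor(gc[None]))
    return float(out.data[0])


def perturbation_contribution(model: BridgeSynModel, pipeline: FeaturePipeline,
                              triplet: SynergyTriplet,
                              baseline_kind: str = "zero"
                              ) -> tuple[float, float]:
    """Two-forward-pass contribution of each drug relative to a null baseline."""
    model.eval()
    base = _baseline_tokens(pipeline, baseline_kind)
    da, db, gc, _ = pipeline.batch([triplet])
    da, db, gc = da[0], db[0], gc[0]
    s_full = _forward_scalar(model, da, db, gc)
    delta_a = s_full - _forward_scalar(model, base, db, gc)
    delta_b = s_full - _forward_scalar(model, da, base, gc)
    return delta_a, delta_b


def integrated_gradients(model: BridgeSynModel, pipeline: FeaturePipeline,
                         triplet: SynergyTriplet,
                         baseline_kind: str = "zero", steps: int = 64,
                         rule: str = "midpoint") -> AttributionResult:
    """Riemann-sum IG over both drug token matrices (cell features fixed).

    IG_i = (x_i - x'_i) * mean_t dS/dx_i at interpolation points along the
    straight baseline-to-input path; ``rule`` picks midpoint (default) or
    right-endpoint abscissae.  Per-drug aggregates sum over tokens and
    channels; with a joint path over both drugs the aggregates satisfy the
    completeness identity against S(x) - S(baseline pair) as steps grow.
    """
    if steps < 1:
        raise ContractError("steps must be >= 1")
    if rule not in ("midpoint", "right"):
        raise ContractError(f"unknown rule {rule!r}")
    model.eval()
    base = _baseline_tokens(pipeline, baseline_kind)
    da, db, gc, _ = pipeline.batch([triplet])
    da, db, gc = da[0], db[0], gc[0]

    if rule == "midpoint":
        alphas = (np.arange(steps) + 0.5) / steps
    else:
        alphas = (np.arange(steps) + 1.0) / steps
    path_a = base[None] + alphas[:, None, None] * (da - base)[None]
    path_b = base[None] + alphas[:, None, None] * (db - base)[None]
    ta = Tensor(path_a, requires_grad=True)
    tb = Tensor(path_b, requires_grad=True)
    tgc = Tensor(np.broadcast_to(gc, (steps,) + gc.shape).copy())
    out = model(ta, tb, tgc)
    out.sum().backward()
    if not (np.all(np.isfinite(ta.grad)) and np.all(np.isfinite(tb.grad))):
        raise FloatingPointError(
            f"non-finite IG gradients for triplet "
            f"({triplet.drug_a}, {triplet.drug_b}, {triplet.cell_line})")
    ig_tokens_a = (da - base) * ta.grad.mean(axis=0)
    ig_tokens_b = (db - base) * tb.grad.mean(axis=0)

    delta_a, delta_b = perturbation_contribution(model, pipeline, triplet,
                                                 baseline_kind)
    return AttributionResult(
        triplet=triplet, delta_a=delta_a, delta_b=delta_b,
        baseline_kind=baseline_kind,
        ig_a=float(ig_tokens_a.sum()), ig_b=float(ig_tokens_b.sum()),
        ig_tokens_a=ig_tokens_a, ig_tokens_b=ig_tokens_b)


def completeness_residual(model: BridgeSynModel, pipeline: FeaturePipeline,
                          triplet: SynergyTriplet,
                          baseline_kind: str = "zero",
                          steps: int = 64, rule: str = "midpoint") -> float:
    """|sum of IG attributions - (S(x) - S(baseline, baseline))|."""
    res = integrated_gradients(model, pipeline, triplet, baseline_kind,
                               steps, rule)
    base = _baseline_tokens(pipeline, baseline_kind)
    da, db, gc, _ = pipeline.batch([triplet])
    s_full = _forward_scalar(model, da[0], db[0], gc[0])
    s_base = _forward_scalar(model, base, base, gc[0])
    return abs((res.ig_a + res.ig_b) - (s_full - s_base))


def order_sensitivity(model: BridgeSynModel, pipeline: FeaturePipeline,
                      triplets: Sequence[SynergyTriplet],
                      batch_size: int = 256) -> OrderSensitivityReport:
    """Predict every triplet in both drug orders and correlate the two sets."""
    y_ab = predict(model, pipeline, triplets, batch_size)
    y_ba = predict(model, pipeline, triplets, batch_size, swap_drugs=True)
    if len(triplets) < 2 or np.std(y_ab) == 0.0 or np.std(y_ba) == 0.0:
        pcc = None
    else:
        pcc = float(np.corrcoef(y_ab, y_ba)[0, 1])
    return OrderSensitivityReport(triplets=list(triplets), y_ab=y_ab,
                                  y_ba=y_ba, pcc_between_orders=pcc)


def contribution_scatter_export(results: Sequence[AttributionResult],
                                path) -> pd.DataFrame:
    """Write the delta_a vs delta_b scatter data (plus off-diagonal distance)
    as a delimited table; returns the frame."""
    df = pd.DataFrame({
        "drug_a": [r.triplet.drug_a for r in results],
        "drug_b": [r.triplet.drug_b for r in results],
        "cell_line": [r.triplet.cell_line for r in results],
        "delta_a": [repr(r.delta_a) for r in results],
        "delta_b": [repr(r.delta_b) for r in results],
        "abs_diff": [repr(abs(r.delta_a - r.delta_b)) for r in results],
    })
    df.to_csv(Path(path), index=False)
    return df
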