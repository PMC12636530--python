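"""Attribution: perturbation deltas, integrated gradients and order swaps."""

import numpy as np
import pytest

import bridgesyn as bs
from bridgesyn import attribution as at
from bridgesyn import nn
from bridgesyn._tensor import Tensor
from bridgesyn.io_data import ContractError


# ---------------------------------------------------------------------------
# a linear surrogate model with the BridgeSynModel calling convention
# ---------------------------------------------------------------------------

class LinearSurrogate(nn.Module):
    """y = <w_a, mean-pooled tokens of drug A> + <w_b, pooled drug B>."""

    def __init__(self, width, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.w_a = Tensor(rng.normal(size=width), requires_grad=True)
        self.w_b = Tensor(rng.normal(size=width), requires_grad=True)
        self.training = False

    def forward(self, da, db, gc):
        return (da.mean(axis=-2) * self.w_a).sum(axis=-1) + \
               (db.mean(axis=-2) * self.w_b).sum(axis=-1)

    def eval(self):
        return self


def test_perturbation_linear_model_closed_form(tiny_pipeline):
    pipe = tiny_pipeline
    model = LinearSurrogate(pipe.drug_width)
    t = pipe.dataset.triplets[0]
    delta_a, delta_b = at.perturbation_contribution(model, pipe, t, "zero")
    da, db, _, _ = pipe.batch([t])
    expect_a = float(da[0].mean(axis=0) @ model.w_a.data)
    expect_b = float(db[0].mean(axis=0) @ model.w_b.data)
    assert delta_a == pytest.approx(expect_a, rel=1e-12)
    assert delta_b == pytest.approx(expect_b, rel=1e-12)


def test_perturbation_zero_when_drug_equals_baseline(tiny_pipeline):
    pipe = tiny_pipeline
    model = LinearSurrogate(pipe.drug_width)
    t = pipe.dataset.triplets[0]
    # overwrite the cached tokens for drug A with the zero baseline
    saved = pipe._drug_cache[t.drug_a]
    pipe._drug_cache[t.drug_a] = np.zeros_like(saved)
    try:
        delta_a, _ = at.perturbation_contribution(model, pipe, t, "zero")
    finally:
        pipe._drug_cache[t.drug_a] = saved
    assert delta_a == 0.0


def test_perturbation_matches_two_forward_oracle_bitwise(tiny_model,
                                                         tiny_pipeline):
    pipe, model = tiny_pipeline, tiny_model
    base = at._baseline_tokens(pipe, "zero")
    for t in pipe.dataset.triplets[:20]:
        delta_a, delta_b = at.perturbation_contribution(model, pipe, t, "zero")
        da, db, gc, _ = pipe.batch([t])
        s_full = at._forward_scalar(model, da[0], db[0], gc[0])
        oracle_a = s_full - at._forward_scalar(model, base, db[0], gc[0])
        oracle_b = s_full - at._forward_scalar(model, da[0], base, gc[0])
        assert delta_a == oracle_a and delta_b == oracle_b


def test_unknown_baseline_rejected(tiny_model, tiny_pipeline):
    with pytest.raises(ContractError, match="baseline"):
        at.perturbation_contribution(tiny_model, tiny_pipeline,
                                     tiny_pipeline.dataset.triplets[0],
                                     "median")


def test_ig_exact_on_linear_model_any_steps(tiny_pipeline):
    pipe = tiny_pipeline
    model = LinearSurrogate(pipe.drug_width)
    t = pipe.dataset.triplets[0]
    for steps in (1, 7):
        res = at.integrated_gradients(model, pipe, t, "zero", steps=steps)
        # for a linear map IG equals w * (x - x') exactly, so the per-drug
        # aggregate equals the perturbation delta
        assert res.ig_a == pytest.approx(res.delta_a, rel=1e-10)
        assert res.ig_b == pytest.approx(res.delta_b, rel=1e-10)


def test_ig_completeness_converges_and_residual_shrinks(tiny_model,
                                                        tiny_pipeline):
    """Averaged over triplets the completeness gap decays with the step
    count.  The mean-drug baseline is used: the all-zero token matrix sits
    at the layer-norm singularity where the path integrand is nearly
    unbounded and convergence is slow."""
    pipe, model = tiny_pipeline, tiny_model
    triplets = pipe.dataset.triplets[:5]
    res = {s: np.mean([at.completeness_residual(model, pipe, t,
                                                baseline_kind="mean", steps=s)
                       for t in triplets])
           for s in (32, 128, 512)}
    assert res[128] <= res[32]
    assert res[512] <= res[128]
    assert res[512] < 2e-3


def test_ig_mean_baseline_and_right_rule_run(tiny_model, tiny_pipeline):
    t = tiny_pipeline.dataset.triplets[0]
    res = at.integrated_gradients(tiny_model, tiny_pipeline, t,
                                  baseline_kind="mean", steps=4, rule="right")
    assert np.isfinite(res.ig_a) and np.isfinite(res.ig_b)
    assert res.baseline_kind == "mean"
    with pytest.raises(ContractError):
        at.integrated_gradients(tiny_model, tiny_pipeline, t, steps=0)


class SymmetrizedModel(nn.Module):
    """Averages both drug orders; predictions are exactly order-invariant."""

    def __init__(self, inner):
        super().__init__()
        self.inner = inner
        self.training = False

    def forward(self, da, db, gc):
        return (self.inner(da, db, gc) + self.inner(db, da, gc)) * 0.5

    def eval(self):
        self.inner.eval()
        return self


def test_order_sensitivity_symmetric_model_pcc_one(tiny_model, tiny_pipeline):
    sym = SymmetrizedModel(tiny_model)
    report = at.order_sensitivity(sym, tiny_pipeline,
                                  tiny_pipeline.dataset.triplets[:30])
    assert np.array_equal(report.y_ab, report.y_ba)
    assert report.pcc_between_orders == pytest.approx(1.0)


class ConstantModel(nn.Module):
    def __init__(self):
        super().__init__()
        self.training = False

    def forward(self, da, db, gc):
        return da.mean(axis=-2).sum(axis=-1) * 0.0 + 3.5

    def eval(self):
        return self


def test_order_sensitivity_constant_model_flagged_missing(tiny_pipeline):
    report = at.order_sensitivity(ConstantModel(), tiny_pipeline,
                                  tiny_pipeline.dataset.triplets[:10])
    assert report.pcc_between_orders is None


def test_order_report_pcc_recomputable_from_export(tiny_model, tiny_pipeline):
    report = at.order_sensitivity(tiny_model, tiny_pipeline,
                                  tiny_pipeline.dataset.triplets[:40])
    df = report.to_frame()
    recomputed = np.corrcoef(df["y_hat_ab"], df["y_hat_ba"])[0, 1]
    assert report.pcc_between_orders == pytest.approx(recomputed, abs=1e-12)


def test_scatter_export_round_trip(tmp_path, tiny_pipeline):
    t = tiny_pipeline.dataset.triplets[0]
    results = [at.AttributionResult(triplet=t, delta_a=0.7, delta_b=0.7,
                                    baseline_kind="zero")]
    path = tmp_path / "scatter.csv"
    at.contribution_scatter_export(results, path)
    import pandas as pd
    df = pd.read_csv(path, float_precision="round_trip")
    assert df["abs_diff"].iloc[0] == 0.0
    assert df["delta_a"].iloc[0] == 0.7

    at.contribution_scatter_export([], tmp_path / "empty.csv")
    assert (tmp_path / "empty.csv").read_text().startswith("drug_a")
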