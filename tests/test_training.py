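"""Loss, metrics, split protocols and the training loop contract."""

import numpy as np
import pytest

import bridgesyn as bs
from bridgesyn.ccf import ConfigError
from bridgesyn.io_data import ContractError, SynergyTriplet
from bridgesyn.model import ModelConfig
from bridgesyn.training import (Metrics, SplitSpec, TrainConfig,
                                aggregate_by_group, compute_metrics,
                                make_splits, mse_loss, split_validation,
                                train)


# -- loss -------------------------------------------------------------------

def test_mse_hand_values_and_permutation_invariance():
    assert mse_loss([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert mse_loss([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(2 / 3)
    perm = mse_loss([3.0, 1.0, 2.0], [2.0, 2.0, 2.0])
    assert perm == pytest.approx(2 / 3)
    with pytest.raises(ContractError):
        mse_loss([1.0], [1.0, 2.0])


# -- metrics ----------------------------------------------------------------

def test_metrics_hand_case():
    m = compute_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
    assert m.rmse == pytest.approx(np.sqrt(2 / 3))
    assert m.r2 == pytest.approx(0.0)
    assert m.pcc is None          # constant predictions: correlation undefined
    assert m.n == 3


def test_metrics_perfect_predictions():
    m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (m.rmse, m.r2, m.pcc) == (0.0, 1.0, pytest.approx(1.0))


def test_metric_identities():
    rng = np.random.default_rng(0)
    y, yh = rng.normal(size=50), rng.normal(size=50)
    m = compute_metrics(y, yh)
    mse = mse_loss(y, yh)
    assert m.rmse ** 2 == pytest.approx(mse, rel=1e-12)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert m.r2 == pytest.approx(1 - mse * len(y) / ss_tot, rel=1e-12)


def test_pcc_invariant_under_positive_affine_rescale():
    rng = np.random.default_rng(1)
    y, yh = rng.normal(size=30), rng.normal(size=30)
    assert compute_metrics(y, 3.0 * yh + 7.0).pcc == \
        pytest.approx(compute_metrics(y, yh).pcc, abs=1e-12)


def test_metrics_flag_constant_observations():
    m = compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    assert m.r2 is None and m.pcc is None


# -- splits -----------------------------------------------------------------

def _toy_triplets(n_drugs=8, n_cells=10, seed=0):
    rng = np.random.default_rng(seed)
    drugs = [f"D{i}" for i in range(n_drugs)]
    out = []
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            for c in range(n_cells):
                out.append(SynergyTriplet(a, b, f"CL{c}", float(rng.normal()),
                                          tissue=f"T{c % 3}"))
    return out


@pytest.mark.parametrize("scheme", ["random", "leave_cell_out",
                                    "leave_combination_out"])
def test_holdout_disjoint_and_folds_partition(scheme):
    triplets = _toy_triplets()
    spec = SplitSpec(scheme=scheme, n_folds=5, seed=3)
    splits = make_splits(triplets, spec)
    assert len(splits.holdout) == round(0.10 * len(triplets))
    key = lambda t: (t.pair_key, t.cell_line)
    hold = {key(t) for t in splits.holdout}
    all_test = []
    for train_set, test_set in splits.folds:
        test_keys = {key(t) for t in test_set}
        assert not (test_keys & {key(t) for t in train_set})
        assert not (test_keys & hold)
        all_test.extend(test_set)
    # folds cover everything outside the hold-out exactly once
    assert sorted(map(key, all_test)) == sorted(
        key(t) for t in triplets if key(t) not in hold)


def test_leave_cell_out_groups_are_disjoint_across_folds():
    triplets = _toy_triplets(n_cells=10)
    splits = make_splits(triplets, SplitSpec(scheme="leave_cell_out",
                                             n_folds=5, seed=1))
    seen_cells = set()
    for train_set, test_set in splits.folds:
        test_cells = {t.cell_line for t in test_set}
        assert len(test_cells) == 2          # 10 cells over 5 folds
        assert not (test_cells & {t.cell_line for t in train_set})
        assert not (test_cells & seen_cells)
        seen_cells |= test_cells
    assert len(seen_cells) == 10


def test_leave_combination_out_keeps_both_orders_together():
    triplets = _toy_triplets()
    # add reversed-order rows to make the check meaningful
    reversed_rows = [SynergyTriplet(t.drug_b, t.drug_a, t.cell_line, t.y)
                     for t in triplets[::7]]
    allt = triplets + reversed_rows
    splits = make_splits(allt, SplitSpec(scheme="leave_combination_out",
                                         n_folds=5, seed=2))
    for train_set, test_set in splits.folds:
        assert not ({t.pair_key for t in test_set} &
                    {t.pair_key for t in train_set})


def test_splits_deterministic_under_seed():
    triplets = _toy_triplets()
    s1 = make_splits(triplets, SplitSpec(scheme="random", seed=5))
    s2 = make_splits(triplets, SplitSpec(scheme="random", seed=5))
    assert s1.holdout == s2.holdout
    assert all(a == b for (a, _), (b, _) in zip(s1.folds, s2.folds))


def test_too_few_groups_raises():
    triplets = [SynergyTriplet("A", "B", f"CL{i}", 0.0) for i in range(3)]
    with pytest.raises(ConfigError, match="groups"):
        make_splits(triplets, SplitSpec(scheme="leave_cell_out", n_folds=5,
                                        holdout_fraction=0.0))


def test_split_validation_respects_group_level():
    triplets = _toy_triplets()
    tr, va = split_validation(triplets, "leave_cell_out", seed=4)
    assert not ({t.cell_line for t in tr} & {t.cell_line for t in va})
    tr2, va2 = split_validation(triplets, "random", seed=4)
    assert len(va2) == round(0.1 * len(triplets))


# -- group aggregation ------------------------------------------------------

def test_aggregate_by_group_perfect_predictions():
    triplets = [SynergyTriplet("A", "B", "CL1", 1.0, tissue="lung"),
                SynergyTriplet("A", "C", "CL1", 2.0, tissue="lung"),
                SynergyTriplet("A", "B", "CL2", 3.0, tissue="lung"),
                SynergyTriplet("A", "C", "CL2", 4.0, tissue="lung")]
    y = np.array([t.y for t in triplets])
    agg = aggregate_by_group(triplets, y, y)
    assert agg["per_group"]["CL1"].pcc == pytest.approx(1.0)
    assert agg["per_group"]["CL2"].pcc == pytest.approx(1.0)
    assert agg["per_tissue"]["lung"]["sd_pcc"] == pytest.approx(0.0)


def test_aggregate_flags_small_groups_and_single_member_tissue():
    triplets = [SynergyTriplet("A", "B", "CL1", 1.0, tissue="skin"),
                SynergyTriplet("A", "C", "CL1", 2.0, tissue="skin"),
                SynergyTriplet("A", "B", "CL2", 3.0, tissue="colon")]
    y = np.array([1.0, 2.0, 3.0])
    yh = np.array([1.1, 1.9, 2.0])
    agg = aggregate_by_group(triplets, y, yh)
    assert agg["per_group"]["CL2"] is None          # one triplet only
    assert agg["per_tissue"]["skin"]["sd_pcc"] is None   # one cell line


def test_aggregate_matches_groupwise_loop_oracle():
    rng = np.random.default_rng(6)
    triplets = _toy_triplets(n_drugs=5, n_cells=4)
    y = np.array([t.y for t in triplets])
    yh = y + rng.normal(0, 0.5, size=len(y))
    agg = aggregate_by_group(triplets, y, yh)
    for cl in {t.cell_line for t in triplets}:
        idx = [i for i, t in enumerate(triplets) if t.cell_line == cl]
        expect = np.corrcoef(y[idx], yh[idx])[0, 1]
        assert agg["per_group"][cl].pcc == pytest.approx(expect, abs=1e-12)


# -- training loop ----------------------------------------------------------

def _train_setup(n_triplets=150, seed=0):
    cfg = bs.SynthConfig(n_drugs=10, n_cells=4, n_genes=30, n_gene_modules=3,
                         tokens_per_drug=3, d_in=6, d_p=4,
                         n_triplets=n_triplets, seed=seed, snr=None,
                         noise_sd=0.0)
    ds, truth = bs.gen_dataset(cfg)
    pipe = bs.FeaturePipeline(ds, ccf=bs.CCFConfig(k=3, n_clusters=3))
    mc = ModelConfig.small(pipe.drug_width, pipe.cell_width, seed=seed)
    mc.d = 16
    mc.fusion.n_heads = 2
    mc.fusion.dropout = 0.0
    return ds, pipe, bs.BridgeSynModel(mc)


def test_train_rejects_overlapping_validation():
    ds, pipe, model = _train_setup()
    with pytest.raises(ContractError, match="overlap"):
        train(model, pipe, ds.triplets, ds.triplets[:5],
              TrainConfig(max_epochs=1))


def test_patience_one_stops_at_first_non_improvement():
    ds, pipe, model = _train_setup()
    tr, va = ds.triplets[:100], ds.triplets[100:]
    log = train(model, pipe, tr, va,
                TrainConfig(learning_rate=0.0, patience=1, max_epochs=50,
                            batch_size=64, seed=0))
    # zero learning rate: validation never improves after the first epoch
    assert log.stopped_epoch == 2
    assert log.best_epoch == 1


def test_training_reduces_loss_on_noiseless_data():
    ds, pipe, model = _train_setup()
    tr, va = ds.triplets[:120], ds.triplets[120:]
    log = train(model, pipe, tr, va,
                TrainConfig(learning_rate=2e-3, patience=30, max_epochs=30,
                            batch_size=64, seed=0))
    target_sd = np.std([t.y for t in va])
    assert np.sqrt(log.best_valid) < 0.5 * target_sd
    assert log.valid_loss[-1] < log.valid_loss[0]


def test_training_curve_reproducible_under_fixed_seed():
    ds, pipe, model1 = _train_setup(seed=1)
    tr, va = ds.triplets[:100], ds.triplets[100:]
    cfg = TrainConfig(learning_rate=1e-3, patience=10, max_epochs=4,
                      batch_size=64, seed=9)
    log1 = train(model1, pipe, tr, va, cfg)
    _, _, model2 = _train_setup(seed=1)
    log2 = train(model2, pipe, tr, va, cfg)
    assert log1.train_loss == log2.train_loss
    assert log1.valid_loss == log2.valid_loss
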