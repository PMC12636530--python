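"""Bridge fusion algebra: pooling, BAU residual structure, parallel
updates, attention normalization and the complexity accounting."""

import numpy as np
import pytest

from bridgesyn import fusion as fu
from bridgesyn import nn
from bridgesyn._tensor import Tensor, concatenate


def _rng():
    return np.random.default_rng(0)


def _seqs(d=8, n1=3, n2=4, nc=5, seed=1):
    rng = np.random.default_rng(seed)
    return (Tensor(rng.normal(size=(n1, d))),
            Tensor(rng.normal(size=(n2, d))),
            Tensor(rng.normal(size=(nc, d))))


# -- bridge token generation ------------------------------------------------

def test_pooling_identities_on_constant_rows():
    d = 6
    gen = fu.BridgeTokenGenerator(d, n_tokens=2, rng=_rng())
    row = np.arange(d, dtype=float)
    H = Tensor(np.tile(row, (5, 1)))
    # with all rows equal, max = mean = attention pool = that row,
    # so the condensed tokens equal condense(row repeated 9 times)
    out = gen(H, H, H)
    manual = np.tile(row, 9) @ gen.condense.W.data + gen.condense.b.data
    assert np.allclose(out.numpy().ravel(), manual, atol=1e-12)


def test_attention_pool_weights_sum_to_one():
    d = 5
    pool = fu.AttentionPool(d, _rng())
    x = Tensor(np.random.default_rng(2).normal(size=(7, d)))
    w = pool.score(x).swapaxes(-1, -2).softmax(axis=-1).numpy()
    assert np.allclose(w.sum(), 1.0, atol=1e-12)


def test_bridge_tokens_match_hand_staged_oracle():
    d, nb = 4, 3
    gen = fu.BridgeTokenGenerator(d, n_tokens=nb, rng=_rng())
    H1, H2, Hc = _seqs(d=d)
    out = gen(H1, H2, Hc).numpy()
    pooled = []
    for H, pool in zip((H1, H2, Hc), gen.pools):
        x = H.numpy()
        pooled.append(x.max(axis=0))
        pooled.append(x.mean(axis=0))
        scores = x @ pool.score.W.data[:, 0] + pool.score.b.data[0]
        w = np.exp(scores - scores.max())
        w /= w.sum()
        pooled.append(w @ x)
    flat = np.concatenate(pooled)
    manual = (flat @ gen.condense.W.data + gen.condense.b.data).reshape(nb, d)
    assert np.allclose(out, manual, atol=1e-10)


def test_generator_rejects_empty_sequence():
    gen = fu.BridgeTokenGenerator(4, 2, _rng())
    with pytest.raises(Exception, match="empty"):
        gen(Tensor(np.zeros((0, 4))), Tensor(np.zeros((2, 4))),
            Tensor(np.zeros((2, 4))))


def test_learned_constant_tokens_mode():
    gen = fu.BridgeTokenGenerator(4, 2, _rng(), learned_tokens=True)
    H1, H2, Hc = _seqs(d=4)
    out1 = gen(H1, H2, Hc).numpy()
    out2 = gen(Hc, H1, H2).numpy()   # constant tokens ignore the inputs
    assert np.array_equal(out1, out2)
    batched = gen(Tensor(np.zeros((5, 3, 4))), H1, H2)
    assert batched.shape == (5, 2, 4)


# -- BAU --------------------------------------------------------------------

def test_bau_identity_when_residual_branches_zeroed():
    bau = fu.BAU(d=8, n_heads=2, ffn_ratio=2, rng=_rng())
    fu.configure_identity(bau)
    H_m, H_n, _ = _seqs(d=8)
    out = bau(H_m, H_n)
    assert np.array_equal(out.numpy(), H_m.numpy())


def test_bau_attention_rows_sum_to_one_per_head():
    bau = fu.BAU(d=8, n_heads=2, ffn_ratio=2, rng=_rng())
    fu.instrument(bau, record=True)
    H_m, H_n, _ = _seqs(d=8)
    bau(H_m, H_n)
    (attn,) = fu.recorded_attention(bau)
    assert attn.shape == (2, 3, 3 + 4)     # heads x queries x (n_n + n_m) keys
    assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


def test_bau_single_head_matches_scalar_hand_computation():
    d = 2
    bau = fu.BAU(d=d, n_heads=1, ffn_ratio=1, rng=_rng())
    # make FFN a no-op so only attention acts
    bau.ffn.fc2.W.data[...] = 0.0
    bau.ffn.fc2.b.data[...] = 0.0
    H_m = Tensor(np.array([[1.0, -1.0]]))
    H_n = Tensor(np.array([[0.5, 2.0]]))
    out = bau(H_m, H_n).numpy()

    def ln(v, gamma, beta, eps=1e-5):
        mu, var = v.mean(), v.var()
        return (v - mu) / np.sqrt(var + eps) * gamma + beta

    q_in = ln(H_m.numpy()[0], bau.ln_q.gamma.data, bau.ln_q.beta.data)
    kv = np.vstack([H_n.numpy(), H_m.numpy()])
    kv_n = np.vstack([ln(r, bau.ln_kv.gamma.data, bau.ln_kv.beta.data)
                      for r in kv])
    q = q_in @ bau.mhca.Wq.W.data + bau.mhca.Wq.b.data
    K = kv_n @ bau.mhca.Wk.W.data + bau.mhca.Wk.b.data
    V = kv_n @ bau.mhca.Wv.W.data + bau.mhca.Wv.b.data
    s = (K @ q) / np.sqrt(d)
    w = np.exp(s - s.max())
    w /= w.sum()
    att = w @ V @ bau.mhca.Wo.W.data + bau.mhca.Wo.b.data
    expect = att + H_m.numpy()[0]   # FFN branch contributes only the residual
    assert np.allclose(out[0], expect, atol=1e-10)


# -- fusion layers ----------------------------------------------------------

def _fusion_state(d=8, seed=3):
    rng = np.random.default_rng(seed)
    return fu.FusionState(H_d1=Tensor(rng.normal(size=(3, d))),
                          H_d2=Tensor(rng.normal(size=(4, d))),
                          H_c=Tensor(rng.normal(size=(5, d))),
                          B=Tensor(rng.normal(size=(2, d))))


def test_fusion_layer_identity_configuration():
    cfg = fu.FusionConfig(n_bridge_tokens=2, n_layers=1, n_heads=2,
                          ffn_ratio=2, dropout=0.0)
    layer = fu.FusionLayer(8, cfg, _rng())
    fu.configure_identity(layer)
    s0 = _fusion_state()
    s1 = layer(s0)
    for a, b in [(s1.H_d1, s0.H_d1), (s1.H_d2, s0.H_d2),
                 (s1.H_c, s0.H_c), (s1.B, s0.B)]:
        assert np.array_equal(a.numpy(), b.numpy())
    assert s1.layer_index == 1


def test_fusion_layer_parallel_update_semantics():
    """The bridge update must read layer-i inputs, not the new sequences."""
    cfg = fu.FusionConfig(n_bridge_tokens=2, n_layers=1, n_heads=2,
                          ffn_ratio=2, dropout=0.0)
    layer = fu.FusionLayer(8, cfg, _rng())
    s0 = _fusion_state()
    new_b = layer(s0).B.numpy()
    # recompute B' directly from the old state: must agree bitwise
    context = concatenate([s0.H_c, s0.H_d2, s0.H_d1], axis=-2)
    direct = layer.to_b(s0.B, context).numpy()
    assert np.array_equal(new_b, direct)


def test_run_fusion_composes_layers_and_preserves_shapes():
    cfg = fu.FusionConfig(n_bridge_tokens=2, n_layers=3, n_heads=2,
                          ffn_ratio=2, dropout=0.0)
    rng = np.random.default_rng(4)
    bf = fu.BridgeFusion(8, cfg, np.random.default_rng(5))
    H1, H2, Hc = _seqs(d=8)
    out = bf(H1, H2, Hc)
    assert out.layer_index == 3
    assert out.H_d1.shape == H1.shape and out.H_c.shape == Hc.shape
    assert out.B.shape == (2, 8)
    # composing the layers manually gives the same result
    B = bf.generator(H1, H2, Hc)
    state = fu.FusionState(H1, H2, Hc, B)
    for layer in bf.layers:
        state = layer(state)
    assert np.array_equal(out.B.numpy(), state.B.numpy())


def test_instrumented_op_count_matches_analytic_formula():
    d, nb, nl = 8, 2, 2
    cfg = fu.FusionConfig(n_bridge_tokens=nb, n_layers=nl, n_heads=2,
                          ffn_ratio=2, dropout=0.0)
    bf = fu.BridgeFusion(d, cfg, _rng())
    counter = fu.instrument(bf)
    n1, n2, nc = 3, 4, 5
    rng = np.random.default_rng(6)
    bf(Tensor(rng.normal(size=(n1, d))), Tensor(rng.normal(size=(n2, d))),
       Tensor(rng.normal(size=(nc, d))))
    assert counter["score_entries"] == \
        fu.expected_score_entries(n1, n2, nc, nb, nl)


def test_op_count_scales_linearly_in_bridge_tokens_and_sequence_lengths():
    f = fu.expected_score_entries
    # the bridge-mediated cross terms dominate; after removing the small
    # self-attention terms (each sequence and the bridge attend to
    # themselves once) the count is exactly linear in N_b ...
    y = [f(6, 6, 10, nb, 1) - nb * nb for nb in (1, 2, 3, 4)]
    diffs = np.diff(y)
    assert np.all(diffs == diffs[0])
    # ... and exactly linear in (N_d1 + N_d2 + N_c) at fixed N_b
    cross = [f(n, n, n, 4, 1) - 3 * n * n - 16 for n in (2, 4, 6, 8)]
    diffs2 = np.diff(cross)
    assert np.all(diffs2 == diffs2[0])


def test_plain_transformer_identity_and_resplit():
    cfg = fu.FusionConfig(n_layers=2, n_heads=2, ffn_ratio=2, dropout=0.0,
                          mode="plain")
    pt = fu.PlainTransformerFusion(8, cfg, _rng())
    fu.configure_identity(pt)
    H1, H2, Hc = _seqs(d=8)
    out = pt(H1, H2, Hc)
    assert out.B is None
    assert np.array_equal(out.H_d1.numpy(), H1.numpy())
    assert np.array_equal(out.H_d2.numpy(), H2.numpy())
    assert np.array_equal(out.H_c.numpy(), Hc.numpy())


def test_gradients_flow_finite_through_fusion():
    cfg = fu.FusionConfig(n_bridge_tokens=2, n_layers=2, n_heads=2,
                          ffn_ratio=2, dropout=0.0)
    bf = fu.BridgeFusion(8, cfg, _rng())
    H1, H2, Hc = _seqs(d=8)
    out = bf(H1, H2, Hc)
    loss = (out.B * out.B).sum() + out.H_d1.sum() + out.H_c.mean()
    loss.backward()
    for name, p in bf.named_parameters():
        if p.grad is not None:
            assert np.all(np.isfinite(p.grad)), name


def test_fusion_config_validation():
    with pytest.raises(ValueError):
        fu.FusionConfig(n_layers=0)
    with pytest.raises(ValueError):
        fu.FusionConfig(mode="co-attention")
    with pytest.raises(ValueError):
        nn.MultiHeadAttention(8, 3, _rng())
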