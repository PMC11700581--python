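import numpy as np
import pytest

from lstaloc.config import LSTAConfig
from lstaloc.lsta import LSTABlock, dynamic_projection, short_term_context
from lstaloc.nn import Tensor


def test_short_term_context_segments():
    assert short_term_context(128, 128) == [(0, 128)]
    assert short_term_context(4, 2) == [(0, 2), (2, 4)]
    assert short_term_context(5, 2) == [(0, 2), (2, 4), (4, 5)]
    assert short_term_context(3, 10) == [(0, 3)]  # w >= P: single full segment


def test_dynamic_projection_uniform_weights_give_column_means(rng):
    K = Tensor(rng.standard_normal((7, 4)).astype(np.float32))
    V = Tensor(rng.standard_normal((7, 4)).astype(np.float32))
    Wp = Tensor(np.zeros((4, 3), dtype=np.float32))  # zero scores -> uniform softmax
    Kbar, Vbar = dynamic_projection(K, V, Wp)
    assert Kbar.shape == (3, 4)
    np.testing.assert_allclose(Kbar.data, np.tile(K.data.mean(axis=0), (3, 1)), atol=1e-6)
    np.testing.assert_allclose(Vbar.data, np.tile(V.data.mean(axis=0), (3, 1)), atol=1e-6)


def test_dynamic_projection_single_position(rng):
    K = Tensor(rng.standard_normal((1, 4)).astype(np.float32))
    V = Tensor(rng.standard_normal((1, 4)).astype(np.float32))
    Wp = Tensor(rng.standard_normal((4, 2)).astype(np.float32))
    Kbar, _ = dynamic_projection(K, V, Wp)
    np.testing.assert_allclose(Kbar.data, np.tile(K.data[0], (2, 1)), atol=1e-6)


def test_dual_norm_scale_invariance(rng):
    """Scaling one branch pre-norm leaves its normalized output unchanged."""
    cfg = LSTAConfig(heads=2, window=8, projection_rank=2, head_width=4, dropout=0.0)
    block = LSTABlock(8, cfg, rng)
    k = Tensor(rng.standard_normal((1, 2, 8, 4)).astype(np.float32))
    v = Tensor(rng.standard_normal((1, 2, 8, 4)).astype(np.float32))
    kl = Tensor(rng.standard_normal((1, 2, 2, 4)).astype(np.float32))
    vl = Tensor(rng.standard_normal((1, 2, 2, 4)).astype(np.float32))
    (ks1, vs1), (kl1, _) = block.dual_norm((k, v), (kl, vl))
    scaled = Tensor(10.0 * k.data)
    (ks2, _), (kl2, _) = block.dual_norm((scaled, v), (kl, vl))
    # exact up to the epsilon inside the normalization
    np.testing.assert_allclose(ks1.data, ks2.data, atol=1e-3)
    np.testing.assert_allclose(kl1.data, kl2.data, atol=1e-6)
    # identical branches normalize identically
    (a, _), (b, _) = block.dual_norm((k, v), (k, v))
    np.testing.assert_allclose(a.data[..., :2, :], b.data[..., :2, :], atol=1e-6)


def brute_force_attention(x, Wq, Wk, Wv, Wo_w, Wo_b, heads, dk):
    """O(P^2) vanilla multi-head attention oracle in float64."""
    B, P, d = x.shape
    out_heads = []
    for h in range(heads):
        q = x @ Wq[:, h * dk : (h + 1) * dk]
        k = x @ Wk[:, h * dk : (h + 1) * dk]
        v = x @ Wv[:, h * dk : (h + 1) * dk]
        res = np.empty((B, P, dk))
        for b in range(B):
            for t in range(P):
                logits = (k[b] @ q[b, t]) / np.sqrt(dk)
                w = np.exp(logits - logits.max())
                w /= w.sum()
                res[b, t] = w @ v[b]
        out_heads.append(res)
    merged = np.concatenate(out_heads, axis=-1)
    return merged @ Wo_w + Wo_b


def test_vanilla_limit_matches_brute_force_oracle(rng):
    """w >= P with projection disabled reduces to plain multi-head attention."""
    cfg = LSTAConfig(heads=3, window=16, projection_rank=0, head_width=4, dropout=0.0)
    block = LSTABlock(8, cfg, rng)
    block.eval()
    x = rng.standard_normal((2, 11, 8)).astype(np.float32)
    got = block(Tensor(x), rng).data
    want = brute_force_attention(
        x.astype(np.float64),
        block.Wq.data.astype(np.float64),
        block.Wk.data.astype(np.float64),
        block.Wv.data.astype(np.float64),
        block.out.weight.data.astype(np.float64),
        block.out.bias.data.astype(np.float64),
        heads=3,
        dk=4,
    )
    np.testing.assert_allclose(got, want, atol=1e-5)


def test_attention_rows_sum_to_one_and_key_count(rng):
    cfg = LSTAConfig(heads=2, window=16, projection_rank=4, head_width=4, dropout=0.3)
    block = LSTABlock(8, cfg, rng)
    block.eval()
    x = Tensor(rng.standard_normal((2, 16, 8)).astype(np.float32))
    _, weights = block(x, rng, return_weights=True)
    (w,) = weights
    assert w.shape == (2, 2, 16, 16 + 4)  # short keys + r projected keys
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-5)
    assert np.all(w >= 0)


def test_single_position_attention_is_identity_on_value_path(rng):
    """P = 1, w = 1, r = 1: the only attention target is the position itself."""
    cfg = LSTAConfig(heads=2, window=1, projection_rank=1, head_width=4, dropout=0.0)
    block = LSTABlock(8, cfg, rng)
    block.eval()
    x = Tensor(rng.standard_normal((1, 1, 8)).astype(np.float32))
    got = block(x, rng).data
    # both keys (short and projected) reference the same position, so the
    # attended value is that position's normalized value row regardless of weights
    v = (x.data @ block.Wv.data).reshape(1, 1, 2, 4).transpose(0, 2, 1, 3)
    vs = block.ln_short(Tensor(v)).data
    vl = block.ln_long(Tensor(v)).data
    _, w = block(x, rng, return_weights=True)
    attended = w[0][..., :1] * vs + w[0][..., 1:] * vl
    merged = attended.transpose(0, 2, 1, 3).reshape(1, 1, 8)
    want = merged @ block.out.weight.data + block.out.bias.data
    np.testing.assert_allclose(got, want, atol=1e-5)


def test_forward_shape_and_eval_determinism(rng):
    cfg = LSTAConfig()  # 6 heads, window 128, rank 4, d_k 6
    block = LSTABlock(32, cfg, rng)
    block.eval()
    x = Tensor(rng.standard_normal((3, 128, 32)).astype(np.float32))
    y1 = block(x, np.random.default_rng(0)).data
    y2 = block(x, np.random.default_rng(99)).data
    assert y1.shape == (3, 128, 32)
    np.testing.assert_array_equal(y1, y2)  # dropout inert in eval mode


def test_forward_rejects_wrong_width(rng):
    block = LSTABlock(8, LSTAConfig(heads=2, head_width=4), rng)
    with pytest.raises(ValueError):
        block(Tensor(rng.standard_normal((1, 4, 5)).astype(np.float32)), rng)
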