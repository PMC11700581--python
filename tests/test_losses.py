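import numpy as np
import pytest

from lstaloc.config import FocalLossConfig
from lstaloc.losses import focal_loss_multiclass, focal_loss_multilabel
from lstaloc.nn import Tensor


def multiclass_oracle(probs, labels, alpha, gamma):
    """Independent scalar-loop reference."""
    total = 0.0
    for i, lab in enumerate(labels):
        p = max(probs[i, lab], 1e-8)
        total += -alpha * (1 - p) ** gamma * np.log(p)
    return total / len(labels)


def multilabel_oracle(probs, labels, alpha_vec, gamma):
    n = probs.shape[1]
    per_class = []
    for j in range(n):
        vals = []
        for i in range(probs.shape[0]):
            p = probs[i, j] if labels[i, j] == 1 else 1 - probs[i, j]
            p = max(p, 1e-8)
            vals.append(-alpha_vec[j] * (1 - p) ** gamma * np.log(p))
        per_class.append(np.mean(vals))
    return float(np.mean(per_class))


def random_probs(rng, m, n):
    p = rng.random((m, n)) + 1e-3
    return (p / p.sum(axis=1, keepdims=True)).astype(np.float32)


def test_multiclass_closed_form_values():
    cfg = FocalLossConfig(alpha=1.0, gamma=2.0)
    # p_true = 1 -> zero loss
    probs = Tensor(np.array([[1.0, 0.0]], dtype=np.float32))
    assert float(focal_loss_multiclass(probs, [0], cfg).data) == pytest.approx(0.0, abs=1e-6)
    # p_true = 0.5, gamma 2: 0.25 * ln 2
    probs = Tensor(np.array([[0.5, 0.5]], dtype=np.float32))
    got = float(focal_loss_multiclass(probs, [0], cfg).data)
    assert got == pytest.approx(0.25 * np.log(2), abs=1e-6)


def test_multiclass_gamma_zero_reduces_to_cross_entropy(rng):
    cfg = FocalLossConfig(alpha=1.0, gamma=0.0)
    probs = random_probs(rng, 20, 5)
    labels = rng.integers(0, 5, 20)
    got = float(focal_loss_multiclass(Tensor(probs), labels, cfg).data)
    ce = -np.mean(np.log(probs[np.arange(20), labels]))
    assert got == pytest.approx(ce, abs=1e-6)


def test_multiclass_focal_bounded_by_cross_entropy(rng):
    cfg = FocalLossConfig(alpha=1.0, gamma=2.0)
    probs = random_probs(rng, 30, 4)
    labels = rng.integers(0, 4, 30)
    focal = float(focal_loss_multiclass(Tensor(probs), labels, cfg).data)
    ce = -np.mean(np.log(probs[np.arange(30), labels]))
    assert 0.0 <= focal <= ce + 1e-7


def test_multilabel_closed_form_value():
    # one sample, one class, label 1, p = 0.9, alpha 0.4, gamma 2
    cfg = FocalLossConfig(gamma=2.0, alpha_vec=(0.4,))
    probs = Tensor(np.array([[0.9]], dtype=np.float32))
    got = float(focal_loss_multilabel(probs, np.array([[1]]), cfg).data)
    assert got == pytest.approx(-0.4 * 0.01 * np.log(0.9), rel=1e-4)
    assert got == pytest.approx(4.2145e-4, rel=1e-3)


def test_multilabel_perfect_predictions_zero_loss():
    cfg = FocalLossConfig(gamma=2.0, alpha_vec=(0.4, 0.03, 0.92))
    probs = Tensor(np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]], dtype=np.float32))
    labels = np.array([[1, 0, 1], [0, 1, 0]])
    assert float(focal_loss_multilabel(probs, labels, cfg).data) == pytest.approx(0.0, abs=1e-6)


def test_multilabel_label_flip_symmetry(rng):
    cfg = FocalLossConfig(gamma=2.0, alpha_vec=tuple(rng.random(4) + 0.1))
    probs = rng.random((10, 4)).astype(np.float32)
    labels = rng.integers(0, 2, (10, 4))
    a = float(focal_loss_multilabel(Tensor(probs), labels, cfg).data)
    b = float(focal_loss_multilabel(Tensor(1.0 - probs), 1 - labels, cfg).data)
    assert a == pytest.approx(b, rel=1e-5)


def test_losses_match_scalar_loop_oracle(rng):
    """100 random draws each, deviation < 1e-6 (float64 pipelines)."""
    for _ in range(100):
        m, n = int(rng.integers(1, 12)), int(rng.integers(2, 7))
        cfg = FocalLossConfig(alpha=float(rng.random() + 0.1), gamma=float(rng.random() * 3))
        probs = random_probs(rng, m, n).astype(np.float64)
        labels = rng.integers(0, n, m)
        got = float(focal_loss_multiclass(Tensor(probs), labels, cfg).data)
        assert got == pytest.approx(multiclass_oracle(probs, labels, cfg.alpha, cfg.gamma), abs=1e-6)

        alpha_vec = tuple(rng.random(n) + 0.05)
        mlcfg = FocalLossConfig(gamma=cfg.gamma, alpha_vec=alpha_vec)
        mprobs = rng.random((m, n))
        mlabels = rng.integers(0, 2, (m, n))
        got = float(focal_loss_multilabel(Tensor(mprobs), mlabels, mlcfg).data)
        assert got == pytest.approx(
            multilabel_oracle(mprobs, mlabels, alpha_vec, cfg.gamma), abs=1e-6
        )


def test_loss_strictly_decreases_in_true_class_probability():
    cfg = FocalLossConfig(alpha=1.0, gamma=2.0)
    ps = np.linspace(0.05, 0.95, 10)
    losses = [
        float(focal_loss_multiclass(Tensor(np.array([[p, 1 - p]], dtype=np.float64)), [0], cfg).data)
        for p in ps
    ]
    assert all(a > b for a, b in zip(losses, losses[1:]))


def test_zero_probability_is_clamped_not_nan():
    cfg = FocalLossConfig()
    probs = Tensor(np.array([[0.0, 1.0]], dtype=np.float32))
    val = float(focal_loss_multiclass(probs, [0], cfg).data)
    assert np.isfinite(val) and val > 0
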