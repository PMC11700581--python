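"""Focal losses for imbalanced single-label and multi-label classification.

Multi-class form (probabilities from a softmax):

    Loss = -(1/m) * sum_samples  alpha * (1 - p_true)^gamma * ln(p_true)

Multi-label form (independent sigmoid outputs), per class i with its own
class weight alpha_i and p_i = p_hat_i when the label is 1 else 1 - p_hat_i:

    FL_i  = mean_samples  -alpha_i * (1 - p_i)^gamma * ln(p_i)
    Loss  = (1/n) * sum_i FL_i

gamma (default 2) down-weights easy examples; natural logarithms throughout.
Probabilities are clamped to [eps, 1] before the log so a confident mistake
yields a large finite loss, never NaN.
"""

from __future__ import annotations

import numpy as np

from .config import FocalLossConfig
from .nn import Tensor, as_tensor

__all__ = ["focal_loss_multiclass", "focal_loss_multilabel"]

_EPS = 1e-8


def focal_loss_multiclass(probs: Tensor, labels: np.ndarray, cfg: FocalLossConfig) -> Tensor:
    """Mean focal loss over a batch; ``labels`` are integer class indices."""
    probs = as_tensor(probs)
    labels = np.asarray(labels)
    m = probs.shape[0]
    p_true = probs[np.arange(m), labels].clip(_EPS, 1.0)
    focal = (1.0 - p_true).pow(cfg.gamma) * p_true.log()
    return (-cfg.alpha) * focal.mean()


def focal_loss_multilabel(probs: Tensor, labels: np.ndarray, cfg: FocalLossConfig) -> Tensor:
    """Per-class focal losses averaged over classes; ``labels`` is a 0/1 matrix."""
    probs = as_tensor(probs)
    labels = np.asarray(labels, dtype=np.float32)
    if labels.shape != probs.shape:
        raise ValueError(f"labels shape {labels.shape} != probs shape {probs.shape}")
    n = probs.shape[1]
    alpha = np.asarray(cfg.alpha_vec, dtype=np.float32)
    if alpha.shape[0] != n:
        raise ValueError(f"alpha_vec has {alpha.shape[0]} entries for {n} classes")
    p = probs * labels + (1.0 - probs) * (1.0 - labels)
    p = p.clip(_EPS, 1.0)
    fl = (1.0 - p).pow(cfg.gamma) * p.log() * Tensor(-alpha)
    # mean over samples within each class, then mean over classes
    return fl.mean(axis=0).mean()
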