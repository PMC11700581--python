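"""TextCNN head and final classifier.

Three parallel valid 1D convolutions (kernel sizes 1, 3 and 5) run over the
fused 128 x 64 feature map; a global max pool keeps the strongest response of
each filter, and the per-kernel vectors are concatenated into a single pooled
vector of 3 x filters entries per branch. The classifier concatenates the two
branch vectors, applies a light dropout, and maps through one fully connected
layer to class scores — softmax for the single-label mode, element-wise
sigmoid for the multi-label mode.
"""

from __future__ import annotations

import numpy as np

from .config import TextCNNConfig
from .nn import Conv1d, Linear, Module, Tensor, adaptive_max_pool, concat

__all__ = ["conv_out_length", "TextCNNHead", "ClassifierHead", "predict_labels"]


def conv_out_length(Lin: int, padding: int, kernelsize: int, stride: int) -> int:
    """Output length of a 1D convolution: floor((Lin + 2p - (k-1) - 1)/s) + 1."""
    Lout = (Lin + 2 * padding - (kernelsize - 1) - 1) // stride + 1
    if Lout <= 0:
        raise ValueError(
            f"convolution over {Lin} positions with kernel {kernelsize}, padding "
            f"{padding}, stride {stride} yields non-positive output length {Lout}"
        )
    return Lout


class TextCNNHead(Module):
    def __init__(self, in_channels: int, cfg: TextCNNConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.convs = [Conv1d(in_channels, cfg.filters, k, rng) for k in cfg.kernel_sizes]

    def forward(self, x: Tensor) -> Tensor:
        """(batch, P, C) -> (batch, 3 * filters) pooled feature vector."""
        pooled = []
        for conv in self.convs:
            y = conv(x).relu()
            pooled.append(adaptive_max_pool(y, 1, axis=-2).reshape(x.shape[0], self.cfg.filters))
        return concat(pooled, axis=-1)

    __call__ = forward


class ClassifierHead(Module):
    def __init__(
        self,
        in_features: int,
        n_classes: int,
        output_mode: str,
        dropout: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        if output_mode not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown output mode {output_mode!r}")
        self.output_mode = output_mode
        self.dropout = dropout
        self.fc = Linear(in_features, n_classes, rng)

    def forward(self, branch_vectors: list[Tensor], rng: np.random.Generator) -> Tensor:
        """Concatenate branch vectors and produce per-class probabilities."""
        x = concat(branch_vectors, axis=-1)
        x = x.dropout(self.dropout, rng, self.training)
        logits = self.fc(x)
        if self.output_mode == "softmax":
            return logits.softmax(axis=-1)
        return logits.sigmoid()

    __call__ = forward


def predict_labels(probs: np.ndarray, output_mode: str, threshold: float = 0.5) -> np.ndarray:
    """Argmax for softmax scores; 0.5-thresholded binary matrix for sigmoid.

    In sigmoid mode a row with no score above threshold falls back to its
    argmax, honoring the at-least-one-compartment convention.
    """
    if output_mode == "softmax":
        return probs.argmax(axis=-1)
    binary = (probs >= threshold).astype(np.int64)
    empty = binary.sum(axis=-1) == 0
    if empty.any():
        binary[empty, probs[empty].argmax(axis=-1)] = 1
    return binary
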