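"""Convolution + adaptive-max-pool (CM) encoder.

Maps an L x 8 encoded sequence to two fixed-size feature maps — one per
convolution-kernel branch (defaults 3 and 5) — via three stages of valid 1D
convolution, ReLU, and adaptive max pooling to 512/256/128 positions. Because
the pool targets are fixed, the output shape (128 positions x 32 channels per
branch) is independent of L: no padding, no truncation.

Feature maps are held positions-first, i.e. (..., positions, channels); the
channels x positions view of the same array is a transpose.
"""

from __future__ import annotations

import numpy as np

from .config import CMConfig
from .nn import Conv1d, Module, Tensor, adaptive_max_pool, ragged_adaptive_max_pool

__all__ = ["adaptive_maxpool", "cm_stage", "CMEncoder"]


def adaptive_maxpool(x: Tensor | np.ndarray, target: int) -> Tensor:
    """Adaptive max-pool over the positions axis (second-to-last).

    Bin ``i`` covers input positions ``floor(i*L/target)`` through
    ``ceil((i+1)*L/target) - 1`` (0-based, half-open); each output position is
    the max over its bin. Bins repeat elements when L < target.
    """
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float32))
    if x.ndim == 1:
        return adaptive_max_pool(x.reshape(-1, 1), target, axis=-2).reshape(-1)
    return adaptive_max_pool(x, target, axis=-2)


def cm_stage(x: Tensor, conv: Conv1d, pool_target: int) -> Tensor:
    """One CM stage: valid convolution, ReLU, adaptive max-pool.

    (..., L, C_in) -> (..., pool_target, filters). Requires L >= kernel.
    """
    if x.shape[-2] < conv.kernel:
        raise ValueError(
            f"input of {x.shape[-2]} positions is shorter than the kernel {conv.kernel}"
        )
    return adaptive_maxpool(conv(x).relu(), pool_target)


class CMEncoder(Module):
    """Dual-branch three-stage CM encoder.

    ``forward`` accepts a list of per-sequence L x 8 matrices (lengths may all
    differ) and returns one (batch, pool_targets[2], stage_filters[2]) tensor
    per kernel branch. Stage 1 convolves a zero-padded batch and pools each
    sample over its own valid positions (padding never enters a pooling bin);
    later stages are fully batched since every sequence occupies
    pool_targets[0] positions after stage 1. Dropout follows each stage's
    activation.
    """

    def __init__(self, cfg: CMConfig, rng: np.random.Generator, in_channels: int = 8):
        super().__init__()
        self.cfg = cfg
        self.branches = []
        for k in cfg.kernel_sizes:
            convs = [
                Conv1d(in_channels, cfg.stage_filters[0], k, rng),
                Conv1d(cfg.stage_filters[0], cfg.stage_filters[1], k, rng),
                Conv1d(cfg.stage_filters[1], cfg.stage_filters[2], k, rng),
            ]
            self.branches.append(_Branch(convs))

    def forward(self, encodings: list[np.ndarray], rng: np.random.Generator) -> list[Tensor]:
        """Encode a batch of variable-length L x 8 matrices; one output per branch."""
        if not encodings:
            raise ValueError("empty batch")
        min_len = min(e.shape[0] for e in encodings)
        max_kernel = max(self.cfg.kernel_sizes)
        if min_len < max_kernel:
            raise ValueError(f"sequence of length {min_len} shorter than kernel {max_kernel}")
        # pad to a common length; stage 1 convolves the padded batch at once
        # and the ragged pool restricts each sample's bins to its own length
        lengths = np.array([e.shape[0] for e in encodings])
        Lmax = int(lengths.max())
        padded = np.zeros((len(encodings), Lmax, encodings[0].shape[1]), dtype=np.float32)
        for i, e in enumerate(encodings):
            padded[i, : e.shape[0]] = e
        x0 = Tensor(padded)
        outputs = []
        p = self.cfg.dropout
        for branch in self.branches:
            conv = branch.convs[0]
            y = ragged_adaptive_max_pool(
                conv(x0).relu(), lengths - conv.kernel + 1, self.cfg.pool_targets[0]
            )
            y = y.dropout(p, rng, self.training)
            y = cm_stage(y, branch.convs[1], self.cfg.pool_targets[1]).dropout(p, rng, self.training)
            y = cm_stage(y, branch.convs[2], self.cfg.pool_targets[2]).dropout(p, rng, self.training)
            outputs.append(y)
        return outputs

    __call__ = forward


class _Branch(Module):
    def __init__(self, convs: list[Conv1d]):
        super().__init__()
        self.convs = convs
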