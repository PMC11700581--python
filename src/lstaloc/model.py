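"""Full localization network.

Pipeline per input sequence (any length >= the largest CM kernel):

    L x 8 encoding
      -> dual-branch CM encoder (kernels 3 and 5)     -> 2 x (128 x 32)
      -> per branch: LSTA block  ||  Bi-LSTM           -> 128 x 32 each
      -> per branch: fuse [LSTA ; BiLSTM]              -> 128 x 64
      -> per branch: TextCNN + global max pool         -> 192
      -> concat branches -> dropout -> fully connected -> n_classes

Each convolution branch owns its own LSTA/Bi-LSTM/TextCNN tower; only the
pooled vectors are concatenated before the output layer.
"""

from __future__ import annotations

import numpy as np

from .bilstm import BiLSTMEncoder, fuse
from .cm import CMEncoder
from .config import ModelConfig
from .lsta import LSTABlock
from .nn import Module, Tensor
from .textcnn import ClassifierHead, TextCNNHead, predict_labels

__all__ = ["LocalizationNetwork"]


class _BranchTower(Module):
    def __init__(self, width: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.lsta = LSTABlock(width, cfg.lsta, rng)
        self.bilstm = BiLSTMEncoder(width, cfg.bilstm, rng)
        fused_width = width + 2 * cfg.bilstm.hidden_size
        self.textcnn = TextCNNHead(fused_width, cfg.textcnn, rng)

    def forward(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        att = self.lsta(x, rng)
        rec = self.bilstm(x, rng)
        return self.textcnn(fuse(att, rec))

    __call__ = forward


class LocalizationNetwork(Module):
    """End-to-end classifier over variable-length encoded sequences."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.cm = CMEncoder(cfg.cm, rng)
        width = cfg.cm.stage_filters[2]
        self.towers = [_BranchTower(width, cfg, rng) for _ in cfg.cm.kernel_sizes]
        pooled = len(cfg.textcnn.kernel_sizes) * cfg.textcnn.filters
        self.head = ClassifierHead(
            len(cfg.cm.kernel_sizes) * pooled,
            cfg.n_classes,
            cfg.output_mode,
            cfg.textcnn.output_dropout,
            rng,
        )
        self.head.fc.weight.data *= cfg.head_init_gain
        # dropout noise source, reseedable for reproducible training runs
        self._dropout_rng = np.random.default_rng(seed + 1)

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)

    def forward(self, encodings: list[np.ndarray]) -> Tensor:
        """Batch of L x 8 matrices -> (batch, n_classes) probabilities."""
        rng = self._dropout_rng
        branch_maps = self.cm(encodings, rng)
        vectors = [tower(x, rng) for tower, x in zip(self.towers, branch_maps)]
        return self.head(vectors, rng)

    __call__ = forward

    def predict_proba(self, encodings: list[np.ndarray], batch_size: int = 128) -> np.ndarray:
        """Evaluation-mode probabilities, computed in mini-batches."""
        was_training = self.training
        self.eval()
        try:
            out = [
                self.forward(encodings[i : i + batch_size]).data
                for i in range(0, len(encodings), batch_size)
            ]
        finally:
            self.train(was_training)
        return np.concatenate(out, axis=0)

    def predict(self, encodings: list[np.ndarray], batch_size: int = 128) -> np.ndarray:
        return predict_labels(self.predict_proba(encodings, batch_size), self.cfg.output_mode)
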