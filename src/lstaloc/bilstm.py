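"""Bidirectional LSTM pathway and fusion with the attention output.

The forward and backward recurrences use independent parameters; the
per-position output concatenates both directions (2 x hidden wide). With the
default hidden size 16 over the 128 x 32 interface this yields 128 x 32,
which is then fused with the LSTA output into 128 x 64 by channel-wise
concatenation in the fixed order [attention ; recurrent].
"""

from __future__ import annotations

import numpy as np

from .config import BiLSTMConfig
from .nn import LSTM, Module, Tensor, concat, stack

__all__ = ["BiLSTMEncoder", "fuse"]


class BiLSTMEncoder(Module):
    def __init__(self, input_size: int, cfg: BiLSTMConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        # one grouped recurrence: group 0 = forward, group 1 = backward
        self.lstm = LSTM(input_size, cfg.hidden_size, rng, groups=2)

    def forward(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        """(batch, P, C) -> (batch, P, 2 * hidden)."""
        both = stack([x, x[:, ::-1, :]], axis=0)
        hs = self.lstm(both)
        out = concat([hs[0], hs[1][:, ::-1, :]], axis=-1)
        return out.dropout(self.cfg.dropout, rng, self.training)

    __call__ = forward


def fuse(lsta_out: Tensor, bilstm_out: Tensor) -> Tensor:
    """Channel-wise concatenation per position, order [LSTA ; BiLSTM]."""
    if lsta_out.shape[:-1] != bilstm_out.shape[:-1]:
        raise ValueError(
            f"position counts differ: {lsta_out.shape[:-1]} vs {bilstm_out.shape[:-1]}"
        )
    return concat([lsta_out, bilstm_out], axis=-1)
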