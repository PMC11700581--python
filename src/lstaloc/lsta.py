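"""Long-short term attention (LSTA).

Multi-head attention in which each query position attends simultaneously to

* **short-term keys** — the positions in its own non-overlapping window of
  width ``w`` (with the default 128-position interface and ``w = 128`` this is
  full attention), capturing fine-grained local correlations, and
* **long-term keys** — ``r`` summary rows obtained by a *dynamic projection*:
  a learned score matrix of shape P x r, softmaxed over positions, projects
  the full key/value set onto rank <= r.

A dual-normalization step applies separate layer norms to the short and the
projected long key/value sets before they are concatenated, compensating for
the scale mismatch between the two branches. Attention logits are scaled by
1/sqrt(d_k); dropout acts on the attention probabilities during training.

The model width 32 with 6 heads does not divide evenly; each head uses key
width d_k = 6 and a final learned projection maps the 36 concatenated head
outputs back to width 32.
"""

from __future__ import annotations

import numpy as np

from .config import LSTAConfig
from .nn import LayerNorm, Linear, Module, Tensor, concat, uniform_init

__all__ = ["short_term_context", "dynamic_projection", "LSTABlock"]


def short_term_context(positions: int, window: int) -> list[tuple[int, int]]:
    """Half-open segment boundaries of the short-term attention windows.

    Positions are split into consecutive segments of length ``window`` (the
    final segment may be shorter); every query attends exactly the keys of its
    own segment. With ``window >= positions`` there is a single segment and
    short-term attention equals full attention.
    """
    if positions < 1:
        raise ValueError("need at least one position")
    return [(s, min(s + window, positions)) for s in range(0, positions, window)]


def dynamic_projection(K: Tensor, V: Tensor, score_weight: Tensor) -> tuple[Tensor, Tensor]:
    """Project keys/values (..., P, d_k) onto r summary rows (..., r, d_k).

    ``score_weight`` (..., d_k, r) produces a P x r score matrix from the keys;
    a softmax over the position axis turns each of its r columns into a
    weighting of positions, and the projected keys/values are the weighted
    position averages ``proj^T K`` and ``proj^T V``.
    """
    scores = K @ score_weight  # (..., P, r)
    proj = scores.softmax(axis=-2)  # column-stochastic over positions
    projT = proj.transpose(*range(proj.ndim - 2), proj.ndim - 1, proj.ndim - 2)
    return projT @ K, projT @ V


class LSTABlock(Module):
    def __init__(self, width: int, cfg: LSTAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.width = width
        H, dk = cfg.heads, cfg.head_width
        bound = 1.0 / np.sqrt(width)
        self.Wq = uniform_init(rng, (width, H * dk), bound)
        self.Wk = uniform_init(rng, (width, H * dk), bound)
        self.Wv = uniform_init(rng, (width, H * dk), bound)
        if cfg.projection_rank > 0:
            self.Wp = uniform_init(rng, (H, dk, cfg.projection_rank), 1.0 / np.sqrt(dk))
        self.ln_short = LayerNorm(dk)
        self.ln_long = LayerNorm(dk)
        self.out = Linear(H * dk, width, rng)

    def dual_norm(self, short_branch: tuple[Tensor, Tensor], long_branch: tuple[Tensor, Tensor]):
        """Separate learned layer norms for the short and long key/value sets."""
        ks, vs = short_branch
        kl, vl = long_branch
        return (self.ln_short(ks), self.ln_short(vs)), (self.ln_long(kl), self.ln_long(vl))

    def forward(
        self,
        x: Tensor,
        rng: np.random.Generator,
        return_weights: bool = False,
    ):
        """(batch, P, width) -> (batch, P, width)."""
        if x.shape[-1] != self.width:
            raise ValueError(f"expected width {self.width}, got {x.shape[-1]}")
        B, P, _ = x.shape
        H, dk, r = self.cfg.heads, self.cfg.head_width, self.cfg.projection_rank

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, P, H, dk).transpose(0, 2, 1, 3)  # (B, H, P, dk)

        q = split_heads(x @ self.Wq)
        k = split_heads(x @ self.Wk)
        v = split_heads(x @ self.Wv)

        if r > 0:
            k_long, v_long = dynamic_projection(k, v, self.Wp)
            (k_short, v_short), (k_long, v_long) = self.dual_norm((k, v), (k_long, v_long))
        else:
            # single branch: no scale mismatch to reconcile, vanilla attention
            k_short, v_short = k, v
            k_long = v_long = None

        scale = 1.0 / np.sqrt(dk)
        seg_outputs = []
        weights = []
        for s, e in short_term_context(P, self.cfg.window):
            q_seg = q[:, :, s:e, :]
            if k_long is not None:
                keys = concat([k_short[:, :, s:e, :], k_long], axis=2)
                vals = concat([v_short[:, :, s:e, :], v_long], axis=2)
            else:
                keys = k_short[:, :, s:e, :]
                vals = v_short[:, :, s:e, :]
            logits = (q_seg @ keys.transpose(0, 1, 3, 2)) * scale
            attn = logits.softmax(axis=-1)  # rows sum to 1 pre-dropout
            if return_weights:
                weights.append(attn.data.copy())
            attn = attn.dropout(self.cfg.dropout, rng, self.training)
            seg_outputs.append(attn @ vals)
        heads = seg_outputs[0] if len(seg_outputs) == 1 else concat(seg_outputs, axis=2)
        merged = heads.transpose(0, 2, 1, 3).reshape(B, P, H * dk)
        y = self.out(merged)
        if return_weights:
            return y, weights
        return y

    __call__ = forward
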