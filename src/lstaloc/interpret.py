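"""Occlusion attribution: which positions drive a compartment prediction.

A sliding window of residues is replaced by N (the all-zero encoding, the
same convention used for ambiguous residues) and the drop in the model's
target-class probability relative to the intact sequence is recorded. Each
position's score is the mean drop over the windows covering it. Positive
scores mark positions whose presence supports the target compartment.

Defaults: window 15 (the length of the longest repertoire motif), stride 1.
All occluded variants share the sequence's length, so they are scored in
batched forward passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import NucleotideSequence, encode_combined
from .model import LocalizationNetwork

__all__ = ["AttributionTrack", "occlusion_attribution", "write_attribution_tsv", "top_windows_bed"]


@dataclass
class AttributionTrack:
    id: str
    scores: np.ndarray  # per-position mean probability drop, length L
    window: int
    stride: int
    target_class: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("attribution scores must be finite")


def occlusion_attribution(
    model: LocalizationNetwork,
    seq: NucleotideSequence,
    window: int = 15,
    stride: int = 1,
    target_class: int = 0,
    batch_size: int = 128,
) -> AttributionTrack:
    L = seq.length
    if window < 1 or window > L:
        raise ValueError(f"window {window} invalid for sequence of length {L}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    enc = encode_combined(seq).matrix
    baseline = float(model.predict_proba([enc])[0, target_class])
    starts = list(range(0, L - window + 1, stride))
    variants = []
    for s in starts:
        occluded = enc.copy()
        occluded[s : s + window, :] = 0.0  # N rows
        variants.append(occluded)
    probs = model.predict_proba(variants, batch_size=batch_size)[:, target_class]
    drops = baseline - probs
    total = np.zeros(L, dtype=np.float64)
    cover = np.zeros(L, dtype=np.int64)
    for s, d in zip(starts, drops):
        total[s : s + window] += d
        cover[s : s + window] += 1
    scores = np.where(cover > 0, total / np.maximum(cover, 1), 0.0)
    return AttributionTrack(
        id=seq.id, scores=scores, window=window, stride=stride, target_class=target_class
    )


def write_attribution_tsv(track: AttributionTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tscore\n")
        for i, s in enumerate(track.scores):
            fh.write(f"{i}\t{s:.6g}\n")


def top_windows_bed(
    track: AttributionTrack, path: str | Path, n_windows: int = 5
) -> None:
    """Export the highest-scoring occlusion windows as 0-based half-open BED."""
    L = track.scores.shape[0]
    w = track.window
    means = np.array([track.scores[s : s + w].mean() for s in range(0, L - w + 1)])
    order = np.argsort(means)[::-1][:n_windows]
    with open(path, "w") as fh:
        for rank, s in enumerate(order):
            fh.write(f"{track.id}\t{s}\t{s + w}\twindow_{rank}\t{means[s]:.6g}\n")
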