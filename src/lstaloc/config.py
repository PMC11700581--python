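"""Hyperparameter configuration for the localization network.

Defaults follow the reference architecture: dual convolution branches
(kernels 3 and 5) through three conv + adaptive-max-pool stages
(64/64/32 filters pooled to 512/256/128 positions), a 6-head long-short term
attention block (window 128, projection rank 4) in parallel with a
bidirectional LSTM (hidden 16), TextCNN heads (kernels 1/3/5) and a single
fully connected output layer. Training defaults: AdamW, learning rate 2e-4,
weight decay 1e-3, batch 256, multi-class focal loss with gamma = 2.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = [
    "CMConfig",
    "LSTAConfig",
    "BiLSTMConfig",
    "TextCNNConfig",
    "FocalLossConfig",
    "TrainConfig",
    "ModelConfig",
    "GridSpec",
]


@dataclass
class CMConfig:
    kernel_sizes: tuple[int, int] = (3, 5)
    stage_filters: tuple[int, int, int] = (64, 64, 32)
    pool_targets: tuple[int, int, int] = (512, 256, 128)
    dropout: float = 0.5

    def __post_init__(self):
        if len(self.stage_filters) != 3 or len(self.pool_targets) != 3:
            raise ValueError("exactly three conv/pool stages are required")
        if not (self.pool_targets[0] > self.pool_targets[1] > self.pool_targets[2]):
            raise ValueError("pool targets must be strictly decreasing")


@dataclass
class LSTAConfig:
    heads: int = 6
    window: int = 128
    projection_rank: int = 4
    head_width: int = 6  # per-head key width d_k; model width 32 / 6 heads rounded up
    dropout: float = 0.65

    def __post_init__(self):
        if self.window < 1 or self.projection_rank < 0 or self.heads < 1:
            raise ValueError("invalid attention configuration")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("attention dropout must be in [0, 1)")


@dataclass
class BiLSTMConfig:
    hidden_size: int = 16
    dropout: float = 0.5


@dataclass
class TextCNNConfig:
    kernel_sizes: tuple[int, int, int] = (1, 3, 5)
    filters: int = 64
    padding: int = 0
    stride: int = 1
    output_dropout: float = 0.05

    def __post_init__(self):
        if len(self.kernel_sizes) != 3:
            raise ValueError("exactly three TextCNN kernel sizes are required")


@dataclass
class FocalLossConfig:
    alpha: float = 1.0
    gamma: float = 2.0
    # per-class alpha for the multi-label mode, matched to
    # (nucleus, exosome, cytosol, ribosome, membrane, ER)
    alpha_vec: tuple[float, ...] = (0.4, 0.03, 0.92, 0.6, 0.9, 0.95)


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    weight_decay: float = 1e-3
    beta2: float = 0.999  # second-moment decay; 0.99 suits short schedules
    schedule: str = "constant"  # constant | onecycle (warmup + cosine decay)
    head_lr_scale: float = 1.0  # lr multiplier for the output layer
    grad_clip: float = 0.0  # global gradient-norm clip; 0 disables
    batch_size: int = 256
    epochs: int = 60
    patience: int = 10
    eval_every: int = 1  # validate every k-th epoch (and always the last)
    eval_from: int = 0  # first epoch eligible for validation/model selection
    # stop once validation macro F1 reaches this level (0 = train full budget);
    # purely a compute saver — the kept checkpoint is already above the level
    stop_at_macro_f1: float = 0.0
    seed: int = 0


@dataclass
class ModelConfig:
    n_classes: int = 5
    output_mode: str = "softmax"  # softmax (single-label) | sigmoid (multi-label)
    class_names: tuple[str, ...] | None = None
    # init gain of the output layer; larger values strengthen early gradient
    # flow into the feature extractor on short schedules
    head_init_gain: float = 1.0
    cm: CMConfig = field(default_factory=CMConfig)
    lsta: LSTAConfig = field(default_factory=LSTAConfig)
    bilstm: BiLSTMConfig = field(default_factory=BiLSTMConfig)
    textcnn: TextCNNConfig = field(default_factory=TextCNNConfig)
    loss: FocalLossConfig = field(default_factory=FocalLossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if self.output_mode not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown output mode {self.output_mode!r}")
        if self.n_classes < 2:
            raise ValueError("need at least two output classes")

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        sub = {
            "cm": CMConfig,
            "lsta": LSTAConfig,
            "bilstm": BiLSTMConfig,
            "textcnn": TextCNNConfig,
            "loss": FocalLossConfig,
            "train": TrainConfig,
        }
        kwargs: dict = {}
        for key, value in d.items():
            if key in sub and isinstance(value, dict):
                klass = sub[key]
                tupled = {
                    f.name: tuple(value[f.name])
                    if isinstance(value.get(f.name), list)
                    else value[f.name]
                    for f in fields(klass)
                    if f.name in value
                }
                kwargs[key] = klass(**tupled)
            elif key == "class_names" and isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GridSpec:
    """Axes of the hyperparameter grid search.

    Kernel sizes are paired-branch combinations (k, k+2) rather than two
    independent axes, so the dual-branch structure is preserved.
    """

    batch_sizes: tuple[int, ...] = (128, 256, 512)
    kernel_sizes: tuple[int, ...] = (3, 4, 5, 6, 7)
    kernel_counts: tuple[int, ...] = (32, 64, 128)
    pool_sizes: tuple[int, ...] = (64, 128, 256)
    attention_heads: tuple[int, ...] = (2, 4, 6, 8)

    def __post_init__(self):
        for name in ("batch_sizes", "kernel_sizes", "kernel_counts", "pool_sizes", "attention_heads"):
            if not getattr(self, name):
                raise ValueError(f"grid axis {name} is empty")
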