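"""Canonical configurations for reproducible experiments.

``reference_config`` carries the published architecture and training
settings (learning rate 2e-4, batch 256, the full dropout scheme) meant for
long schedules on benchmark-scale data.

``short_schedule_config`` is the package's configuration for compact
synthetic-data runs of at most ~20 epochs: same architecture, but light
regularization and a faster, decaying learning rate. The planted-motif
datasets are small and carry no label noise, so the heavy dropout of the
reference setting — tuned for a larger, noisy benchmark over hundreds of
epochs — only slows convergence there.
"""

from __future__ import annotations

from .config import (
    BiLSTMConfig,
    CMConfig,
    LSTAConfig,
    ModelConfig,
    TextCNNConfig,
    TrainConfig,
)

__all__ = ["reference_config", "short_schedule_config"]


def reference_config(n_classes: int = 5, output_mode: str = "softmax") -> ModelConfig:
    return ModelConfig(n_classes=n_classes, output_mode=output_mode)


def short_schedule_config(
    n_classes: int = 5,
    output_mode: str = "softmax",
    epochs: int = 20,
    seed: int = 0,
) -> ModelConfig:
    return ModelConfig(
        n_classes=n_classes,
        output_mode=output_mode,
        head_init_gain=10.0,
        cm=CMConfig(dropout=0.0),
        lsta=LSTAConfig(dropout=0.0),
        bilstm=BiLSTMConfig(dropout=0.0),
        textcnn=TextCNNConfig(output_dropout=0.0),
        train=TrainConfig(
            learning_rate=3e-3,
            beta2=0.99,
            schedule="constant",
            batch_size=16,
            epochs=epochs,
            patience=epochs,
            eval_every=3,
            eval_from=6,
            stop_at_macro_f1=0.95,
            seed=seed,
        ),
    )
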