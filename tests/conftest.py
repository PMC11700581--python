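import numpy as np
import pytest

from lstaloc.config import (
    BiLSTMConfig,
    CMConfig,
    LSTAConfig,
    ModelConfig,
    TextCNNConfig,
    TrainConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_model_config(n_classes: int = 5, output_mode: str = "softmax") -> ModelConfig:
    """A shrunken architecture with the same structure, for fast unit tests."""
    return ModelConfig(
        n_classes=n_classes,
        output_mode=output_mode,
        cm=CMConfig(kernel_sizes=(3, 5), stage_filters=(8, 8, 8), pool_targets=(64, 32, 16)),
        lsta=LSTAConfig(heads=2, window=16, projection_rank=2, head_width=4, dropout=0.1),
        bilstm=BiLSTMConfig(hidden_size=4, dropout=0.1),
        textcnn=TextCNNConfig(filters=8),
        train=TrainConfig(batch_size=8, epochs=2, patience=5, seed=0),
    )


@pytest.fixture
def small_config():
    return small_model_config()
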