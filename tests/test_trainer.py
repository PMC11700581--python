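import numpy as np
import pytest

from conftest import small_model_config
from lstaloc.config import GridSpec
from lstaloc.model import LocalizationNetwork
from lstaloc.simulate import ClassSpec, SyntheticSpec, generate_dataset
from lstaloc.trainer import (
    SequenceDataset,
    cross_validate,
    load_checkpoint,
    save_checkpoint,
    stratified_kfold,
    train,
)

NAMES = ("Nucleus", "Exosome", "Cytoplasm", "Cytosol", "Ribosome")


def tiny_dataset(per_class=8, seed=0, n_classes=2, length=(60, 120), prob=1.0):
    motifs = ["TTTTTTTTTTTTTTTT", "ACACACACACACACA", "CTCAGCCTCCC", "GGCTAAGGCTAAGGC",
              "CGTTCGAACGTTCGA"]
    spec = SyntheticSpec(
        classes=tuple(
            ClassSpec(name=NAMES[i], count=per_class, length_range=length,
                      motifs=((motifs[i], prob),))
            for i in range(n_classes)
        ),
        seed=seed,
    )
    seqs, labels = generate_dataset(spec)
    return SequenceDataset.from_sequences(seqs, labels, NAMES[:n_classes])


# -- stratified folds ---------------------------------------------------------


def test_stratified_fold_sizes_842():
    """842 samples split 5 ways -> sizes {169, 169, 168, 168, 168}."""
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 5, 842)
    folds = stratified_kfold(labels, k=5, seed=1)
    sizes = sorted(len(f) for f in folds)
    assert sizes == [168, 168, 168, 169, 169]
    assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(842))


def test_stratification_balances_classes_and_is_deterministic():
    labels = np.repeat(np.arange(3), [10, 25, 40])
    a = stratified_kfold(labels, k=5, seed=7)
    b = stratified_kfold(labels, k=5, seed=7)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa, fb)
    for fold in a:
        counts = np.bincount(labels[fold], minlength=3)
        np.testing.assert_array_equal(counts, [2, 5, 8])
    # 10 samples of one class across 5 folds -> exactly 2 per fold
    ten = stratified_kfold(np.zeros(10, dtype=int), k=5, seed=0)
    assert all(len(f) == 2 for f in ten)


def test_stratified_kfold_rejects_rare_classes():
    labels = np.array([0, 0, 0, 1])
    with pytest.raises(ValueError):
        stratified_kfold(labels, k=3, seed=0)
    with pytest.raises(ValueError):
        stratified_kfold(np.zeros(3, dtype=int), k=5, seed=0)


# -- training loop ------------------------------------------------------------


def test_zero_learning_rate_leaves_parameters_unchanged():
    cfg = small_model_config(n_classes=2)
    cfg.train.learning_rate = 0.0
    cfg.train.weight_decay = 0.0
    cfg.train.epochs = 1
    ds = tiny_dataset()
    model = LocalizationNetwork(cfg, seed=3)
    before = {k: v.copy() for k, v in model.state_dict().items()}
    train(model, ds, ds, cfg)
    after = model.state_dict()
    for key in before:
        np.testing.assert_array_equal(before[key], after[key])


def test_training_reduces_loss_on_separable_toy():
    """A compositionally separable two-class toy is learned in a few epochs."""
    from lstaloc.features import LabelRecord, NucleotideSequence

    rng = np.random.default_rng(5)
    seqs, recs = [], []
    for i in range(48):
        cls = i % 2
        alphabet = list("AAAC") if cls == 0 else list("TTTG")
        s = "".join(rng.choice(alphabet, size=int(rng.integers(60, 120))))
        seqs.append(NucleotideSequence(id=f"s{i}", residues=s))
        recs.append(LabelRecord(id=f"s{i}", label=NAMES[cls]))
    ds = SequenceDataset.from_sequences(seqs, recs, NAMES[:2])
    cfg = small_model_config(n_classes=2)
    cfg.train.learning_rate = 3e-3
    cfg.train.epochs = 6
    cfg.train.batch_size = 8
    cfg.train.patience = 6
    model = LocalizationNetwork(cfg, seed=1)
    result = train(model, ds, ds, cfg)
    losses = [h["train_loss"] for h in result.history]
    assert losses[-1] < losses[0]
    assert result.best_valid_macro_f1 >= 0.8


def test_same_seed_reproduces_history_exactly():
    cfg = small_model_config(n_classes=2)
    cfg.train.epochs = 2
    ds = tiny_dataset(per_class=5)
    histories = []
    for _ in range(2):
        model = LocalizationNetwork(cfg, seed=cfg.train.seed)
        histories.append(train(model, ds, ds, cfg).history)
    assert histories[0] == histories[1]


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_divergence_aborts_with_diagnostic():
    cfg = small_model_config(n_classes=2)
    cfg.train.learning_rate = 1e6  # forces non-finite loss quickly
    cfg.train.epochs = 3
    ds = tiny_dataset(per_class=4)
    model = LocalizationNetwork(cfg, seed=0)
    with pytest.raises(FloatingPointError):
        train(model, ds, ds, cfg)


# -- cross-validation and checkpoints ----------------------------------------


def test_cross_validate_shapes_and_summary():
    cfg = small_model_config(n_classes=2)
    cfg.train.epochs = 1
    ds = tiny_dataset(per_class=8)
    result = cross_validate(ds, cfg, k=2)
    assert len(result.fold_reports) == 2
    stats = result.mean_sd()
    assert set(stats) >= {"acc", "macro_f1", "mi_auc"}
    for mean, sd in stats.values():
        assert sd >= 0
    summary = result.summary()
    assert all("±" in v for v in summary.values())


def test_multilabel_training_round(tmp_path):
    """Sigmoid-mode model trains end to end on multi-label synthetic data."""
    from lstaloc.simulate import MultiLabelSpec, generate_multilabel_dataset

    spec = MultiLabelSpec(
        class_names=("nucleus", "exosome"), priors=(0.6, 0.6), count=16,
        motifs=("TTTTTTTTTTTTTTTT", "ACACACACACACACA"), planting_prob=1.0,
        length_range=(60, 120), seed=3,
    )
    seqs, labels = generate_multilabel_dataset(spec)
    ds = SequenceDataset.from_sequences(seqs, labels, ("nucleus", "exosome"))
    assert ds.labels.shape == (16, 2)
    cfg = small_model_config(n_classes=2, output_mode="sigmoid")
    cfg.loss.alpha_vec = (0.5, 0.5)
    cfg.train.epochs = 2
    model = LocalizationNetwork(cfg, seed=0)
    result = train(model, ds, ds, cfg)
    assert len(result.history) == 2
    preds = model.predict(ds.encodings)
    assert preds.shape == (16, 2)
    assert set(np.unique(preds)) <= {0, 1}


def test_checkpoint_round_trip_reproduces_predictions(tmp_path):
    cfg = small_model_config(n_classes=2)
    ds = tiny_dataset(per_class=4)
    model = LocalizationNetwork(cfg, seed=5)
    model.eval()
    before = model.predict_proba(ds.encodings)
    save_checkpoint(model, tmp_path / "ckpt.npz")
    restored = load_checkpoint(tmp_path / "ckpt.npz")
    after = restored.predict_proba(ds.encodings)
    np.testing.assert_array_equal(before, after)


def test_grid_search_returns_best_config_and_leaderboard():
    from lstaloc.trainer import grid_search

    base = small_model_config(n_classes=2)
    base.train.epochs = 1
    ds = tiny_dataset(per_class=6)
    grid = GridSpec(batch_sizes=(8,), kernel_sizes=(3,), kernel_counts=(8,),
                    pool_sizes=(16,), attention_heads=(2,))
    best, leaderboard = grid_search(ds, base, grid, budget=1, k=2)
    assert len(leaderboard) == 1
    assert best.train.batch_size == 8
    assert 0.0 <= leaderboard[0][1] <= 1.0  # cross-validated macro F1


def test_grid_spec_validation_and_config_enumeration():
    from lstaloc.trainer import _grid_configs

    with pytest.raises(ValueError):
        GridSpec(batch_sizes=())
    base = small_model_config()
    grid = GridSpec(batch_sizes=(16,), kernel_sizes=(3,), kernel_counts=(8,),
                    pool_sizes=(16,), attention_heads=(2,))
    configs = list(_grid_configs(base, grid))
    assert len(configs) == 1
    cfg = configs[0]
    assert cfg.cm.kernel_sizes == (3, 5)  # paired-branch kernels
    assert cfg.cm.pool_targets == (64, 32, 16)
    assert cfg.lsta.heads == 2
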