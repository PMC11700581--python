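"""Training loop, stratified cross-validation and hyperparameter grid search.

Optimization uses AdamW on the focal loss (multi-class or multi-label,
depending on the model's output mode). Model selection within a run keeps the
checkpoint with the best validation macro F1; early stopping monitors the
same quantity. All randomness (fold assignment, batch shuffling, parameter
initialization, dropout) derives from explicit integer seeds, so a run is
reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import GridSpec, ModelConfig
from .features import EncodedSequence, LabelRecord, NucleotideSequence, encode_combined
from .losses import focal_loss_multiclass, focal_loss_multilabel
from .metrics import MetricsReport, compute_report, confusion_counts, macro_f1
from .model import LocalizationNetwork
from .textcnn import predict_labels

__all__ = [
    "SequenceDataset",
    "stratified_kfold",
    "train",
    "cross_validate",
    "grid_search",
    "CVResult",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class SequenceDataset:
    """Encoded sequences with labels ready for training.

    ``labels`` is an integer vector (single-label) or a 0/1 matrix
    (multi-label); ``class_names`` fixes the label vocabulary and its order.
    """

    ids: list[str]
    encodings: list[np.ndarray]
    labels: np.ndarray
    class_names: tuple[str, ...]

    @classmethod
    def from_sequences(
        cls,
        sequences: list[NucleotideSequence],
        label_records: list[LabelRecord],
        class_names: tuple[str, ...],
    ) -> "SequenceDataset":
        by_id = {r.id: r for r in label_records}
        missing = [s.id for s in sequences if s.id not in by_id]
        if missing:
            raise ValueError(f"sequences without labels: {missing[:5]}")
        encs = [encode_combined(s).matrix for s in sequences]
        first = by_id[sequences[0].id]
        if first.label is not None:
            index = {name: i for i, name in enumerate(class_names)}
            labels = np.array([index[by_id[s.id].label] for s in sequences], dtype=np.int64)
        else:
            labels = np.array([by_id[s.id].multilabel for s in sequences], dtype=np.int64)
        return cls(
            ids=[s.id for s in sequences],
            encodings=encs,
            labels=labels,
            class_names=tuple(class_names),
        )

    def __len__(self) -> int:
        return len(self.encodings)

    def subset(self, indices: np.ndarray) -> "SequenceDataset":
        return SequenceDataset(
            ids=[self.ids[i] for i in indices],
            encodings=[self.encodings[i] for i in indices],
            labels=self.labels[indices],
            class_names=self.class_names,
        )

    def strata(self) -> np.ndarray:
        """Labels usable for stratification (single label, or first active one)."""
        if self.labels.ndim == 1:
            return self.labels
        return self.labels.argmax(axis=1)


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified fold assignment; returns k test-index arrays.

    Fold sizes differ by at most one, as do per-class counts across folds.
    """
    labels = np.asarray(labels)
    if k > labels.shape[0]:
        raise ValueError(f"cannot make {k} folds from {labels.shape[0]} samples")
    small = [c for c, n in zip(*np.unique(labels, return_counts=True)) if n < k]
    if small:
        raise ValueError(f"classes with fewer than {k} members: {small}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros_like(labels), labels)]


@dataclass
class TrainResult:
    history: list[dict]
    best_state: dict
    best_epoch: int
    best_valid_macro_f1: float


def _loss_fn(model: LocalizationNetwork, probs, labels):
    if model.cfg.output_mode == "softmax":
        return focal_loss_multiclass(probs, labels, model.cfg.loss)
    return focal_loss_multilabel(probs, labels, model.cfg.loss)


def _valid_macro_f1(model: LocalizationNetwork, ds: SequenceDataset, batch_size: int) -> tuple[float, np.ndarray]:
    probs = model.predict_proba(ds.encodings, batch_size=batch_size)
    preds = predict_labels(probs, model.cfg.output_mode)
    counts = confusion_counts(ds.labels, preds, len(ds.class_names))
    return macro_f1(counts), probs


def train(
    model: LocalizationNetwork,
    train_data: SequenceDataset,
    valid_data: SequenceDataset,
    cfg: ModelConfig,
    log_fn=None,
) -> TrainResult:
    """Optimize the focal loss; keep the best-validation-macro-F1 checkpoint.

    The best state is loaded back into ``model`` before returning. Raises on
    divergence (non-finite loss).
    """
    from .nn import AdamW

    rng = np.random.default_rng(cfg.train.seed)
    model.reseed_dropout(cfg.train.seed + 1)
    named = model.named_parameters()
    scales = [
        cfg.train.head_lr_scale if name.startswith("head.") else 1.0 for name, _ in named
    ]
    opt = AdamW(
        [p for _, p in named],
        lr=cfg.train.learning_rate,
        betas=(0.9, cfg.train.beta2),
        weight_decay=cfg.train.weight_decay,
        lr_scales=scales,
    )
    n = len(train_data)
    bs = min(cfg.train.batch_size, n)
    steps_per_epoch = (n + bs - 1) // bs
    total_steps = max(1, cfg.train.epochs * steps_per_epoch)
    warmup = max(1, total_steps // 10)
    base_lr = cfg.train.learning_rate

    def lr_at(step: int) -> float:
        if cfg.train.schedule == "constant":
            return base_lr
        if cfg.train.schedule == "onecycle":
            if step < warmup:
                return base_lr * (step + 1) / warmup
            frac = (step - warmup) / max(1, total_steps - warmup)
            return base_lr * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * min(frac, 1.0))))
        if cfg.train.schedule == "flat_cosine":
            flat_until = int(0.7 * total_steps)
            if step < flat_until:
                return base_lr
            frac = (step - flat_until) / max(1, total_steps - flat_until)
            return base_lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * min(frac, 1.0))))
        raise ValueError(f"unknown schedule {cfg.train.schedule!r}")

    history: list[dict] = []
    best_state = model.state_dict()
    best_f1 = -1.0
    best_epoch = -1
    stale = 0
    for epoch in range(cfg.train.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, bs):
            opt.lr = lr_at(opt.t)
            idx = order[start : start + bs]
            probs = model([train_data.encodings[i] for i in idx])
            loss = _loss_fn(model, probs, train_data.labels[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(f"training diverged at epoch {epoch} (loss={value})")
            model.zero_grad()
            loss.backward()
            if cfg.train.grad_clip > 0:
                norm = np.sqrt(
                    sum(float(np.sum(p.grad**2)) for p in opt.params if p.grad is not None)
                )
                if norm > cfg.train.grad_clip:
                    scale = cfg.train.grad_clip / norm
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad = p.grad * scale
            opt.step()
            epoch_loss += value
            nb += 1
        last = epoch == cfg.train.epochs - 1
        if (epoch < cfg.train.eval_from or epoch % cfg.train.eval_every != 0) and not last:
            history.append({"epoch": epoch, "train_loss": epoch_loss / nb})
            if log_fn is not None:
                log_fn(history[-1])
            continue
        valid_f1, _ = _valid_macro_f1(model, valid_data, batch_size=max(bs, 64))
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / nb, "valid_macro_f1": valid_f1}
        )
        if log_fn is not None:
            log_fn(history[-1])
        if valid_f1 > best_f1:
            best_f1 = valid_f1
            best_epoch = epoch
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.train.patience:
                break
        if cfg.train.stop_at_macro_f1 > 0 and best_f1 >= cfg.train.stop_at_macro_f1:
            break
    model.load_state_dict(best_state)
    return TrainResult(
        history=history, best_state=best_state, best_epoch=best_epoch, best_valid_macro_f1=best_f1
    )


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    fold_indices: list[np.ndarray]
    models: list[LocalizationNetwork] = field(default_factory=list)

    def mean_sd(self) -> dict[str, tuple[float, float]]:
        """Per-metric mean and standard deviation across folds ("x ± y")."""
        keys = [k for k in self.fold_reports[0].to_dict() if k != "per_class_counts"]
        out = {}
        for key in keys:
            vals = np.array([r.to_dict()[key] for r in self.fold_reports], dtype=float)
            out[key] = (float(vals.mean()), float(vals.std()))
        return out

    def summary(self) -> dict[str, str]:
        return {k: f"{m:.3f} ± {s:.3f}" for k, (m, s) in self.mean_sd().items()}


def cross_validate(
    dataset: SequenceDataset,
    cfg: ModelConfig,
    k: int = 5,
    keep_models: bool = False,
) -> CVResult:
    """k rounds of train/evaluate over a stratified split."""
    folds = stratified_kfold(dataset.strata(), k=k, seed=cfg.train.seed)
    all_idx = np.arange(len(dataset))
    reports: list[MetricsReport] = []
    models: list[LocalizationNetwork] = []
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = LocalizationNetwork(cfg, seed=cfg.train.seed + 1000 * fold_no)
        train(model, dataset.subset(train_idx), dataset.subset(test_idx), cfg)
        test = dataset.subset(test_idx)
        probs = model.predict_proba(test.encodings)
        preds = predict_labels(probs, cfg.output_mode)
        reports.append(compute_report(probs, test.labels, preds))
        if keep_models:
            models.append(model)
    return CVResult(fold_reports=reports, fold_indices=list(folds), models=models)


def _grid_configs(base: ModelConfig, grid: GridSpec):
    """Exhaustive configs in declared axis order (batch, kernel, count, pool, heads)."""
    for bs in grid.batch_sizes:
        for k in grid.kernel_sizes:
            for count in grid.kernel_counts:
                for pool in grid.pool_sizes:
                    for heads in grid.attention_heads:
                        d = base.to_dict()
                        d["train"]["batch_size"] = bs
                        # paired-branch kernels (k, k+2), mirroring the 3+5 default
                        d["cm"]["kernel_sizes"] = (k, k + 2)
                        d["cm"]["stage_filters"] = (count, count, base.cm.stage_filters[2])
                        d["cm"]["pool_targets"] = (4 * pool, 2 * pool, pool)
                        d["lsta"]["heads"] = heads
                        d["lsta"]["window"] = pool
                        yield ModelConfig.from_dict(d)


def grid_search(
    dataset: SequenceDataset,
    base_cfg: ModelConfig,
    grid: GridSpec,
    budget: int | None = None,
    k: int = 5,
) -> tuple[ModelConfig, list[tuple[dict, float]]]:
    """Evaluate grid points by cross-validated macro F1.

    Returns the best config and a leaderboard of (config dict, score).
    Points are visited in declared axis order and truncated at ``budget``;
    ties keep the earliest (lexicographically first) config.
    """
    leaderboard: list[tuple[dict, float]] = []
    best_cfg: ModelConfig | None = None
    best_score = -np.inf
    for i, cfg in enumerate(_grid_configs(base_cfg, grid)):
        if budget is not None and i >= budget:
            break
        result = cross_validate(dataset, cfg, k=k)
        score = result.mean_sd()["macro_f1"][0]
        leaderboard.append((cfg.to_dict(), score))
        if score > best_score:
            best_score = score
            best_cfg = cfg
    if best_cfg is None:
        raise ValueError("empty grid")
    return best_cfg, leaderboard


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: LocalizationNetwork, path: str | Path) -> None:
    """Write weights (npz) next to a YAML copy of the config."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    model.cfg.to_yaml(path.with_suffix(".yaml"))


def load_checkpoint(path: str | Path) -> LocalizationNetwork:
    path = Path(path)
    cfg = ModelConfig.from_yaml(path.with_suffix(".yaml"))
    model = LocalizationNetwork(cfg, seed=cfg.train.seed)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model
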