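"""Stratified splitting and the deterministic seeded training loop.

Defaults mirror the study configuration: Adam, initial learning rate 1e-4,
batch size 32, 150 epochs, cross-entropy loss, and a per-class 8:2
train/test split.  Note that test accuracy is tracked during training
(the test set doubles as a validation set); there is no third held-out
set, so per-epoch test accuracy is an optimistically monitored quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _nn
from .resnet import ModelSpec, NumpyModel, materialize
from .signal_io import CLASSES

__all__ = [
    "TrainConfig",
    "SplitResult",
    "stratified_split",
    "train_model",
    "run_variant_comparison",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimizer and loop configuration (defaults per the study setup)."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 150
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "cross-entropy"

    def __post_init__(self):
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross-entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class SplitResult:
    """Disjoint train/test index sets with per-class bookkeeping."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    per_class_counts: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        train, test = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")


def stratified_split(labels: Sequence[str], ratio: float = 0.8, seed: int = 0) -> SplitResult:
    """Per-class random split; the first ``floor(ratio * n)`` of each
    class's shuffled indices go to training, the rest to testing.

    The floor-on-the-train-side rule reproduces the study's published
    per-class allocation exactly (e.g. 1841 -> 1472/369, 328 -> 262/66).
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()), key=lambda c: (CLASSES.index(c) if c in CLASSES else len(CLASSES), c))
    rng = np.random.default_rng(seed)
    train_parts, test_parts, rows = [], [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls!r} has no samples")
        idx = rng.permutation(idx)
        n_train = int(np.floor(ratio * idx.size))
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
        rows.append({"class": cls, "n_total": idx.size, "n_train": n_train, "n_test": idx.size - n_train})
    counts = pd.DataFrame(rows).set_index("class")
    counts.loc["Total"] = counts.sum()
    return SplitResult(
        train_indices=np.sort(np.concatenate(train_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
        per_class_counts=counts,
    )


def train_model(
    spec: ModelSpec,
    images: np.ndarray,
    targets: np.ndarray,
    cfg: TrainConfig,
    eval_images: np.ndarray | None = None,
    eval_targets: np.ndarray | None = None,
    callback: Callable[[int, float, float], None] | None = None,
) -> tuple[NumpyModel, pd.DataFrame]:
    """Train a materialized ``spec`` on (N, S, S) float images.

    Returns the trained model and a history frame with one row per epoch:
    mean training loss and accuracy on the evaluation set (the training
    set itself when no evaluation set is given).  With ``epochs == 0`` the
    initialized model is returned untouched with an empty history.  The
    run is deterministic for fixed seed, data and config on one machine.
    """
    images = np.asarray(images, dtype=_nn.DEFAULT_DTYPE)
    if images.ndim != 3 or images.shape[1] != images.shape[2]:
        raise ValueError(f"images must be (N, S, S), got {images.shape}")
    if images.shape[0] == 0:
        raise ValueError("no training images")
    targets = np.asarray(targets, dtype=np.int64)
    if eval_images is None:
        eval_images, eval_targets = images, targets
    else:
        eval_images = np.asarray(eval_images, dtype=_nn.DEFAULT_DTYPE)
        eval_targets = np.asarray(eval_targets, dtype=np.int64)
        if eval_images.shape[1:] != images.shape[1:]:
            raise ValueError(
                f"evaluation image size {eval_images.shape[1:]} != training size {images.shape[1:]}"
            )

    model = materialize(spec, seed=cfg.seed)
    opt = _nn.Adam(model.param_slots(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    n = images.shape[0]
    rows = []
    for epoch in range(cfg.epochs):
        model.train_mode(True)
        order = shuffle_rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            batch = order[i : i + cfg.batch_size]
            loss = model.loss_and_grad(images[batch][:, None, :, :], targets[batch])
            opt.step()
            losses.append(loss)
        acc = float((model.predict(eval_images) == eval_targets).mean())
        mean_loss = float(np.mean(losses))
        rows.append({"epoch": epoch + 1, "loss": mean_loss, "test_acc": acc})
        if callback is not None:
            callback(epoch + 1, mean_loss, acc)
        log.info("epoch %d/%d loss %.4f test_acc %.3f", epoch + 1, cfg.epochs, mean_loss, acc)
    history = pd.DataFrame(rows, columns=["epoch", "loss", "test_acc"])
    model.train_mode(False)
    return model, history


def run_variant_comparison(
    images: np.ndarray,
    targets: np.ndarray,
    variants: Mapping[str, ModelSpec],
    cfg: TrainConfig,
    split: SplitResult | None = None,
    seeds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Train each variant on one shared split and tabulate test accuracy.

    With several ``seeds`` the table reports mean and standard deviation
    over runs; otherwise a single accuracy per variant, mirroring the
    network-comparison experiment design.
    """
    if len(variants) < 2:
        raise ValueError("need at least 2 variants to compare")
    if split is None:
        split = stratified_split([str(t) for t in targets], ratio=0.8, seed=cfg.seed)
    tr, te = split.train_indices, split.test_indices
    seeds = list(seeds) if seeds is not None else [cfg.seed]
    rows = []
    for name, spec in variants.items():
        accs = []
        for seed in seeds:
            run_cfg = TrainConfig(
                learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                epochs=cfg.epochs, seed=seed,
            )
            model, _ = train_model(
                spec, images[tr], targets[tr], run_cfg,
                eval_images=images[te], eval_targets=targets[te],
            )
            accs.append(float((model.predict(images[te]) == targets[te]).mean()))
        rows.append(
            {
                "network": name,
                "accuracy": float(np.mean(accs)),
                "accuracy_sd": float(np.std(accs)) if len(accs) > 1 else np.nan,
                "n_seeds": len(accs),
            }
        )
    return pd.DataFrame(rows, columns=["network", "accuracy", "accuracy_sd", "n_seeds"])
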