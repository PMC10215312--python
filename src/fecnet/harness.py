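"""Training and cross-validation orchestration.

Defaults mirror the reference protocol: Adam, learning rate 1e-4, batch
size 8, 130 epochs, 224×224 inputs, five folds.  One master seed fans out to
weight initialization, shuffling and augmentation.  Folds are split before
augmentation so a variant can never land in a different fold than its
source image.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .backbone import Network, build_network, preset_config, scheme_config
from .data import (
    AugmentationPlan,
    DatasetInventory,
    ImageFolderDataset,
    augment_image,
    kfold_split,
)
from .nn import Adam, Tensor, cross_entropy

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "train_model",
    "evaluate_model",
    "cross_validate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class RunConfig:
    """CLI-facing experiment configuration (defaults = reference protocol)."""

    model: str = "mc_scmnet"  # preset name or "scheme<N>"
    optimizer: str = "adam"
    learning_rate: float = 0.0001
    batch_size: int = 8
    epochs: int = 130
    image_size: int = 224
    folds: int = 5
    seed: int = 0
    num_classes: int = 4
    base_width: int = 64
    stem_channels: int = 64
    stage_depths: tuple[int, int, int, int] = (3, 4, 6, 3)
    augment: bool = False
    data_root: str | None = None

    def network_config(self):
        over = dict(
            base_width=self.base_width,
            stem_channels=self.stem_channels,
            stage_depths=tuple(self.stage_depths),
        )
        if self.model.startswith("scheme"):
            return scheme_config(int(self.model[len("scheme"):]),
                                 num_classes=self.num_classes, **over)
        return preset_config(self.model, num_classes=self.num_classes, **over)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stage_depths"] = list(d["stage_depths"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["stage_depths"] = tuple(d["stage_depths"])
        return cls(**d)


def save_checkpoint(model: Network, path, epoch: int = 0) -> None:
    state = model.state_dict()
    np.savez(path, __epoch__=np.array(epoch), **state)


def load_checkpoint(model: Network, path) -> int:
    with np.load(path) as data:
        state = {k: data[k] for k in data.files if k != "__epoch__"}
        epoch = int(data["__epoch__"]) if "__epoch__" in data.files else 0
    model.load_state_dict(state)
    return epoch


def _iter_batches(dataset, indices, batch_size, rng, augment_plan=None, aug_rng=None):
    order = rng.permutation(indices)
    for start in range(0, len(order), batch_size):
        chunk = order[start : start + batch_size]
        xs, ys = [], []
        for i in chunk:
            x, y = dataset[int(i)]
            if augment_plan is not None and aug_rng.random() < 0.5:
                hwc = x.transpose(1, 2, 0)
                hwc, _ = augment_image(hwc, augment_plan, aug_rng)
                x = hwc.transpose(2, 0, 1)
            xs.append(x)
            ys.append(y)
        yield np.stack(xs), np.array(ys)


def evaluate_model(model: Network, dataset, indices, batch_size: int = 8):
    """(accuracy in [0,1], mean loss, predicted labels) on ``indices``."""
    model.eval()
    preds, losses = [], []
    indices = np.asarray(indices)
    for start in range(0, len(indices), batch_size):
        chunk = indices[start : start + batch_size]
        xs = np.stack([dataset[int(i)][0] for i in chunk])
        ys = np.array([dataset[int(i)][1] for i in chunk])
        logits = model(Tensor(xs))
        losses.append(cross_entropy(logits, ys).item() * len(chunk))
        preds.extend(np.argmax(logits.data, axis=1).tolist())
    preds = np.array(preds)
    labels = np.array([dataset[int(i)][1] for i in indices])
    acc = float((preds == labels).mean()) if len(labels) else 0.0
    return acc, float(np.sum(losses) / max(len(indices), 1)), preds


def train_model(
    model: Network,
    dataset,
    train_idx,
    val_idx=None,
    epochs: int = 2,
    learning_rate: float = 1e-4,
    batch_size: int = 8,
    seed: int = 0,
    augment_plan: AugmentationPlan | None = None,
    log_path=None,
    start_epoch: int = 0,
) -> list[dict]:
    """Cross-entropy training with Adam; returns per-epoch log rows."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    aug_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    opt = Adam(model.parameters(), lr=learning_rate)
    rows: list[dict] = []
    for epoch in range(start_epoch + 1, start_epoch + epochs + 1):
        model.train()
        t0 = time.time()
        total_loss, total_correct, total_n = 0.0, 0, 0
        for xs, ys in _iter_batches(
            dataset, np.asarray(train_idx), batch_size, rng, augment_plan, aug_rng
        ):
            logits = model(Tensor(xs))
            loss = cross_entropy(logits, ys)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += loss.item() * len(ys)
            total_correct += int((np.argmax(logits.data, axis=1) == ys).sum())
            total_n += len(ys)
        row = {
            "epoch": epoch,
            "train_loss": total_loss / total_n,
            "train_acc": total_correct / total_n,
            "seconds": round(time.time() - t0, 2),
        }
        if val_idx is not None and len(val_idx):
            val_acc, val_loss, _ = evaluate_model(model, dataset, val_idx, batch_size)
            row["val_loss"] = val_loss
            row["val_acc"] = val_acc
        rows.append(row)
        log.info("epoch %d: %s", epoch, row)
    if log_path is not None:
        write_log_csv(rows, log_path)
    return rows


def write_log_csv(rows: list[dict], path, append: bool = False) -> None:
    if not rows:
        return
    keys = list(rows[0].keys())
    mode = "a" if append and Path(path).exists() else "w"
    with open(path, mode, newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        if mode == "w":
            writer.writeheader()
        writer.writerows(rows)


def cross_validate(
    make_model,
    dataset,
    folds: int = 5,
    epochs: int = 1,
    learning_rate: float = 1e-4,
    batch_size: int = 8,
    seed: int = 0,
    augment_plan: AugmentationPlan | None = None,
) -> dict:
    """K-fold protocol: per-fold accuracy and their arithmetic mean."""
    splits = kfold_split(len(dataset), folds=folds, seed=seed)
    fold_rows = []
    for f, (train_idx, test_idx) in enumerate(splits, start=1):
        nn.set_seed(seed + f)
        model = make_model()
        train_model(
            model, dataset, train_idx,
            epochs=epochs, learning_rate=learning_rate,
            batch_size=batch_size, seed=seed + f, augment_plan=augment_plan,
        )
        acc, loss, _ = evaluate_model(model, dataset, test_idx, batch_size)
        fold_rows.append(
            {"fold": f, "test_acc": acc, "test_loss": loss,
             "test_indices": test_idx.tolist()}
        )
        log.info("fold %d: acc=%.4f", f, acc)
    mean_acc = float(np.mean([r["test_acc"] for r in fold_rows]))
    return {"folds": fold_rows, "mean_acc": mean_acc, "seed": seed}
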