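"""Optimisation loop, learning-rate schedule, and cross-validation.

The schedule reproduces the published protocol: SGD with momentum 0.9 and
weight decay 5e-4, base learning rate 1e-3 reached through a half-cosine
warm-up across the first epoch (starting at base_lr/1000), then multiplied
by gamma = 0.1 at the milestone epochs 50 and 75.  Batches are 10 patients,
zero-padded to equal instance count; augmentation runs on the training path
only.  The best model is selected by validation AUROC, ties breaking toward
the earlier epoch.

Every stochastic component (bag shuffling, augmentation draws, weight init)
draws from a named substream of the single experiment seed, so repeat runs
are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import stream, substream_seed
from .bags import Bag, CohortSplit, augment, collate_batch, load_bag_images
from .metrics import (
    DEFAULT_THRESHOLD,
    MetricsReport,
    auroc,
    compute_report,
    summarize_folds,
    youden_threshold,
)
from .model import MILModel, ModelConfig, bag_loss, save_checkpoint
from .nn import SGD

__all__ = ["TrainConfig", "FoldResult", "CVResult", "lr_at", "train_fold",
           "score_bags", "run_cv"]


@dataclass
class TrainConfig:
    base_lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 5e-4
    warmup_epochs: int = 1
    warmup_factor: float = 1e-3
    milestones: tuple[int, ...] = (50, 75)
    gamma: float = 0.1
    epochs: int = 100
    batch_bags: int = 10
    seed: int = 0

    def __post_init__(self):
        ms = tuple(self.milestones)
        if any(b <= a for a, b in zip(ms, ms[1:])):
            raise ValueError("milestones must be strictly increasing")
        if ms and ms[-1] >= self.epochs:
            raise ValueError("milestones must lie before the final epoch")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        if self.epochs < 1 or self.batch_bags < 1:
            raise ValueError("epochs and batch_bags must be positive")


def lr_at(step: int, steps_per_epoch: int, config: TrainConfig) -> float:
    """Learning rate at a global optimisation step.

    During the warm-up epoch(s) the rate follows a half-cosine ease-in from
    ``base_lr * warmup_factor`` to ``base_lr``; afterwards it is
    ``base_lr * gamma**(number of passed milestones)``.
    """
    if step < 0:
        raise ValueError("step must be nonnegative")
    warm_steps = config.warmup_epochs * steps_per_epoch
    if step < warm_steps:
        t = step / warm_steps
        lo = config.base_lr * config.warmup_factor
        return lo + (config.base_lr - lo) * 0.5 * (1.0 - math.cos(math.pi * t))
    epoch = step // steps_per_epoch
    decays = sum(1 for m in config.milestones if epoch >= m)
    return config.base_lr * config.gamma**decays


@dataclass
class FoldResult:
    fold_index: int
    best_epoch: int
    best_val_auroc: float
    history: list[dict]
    checkpoint_path: Path | None = None
    state_dict: dict = field(default_factory=dict, repr=False)
    threshold: float = DEFAULT_THRESHOLD
    model: MILModel | None = field(default=None, repr=False)


def score_bags(model: MILModel, bags: list[Bag], batch_bags: int = 10
               ) -> tuple[np.ndarray, np.ndarray, list]:
    """Evaluation-mode malignancy scores for a list of loaded bags.

    Returns (scores, labels, predictions) aligned with ``bags``.
    """
    preds = []
    for start in range(0, len(bags), batch_bags):
        batch = collate_batch(bags[start:start + batch_bags])
        preds.extend(model.predict(batch))
    scores = np.array([p.malignancy_score for p in preds])
    labels = np.array([b.label for b in bags])
    return scores, labels, preds


def train_fold(train_bags: list[Bag], val_bags: list[Bag],
               config: TrainConfig, model_config: ModelConfig,
               fold_index: int = 0, out_dir: str | Path | None = None,
               ) -> FoldResult:
    """Train one model, selecting the best epoch by validation AUROC."""
    if not train_bags or not val_bags:
        raise ValueError("empty train or val set")
    train_pids = {b.patient_id for b in train_bags}
    if train_pids & {b.patient_id for b in val_bags}:
        raise ValueError("train and val patient sets overlap")
    val_labels = {b.label for b in val_bags}
    if len(val_labels) < 2:
        raise ValueError("AUROC undefined for single-class validation set")

    size = model_config.image_size
    for b in train_bags + val_bags:
        load_bag_images(b, size=size)

    seed = config.seed
    model = MILModel(model_config, seed=seed)
    optimizer = SGD(model.parameters(), momentum=config.momentum,
                    weight_decay=config.weight_decay)
    n_train = len(train_bags)
    steps_per_epoch = math.ceil(n_train / config.batch_bags)

    history: list[dict] = []
    best_epoch, best_auroc, best_state = -1, -np.inf, {}
    global_step = 0
    for epoch in range(config.epochs):
        order = stream(seed, f"shuffle/epoch{epoch}").permutation(n_train)
        aug_rng = stream(seed, f"augment/epoch{epoch}")
        model.train()
        losses = []
        for start in range(0, n_train, config.batch_bags):
            chunk = [train_bags[i] for i in order[start:start + config.batch_bags]]
            aug_bags = [
                dataclasses.replace(
                    b, images=[augment(img, aug_rng) for img in b.images])
                for b in chunk
            ]
            batch = collate_batch(aug_bags)
            probs, _ = model.forward(batch.images, batch.mask)
            loss = bag_loss(probs, batch.labels)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step(lr_at(global_step, steps_per_epoch, config))
            global_step += 1
            losses.append(loss.item())
        scores, labels, _ = score_bags(model, val_bags, config.batch_bags)
        val_auroc = auroc(scores, labels)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_auroc": val_auroc,
                        "lr": lr_at(global_step - 1, steps_per_epoch, config)})
        if val_auroc > best_auroc:  # ties keep the earlier epoch
            best_epoch, best_auroc = epoch, val_auroc
            best_state = model.state_dict()

    result = FoldResult(fold_index=fold_index, best_epoch=best_epoch,
                        best_val_auroc=float(best_auroc), history=history,
                        state_dict=best_state)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"fold{fold_index}_best.npz"
        model.load_state_dict(best_state)
        save_checkpoint(model, path, epoch=best_epoch, val_metric=best_auroc)
        result.checkpoint_path = path
    # leave the model holding its best-epoch weights either way
    model.load_state_dict(best_state)
    result.model = model
    return result


@dataclass
class CVResult:
    folds: list[FoldResult]
    test_reports: list[MetricsReport]
    summary: dict
    test_scores: pd.DataFrame


def run_cv(bags: list[Bag], split: CohortSplit, config: TrainConfig,
           model_config: ModelConfig, out_dir: str | Path | None = None,
           threshold: float | str = DEFAULT_THRESHOLD) -> CVResult:
    """Train one model per fold; evaluate each best checkpoint on the
    held-out test patients; report per-fold and mean +/- sd metrics.

    ``threshold="youden"`` picks each fold's operating point on its own
    validation scores; otherwise the given fixed threshold is used.
    """
    by_pid = {b.patient_id: b for b in bags}
    missing = (split.test_patients |
               set().union(*[tr | va for tr, va in split.folds])) - set(by_pid)
    if missing:
        raise ValueError(f"split names unknown patients: {sorted(missing)[:5]}")
    test_bags = [by_pid[p] for p in sorted(split.test_patients)]
    for b in test_bags:
        load_bag_images(b, size=model_config.image_size)

    folds, reports, rows = [], [], []
    for i, (tr, va) in enumerate(split.folds):
        fold_cfg = replace(config, seed=substream_seed(config.seed, f"fold{i}"))
        result = train_fold([by_pid[p] for p in sorted(tr)],
                            [by_pid[p] for p in sorted(va)],
                            fold_cfg, model_config, fold_index=i,
                            out_dir=None if out_dir is None
                            else Path(out_dir) / "checkpoints")
        model = result.model  # best-epoch weights
        if threshold == "youden":
            v_scores, v_labels, _ = score_bags(
                model, [by_pid[p] for p in sorted(va)], config.batch_bags)
            thr = youden_threshold(v_scores, v_labels)
        else:
            thr = float(threshold)
        result.threshold = thr
        scores, labels, _ = score_bags(model, test_bags, config.batch_bags)
        reports.append(compute_report(scores, labels, threshold=thr, fold_index=i))
        for b, s in zip(test_bags, scores):
            rows.append({"fold": i, "patient_id": b.patient_id,
                         "label": b.label, "malignancy_score": float(s)})
        folds.append(result)

    summary = summarize_folds(reports)
    scores_df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.concat([pd.DataFrame(f.history).assign(fold=f.fold_index)
                   for f in folds]).to_csv(out_dir / "history.csv", index=False)
        scores_df.to_csv(out_dir / "scores.csv", index=False)
        payload = {
            "per_fold": [dataclasses.asdict(r) for r in reports],
            "summary": summary,
            "best_epochs": [f.best_epoch for f in folds],
            "best_val_auroc": [f.best_val_auroc for f in folds],
        }
        (out_dir / "metrics.json").write_text(json.dumps(payload, indent=1))
    return CVResult(folds=folds, test_reports=reports, summary=summary,
                    test_scores=scores_df)
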