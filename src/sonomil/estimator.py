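"""Scikit-learn style estimator front end for the bag classifiers.

``AttentionMILClassifier`` wraps the whole pipeline — backbone, aggregation
variant, training schedule, model selection by validation AUROC — behind the
familiar ``fit`` / ``predict`` / ``predict_proba`` surface, so it composes
with sklearn model selection utilities that accept list-like ``X``.  ``X``
is a list of :class:`~sonomil.bags.Bag` (one per patient); ``y`` defaults to
the bags' own labels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit

from ._rng import substream_seed
from .bags import Bag, load_bag_images
from .metrics import DEFAULT_THRESHOLD
from .model import MILModel, ModelConfig
from .ranking import InstanceRanking, rank_instances
from .training import TrainConfig, score_bags, train_fold

__all__ = ["AttentionMILClassifier"]


class AttentionMILClassifier(ClassifierMixin, BaseEstimator):
    """Patient-level bag classifier with attention (or pooling) aggregation.

    Parameters mirror the training protocol: SGD with momentum and weight
    decay, half-cosine warm-up over the first epoch, step decay at the
    milestone epochs, best epoch chosen by AUROC on an internal stratified
    validation split of ``validation_fraction`` patients.

    Attributes set by :meth:`fit` (trailing underscore): ``model_``,
    ``classes_``, ``history_``, ``best_epoch_``, ``best_val_auroc_``.
    """

    def __init__(self, variant: str = "dual_attention", backbone: str = "tinycnn",
                 image_size: int | None = None, epochs: int = 30,
                 base_lr: float = 1e-3, momentum: float = 0.9,
                 weight_decay: float = 5e-4, warmup_epochs: int = 1,
                 warmup_factor: float = 1e-3, milestones: tuple[int, ...] = (),
                 gamma: float = 0.1, batch_bags: int = 10,
                 validation_fraction: float = 0.2,
                 threshold: float = DEFAULT_THRESHOLD,
                 pretrained_path: str | None = None, random_state: int = 0):
        self.variant = variant
        self.backbone = backbone
        self.image_size = image_size
        self.epochs = epochs
        self.base_lr = base_lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.warmup_epochs = warmup_epochs
        self.warmup_factor = warmup_factor
        self.milestones = milestones
        self.gamma = gamma
        self.batch_bags = batch_bags
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.pretrained_path = pretrained_path
        self.random_state = random_state

    # -- configs --------------------------------------------------------------

    def _train_config(self) -> TrainConfig:
        ms = tuple(m for m in self.milestones if m < self.epochs)
        return TrainConfig(base_lr=self.base_lr, momentum=self.momentum,
                           weight_decay=self.weight_decay,
                           warmup_epochs=self.warmup_epochs,
                           warmup_factor=self.warmup_factor, milestones=ms,
                           gamma=self.gamma, epochs=self.epochs,
                           batch_bags=self.batch_bags, seed=self.random_state)

    def _model_config(self) -> ModelConfig:
        return ModelConfig(variant=self.variant, backbone=self.backbone,
                           image_size=self.image_size,
                           pretrained_path=self.pretrained_path)

    @staticmethod
    def _check_bags(X, y=None) -> list[Bag]:
        bags = list(X)
        if not bags or not all(isinstance(b, Bag) for b in bags):
            raise ValueError("X must be a non-empty list of Bag objects")
        if y is not None:
            y = np.asarray(y, dtype=int)
            if len(y) != len(bags):
                raise ValueError("X and y length mismatch")
            bags = [dataclasses.replace(b, label=int(lbl),
                                        instance_labels=None)
                    if b.label != int(lbl) else b
                    for b, lbl in zip(bags, y)]
        return bags

    # -- sklearn surface ------------------------------------------------------

    def fit(self, X, y=None) -> "AttentionMILClassifier":
        bags = self._check_bags(X, y)
        labels = np.array([b.label for b in bags])
        if len(np.unique(labels)) < 2:
            raise ValueError("need both classes to fit")
        n_val = max(2, int(round(self.validation_fraction * len(bags))))
        sss = StratifiedShuffleSplit(
            n_splits=1, test_size=n_val,
            random_state=substream_seed(self.random_state, "fit/val"))
        (tr_idx, va_idx), = sss.split(labels, labels)
        result = train_fold([bags[i] for i in tr_idx],
                            [bags[i] for i in va_idx],
                            self._train_config(), self._model_config())
        self.model_: MILModel = result.model
        self.classes_ = np.array([0, 1])
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.best_val_auroc_ = result.best_val_auroc
        return self

    def decision_function(self, X) -> np.ndarray:
        """Malignancy scores p(malignant) per bag."""
        self._require_fitted()
        bags = self._check_bags(X)
        for b in bags:
            load_bag_images(b, size=self.model_.config.image_size)
        scores, _, _ = score_bags(self.model_, bags, self.batch_bags)
        return scores

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.column_stack([1.0 - scores, scores])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold).astype(int)

    def attention_rankings(self, X) -> list[InstanceRanking]:
        """Per-bag instance rankings by attention weight (dual attention only)."""
        self._require_fitted()
        return [rank_instances(b, self.model_) for b in self._check_bags(X)]

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def _more_tags(self):
        return {"X_types": ["list"], "non_deterministic": False}
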