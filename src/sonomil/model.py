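"""Bag classifiers: dual-attention aggregation and the Meanpool/Maxpool baselines.

All three variants share the backbone and classifier code path and differ
only in how pooled instance vectors become one bag vector:

* ``dual_attention`` — spatial refinement of each instance's feature map,
  global average pooling, then gated instance attention;
* ``meanpool`` / ``maxpool`` — global average pooling of the raw backbone
  maps followed by a masked channel-wise mean / max over instances (both
  attention sub-modules absent).

Padded instance slots never enter the network: the forward pass gathers the
mask-selected real instances into a flat batch, runs backbone (and spatial
attention), and scatters the pooled vectors back into bag layout, so padding
invariance holds exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from ._rng import stream
from .attention import (
    AttentionWeights,
    GatedInstanceAttention,
    InstanceAttentionConfig,
    SpatialAttention,
    SpatialAttentionConfig,
    pool_instance,
)
from .backbone import build_backbone
from .bags import PaddedBatch
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "BagPrediction",
    "MILModel",
    "aggregate_mean",
    "aggregate_max",
    "classify",
    "bag_loss",
    "forward_bag",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("dual_attention", "meanpool", "maxpool")

# Per-backbone attention profile: (C', tau, D).  The large profile is the
# published one; the small profile scales the projection widths with C.
_PROFILES = {"resnet34": (128, 128.0, 256), "tinycnn": (32, 32.0, 64)}


@dataclass
class ModelConfig:
    variant: str = "dual_attention"
    backbone: str = "tinycnn"
    image_size: int | None = None          # default: 256 (resnet34) / 64 (tinycnn)
    iram: SpatialAttentionConfig | None = None
    isam: InstanceAttentionConfig | None = None
    pretrained_path: str | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.backbone not in _PROFILES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        channels = 512 if self.backbone == "resnet34" else 64
        c_prime, tau, hidden = _PROFILES[self.backbone]
        if self.image_size is None:
            self.image_size = 256 if self.backbone == "resnet34" else 64
        if self.iram is None:
            self.iram = SpatialAttentionConfig(channels=channels, c_prime=c_prime,
                                               tau=tau)
        if self.isam is None:
            self.isam = InstanceAttentionConfig(channels=channels, hidden_dim=hidden)

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class BagPrediction:
    """Class probabilities for one bag; ``malignancy_score`` = P(malignant)."""

    patient_id: str
    probs: np.ndarray
    malignancy_score: float
    alpha: np.ndarray | None = None


class MILModel(nn.Module):
    """Backbone + aggregation + linear softmax classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        init_rng = stream(seed, "init")
        self.backbone = build_backbone(config.backbone, rng=init_rng,
                                       pretrained_path=config.pretrained_path)
        channels = self.backbone.out_channels
        if config.variant == "dual_attention":
            self.iram = SpatialAttention(config.iram, rng=init_rng)
            self.isam = GatedInstanceAttention(config.isam, rng=init_rng)
        self.classifier = nn.Linear(channels, 2, rng=init_rng)

    # -- forward -------------------------------------------------------------

    def forward(self, images: np.ndarray, mask: np.ndarray
                ) -> tuple[Tensor, AttentionWeights | None]:
        """``images``: [B, n_max, 3, H, W]; ``mask``: [B, n_max].

        Returns bag class probabilities [B, 2] and, for the dual-attention
        variant, the instance attention weights.
        """
        b, n_max = mask.shape
        if (mask.sum(axis=1) < 1).any():
            raise ValueError("empty bag: each bag needs at least one real instance")
        flat_mask = np.asarray(mask, dtype=bool).reshape(-1)
        real_idx = np.nonzero(flat_mask)[0]
        flat = np.asarray(images, dtype=np.float32).reshape(
            b * n_max, *images.shape[2:])
        feats = self.backbone(Tensor(flat[real_idx]))

        weights: AttentionWeights | None = None
        if self.config.variant == "dual_attention":
            feats = self.iram(feats)
            vecs = pool_instance(feats)                       # [M_real, C]
            v_bags = _scatter_rows(vecs, real_idx, b * n_max).reshape(
                b, n_max, vecs.shape[1])
            weights, z = self.isam(v_bags, mask)
        else:
            vecs = pool_instance(feats)
            v_bags = _scatter_rows(vecs, real_idx, b * n_max).reshape(
                b, n_max, vecs.shape[1])
            if self.config.variant == "meanpool":
                z = aggregate_mean(v_bags, mask)
            else:
                z = aggregate_max(v_bags, mask)
        logits = self.classifier(z)
        return F.softmax(logits, axis=-1), weights

    def predict(self, batch: PaddedBatch) -> list[BagPrediction]:
        """Evaluation-mode forward pass returning one prediction per bag."""
        was_training = self.training
        self.eval()
        try:
            probs, weights = self.forward(batch.images, batch.mask)
        finally:
            self.train(was_training)
        out = []
        for i, pid in enumerate(batch.patient_ids):
            n_i = int(batch.mask[i].sum())
            alpha = weights.alpha[i, :n_i].copy() if weights is not None else None
            p = probs.data[i]
            out.append(BagPrediction(patient_id=pid, probs=p.copy(),
                                     malignancy_score=float(p[1]), alpha=alpha))
        return out


def _scatter_rows(src: Tensor, index: np.ndarray, n_rows: int) -> Tensor:
    """Place rows of ``src`` at ``index`` in an otherwise-zero [n_rows, C] tensor."""
    out_data = np.zeros((n_rows, src.shape[1]), dtype=src.data.dtype)
    out_data[index] = src.data

    def backward(g):
        return (g[index],)

    return Tensor._from_op(out_data, (src,), backward)


# -- aggregation and classification ops ---------------------------------------

def _as_batched(v, mask):
    t = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64))
    squeeze = t.ndim == 2
    if squeeze:
        t = t.reshape(1, *t.shape)
        mask = np.asarray(mask).reshape(1, -1)
    mask = np.asarray(mask, dtype=t.data.dtype)
    if (mask.sum(axis=1) < 1).any():
        raise ValueError("empty bag")
    return t, mask, squeeze


def aggregate_mean(v, mask) -> Tensor:
    """Masked arithmetic mean over instances: [B, n, C] -> [B, C]."""
    t, m, squeeze = _as_batched(v, mask)
    total = (t * Tensor(m[..., None])).sum(axis=1)
    out = total * Tensor(1.0 / m.sum(axis=1, keepdims=True))
    return out.reshape(out.shape[1]) if squeeze else out


def aggregate_max(v, mask) -> Tensor:
    """Masked channel-wise maximum over instances: [B, n, C] -> [B, C]."""
    t, m, squeeze = _as_batched(v, mask)
    shifted = t + Tensor(((1.0 - m) * -1e9)[..., None])
    out = shifted.max(axis=1)
    return out.reshape(out.shape[1]) if squeeze else out


def classify(z: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Stable softmax of the linear head: probs = softmax(z W + b)."""
    logits = np.asarray(z, dtype=np.float64) @ weight + bias
    logits = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


_EPS = 1e-12  # probability clamp so the loss is never infinite


def bag_loss(predictions, labels) -> Tensor | float:
    """Mean cross-entropy over bags: -(1/N) sum log p_{i, y_i}.

    Accepts either the probability tensor from a forward pass (returns a
    differentiable scalar) or a list of :class:`BagPrediction` (returns a
    float).  True-class probabilities are clamped at 1e-12.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if isinstance(predictions, Tensor):
        if predictions.shape[0] != labels.shape[0]:
            raise ValueError("predictions and labels length mismatch")
        p_true = predictions[np.arange(labels.shape[0]), labels]
        return -(p_true.clip_min(_EPS).log().mean())
    probs = np.stack([p.probs for p in predictions])
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("predictions and labels length mismatch")
    p_true = np.clip(probs[np.arange(len(labels)), labels], _EPS, None)
    return float(-np.mean(np.log(p_true)))


def forward_bag(model: MILModel, batch: PaddedBatch,
                training: bool = False) -> list[BagPrediction]:
    """Run one batch through ``model`` and return per-bag predictions."""
    if training:
        model.train()
        probs, weights = model.forward(batch.images, batch.mask)
        out = []
        for i, pid in enumerate(batch.patient_ids):
            n_i = int(batch.mask[i].sum())
            alpha = weights.alpha[i, :n_i].copy() if weights is not None else None
            p = probs.data[i]
            out.append(BagPrediction(patient_id=pid, probs=p.copy(),
                                     malignancy_score=float(p[1]), alpha=alpha))
        return out
    return model.predict(batch)


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(model: MILModel, path: str | Path, *, epoch: int,
                    val_metric: float) -> None:
    """Single-file checkpoint: parameters + config fingerprint + metadata."""
    meta = {
        "config": asdict(model.config),
        "fingerprint": model.config.fingerprint(),
        "epoch": int(epoch),
        "val_metric": float(val_metric),
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[MILModel, dict]:
    """Rebuild a model from a checkpoint file; returns (model, metadata)."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg_dict = dict(meta["config"])
    iram = cfg_dict.pop("iram", None)
    isam = cfg_dict.pop("isam", None)
    config = ModelConfig(
        **cfg_dict,
        iram=SpatialAttentionConfig(**iram) if iram else None,
        isam=InstanceAttentionConfig(**isam) if isam else None,
    )
    model = MILModel(config)
    model.load_state_dict(state)
    model.eval()
    return model, meta
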