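"""Dual attention: spatial refinement of instance feature maps and gated
instance attention that aggregates a bag into a single vector.

Spatial attention (per instance)
    Three 1x1-convolution projections psi1, psi2, psi3 map the C-channel
    feature map to C' channels.  Queries come from the full-resolution map;
    keys and values from a 0.5x bilinear downsample (corner-excluding
    convention, i.e. 2x2 mean pooling).  The attention matrix

        Psi12 = row_softmax( Q . K / tau ),   Q in [HW, C'], K in [C', HW/4]

    distributes unit attention from every query position over the
    downsampled key positions.  The context Psi12 . V is mapped back to C
    channels by a fourth 1x1 convolution psi4 and added residually to the
    input, so with psi4 zero-initialised the module starts as the identity.

Instance attention (per bag)
    Pooled instance vectors v_j in R^C are scored by a gated mechanism

        a_j = w_c^T ( tanh(W_a v_j) * sigmoid(W_b v_j) ),   W_a, W_b in R^{DxC}

    and normalised with a masked softmax (padded slots get weight exactly
    zero); the bag embedding is z = sum_j alpha_j v_j.

Flattening order of spatial positions is row-major over (H, W); the oracle
tests pin this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "SpatialAttentionConfig",
    "InstanceAttentionConfig",
    "AttentionWeights",
    "SpatialAttention",
    "GatedInstanceAttention",
    "pool_instance",
]

_NEG_INF = -1e9  # additive logit mask; exp underflows to exactly 0 after shift


@dataclass
class SpatialAttentionConfig:
    channels: int = 512        # C, backbone output channels
    c_prime: int = 128         # C', projection width
    tau: float = 128.0         # logit scaling constant
    dropout: float = 0.25
    downsample_scale: float = 0.5  # fixed; recorded for reproducibility

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.downsample_scale != 0.5:
            raise ValueError("only the 0.5x key/value downsample is supported")


@dataclass
class InstanceAttentionConfig:
    channels: int = 512        # C, instance vector length
    hidden_dim: int = 256      # D, gated hidden width
    dropout: float = 0.25


@dataclass
class AttentionWeights:
    """Normalised instance weights with their raw scores and validity mask."""

    alpha: np.ndarray
    raw: np.ndarray
    mask: np.ndarray


class SpatialAttention(nn.Module):
    """Residual non-local spatial attention over one instance's feature map."""

    def __init__(self, config: SpatialAttentionConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c, cp = config.channels, config.c_prime
        self.config = config
        self.psi1 = nn.Conv2d(c, cp, 1, rng=rng)
        self.psi2 = nn.Conv2d(c, cp, 1, rng=rng)
        self.psi3 = nn.Conv2d(c, cp, 1, rng=rng)
        # zero-init so the module starts as the identity (pure residual)
        self.psi4 = nn.Conv2d(cp, c, 1, rng=rng)
        self.psi4.weight.data[:] = 0.0
        self.psi4.bias.data[:] = 0.0
        self.drop = nn.Dropout(config.dropout, rng=np.random.default_rng(
            rng.integers(2**31)))

    def forward(self, x: Tensor, return_attention: bool = False):
        m, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(
                f"spatial attention needs even feature sizes, got {h}x{w}; "
                "use even input dimensions"
            )
        cp = self.config.c_prime
        q = self.psi1(x).reshape(m, cp, h * w).transpose(0, 2, 1)   # [M, HW, C']
        xd = F.avg_pool2d_half(x)                                    # [M, C, H/2, W/2]
        k = self.psi2(xd).reshape(m, cp, (h // 2) * (w // 2))        # [M, C', HW/4]
        v = self.psi3(xd).reshape(m, cp, (h // 2) * (w // 2)).transpose(0, 2, 1)
        logits = (q @ k) * (1.0 / self.config.tau)                   # [M, HW, HW/4]
        attn = F.softmax(logits, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1).reshape(m, cp, h, w)     # [M, C', H, W]
        ctx = self.drop(ctx)
        out = self.psi4(ctx) + x
        if return_attention:
            return out, attn
        return out


class GatedInstanceAttention(nn.Module):
    """Gated attention pooling of instance vectors into a bag embedding."""

    def __init__(self, config: InstanceAttentionConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c, d = config.channels, config.hidden_dim
        self.config = config
        self.w_a = nn.Parameter(rng.normal(0.0, np.sqrt(1.0 / c), (d, c)))
        self.w_b = nn.Parameter(rng.normal(0.0, np.sqrt(1.0 / c), (d, c)))
        # zero-init scoring vector: attention starts uniform (the bag embedding
        # begins as the instance mean) and sharpens only as evidence accrues
        self.w_c = nn.Parameter(np.zeros((d, 1)))
        self.drop = nn.Dropout(config.dropout, rng=np.random.default_rng(
            rng.integers(2**31)))

    def forward(self, v: Tensor, mask: np.ndarray) -> tuple[AttentionWeights, Tensor]:
        """``v``: [B, n, C] pooled instance vectors; ``mask``: [B, n] binaries.

        Returns the attention weights (padded slots exactly zero, real slots
        summing to one per bag) and the bag embeddings z: [B, C].
        """
        squeeze = v.ndim == 2
        if squeeze:
            v = v.reshape(1, *v.shape)
            mask = np.asarray(mask).reshape(1, -1)
        mask = np.asarray(mask, dtype=np.float32)
        if mask.shape != v.shape[:2]:
            raise ValueError(f"mask shape {mask.shape} does not match bags {v.shape[:2]}")
        if (mask.sum(axis=1) < 1).any():
            raise ValueError("empty bag: every bag needs at least one real instance")

        hidden = (v @ self.w_a.T).tanh() * (v @ self.w_b.T).sigmoid()  # [B, n, D]
        hidden = self.drop(hidden)
        raw = hidden @ self.w_c                                        # [B, n, 1]
        # additive mask: real slots get +0, padded slots get -1e9
        logits = raw + Tensor(((1.0 - mask) * _NEG_INF)[..., None])
        alpha = F.softmax(logits, axis=1)                              # [B, n, 1]
        z = (alpha * v).sum(axis=1)                                    # [B, C]

        alpha_np = alpha.data[..., 0]
        raw_np = raw.data[..., 0]
        if squeeze:
            weights = AttentionWeights(alpha=alpha_np[0], raw=raw_np[0], mask=mask[0])
            return weights, z.reshape(z.shape[1])
        return AttentionWeights(alpha=alpha_np, raw=raw_np, mask=mask), z


def pool_instance(h: Tensor) -> Tensor:
    """Global average pooling: [M, C, H, W] feature maps -> [M, C] vectors."""
    if h.ndim != 4:
        raise ValueError(f"expected [M,C,H,W], got shape {h.shape}")
    if not np.isfinite(h.data).all():
        raise ValueError("non-finite values in feature map")
    return F.global_avg_pool(h)
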