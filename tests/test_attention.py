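"""Spatial and instance attention against independent loop-based oracles."""

import numpy as np
import pytest

from sonomil import (
    GatedInstanceAttention,
    InstanceAttentionConfig,
    SpatialAttention,
    SpatialAttentionConfig,
    pool_instance,
)
from sonomil.nn.tensor import Tensor

from conftest import numeric_grad


# ---------------------------------------------------------------------------
# oracles: explicit loops over spatial positions / instances
# ---------------------------------------------------------------------------

def spatial_attention_oracle(h, w1, b1, w2, b2, w3, b3, w4, b4, tau):
    """Loop-based evaluation of the residual spatial attention block.

    ``h``: [C,H,W]; 1x1-conv weights ``wi``: [C_out, C_in, 1, 1].
    """
    c, hh, ww = h.shape
    cp = w1.shape[0]
    # 2x2 mean downsample
    hd = np.zeros((c, hh // 2, ww // 2))
    for ci in range(c):
        for i in range(hh // 2):
            for j in range(ww // 2):
                hd[ci, i, j] = h[ci, 2*i:2*i+2, 2*j:2*j+2].mean()

    def conv1x1(x, w, b):
        co, ci_ = w.shape[:2]
        out = np.zeros((co,) + x.shape[1:])
        for o in range(co):
            for yx in np.ndindex(x.shape[1:]):
                out[(o,) + yx] = np.dot(w[o, :, 0, 0], x[(slice(None),) + yx]) + b[o]
        return out

    q = conv1x1(h, w1, b1).reshape(cp, hh * ww).T          # [HW, C']
    k = conv1x1(hd, w2, b2).reshape(cp, (hh // 2) * (ww // 2))
    v = conv1x1(hd, w3, b3).reshape(cp, (hh // 2) * (ww // 2)).T
    logits = q @ k / tau
    psi = np.zeros_like(logits)
    for p in range(logits.shape[0]):
        e = np.exp(logits[p] - logits[p].max())
        psi[p] = e / e.sum()
    ctx = (psi @ v).T.reshape(cp, hh, ww)
    out = conv1x1(ctx, w4, b4) + h
    return out, psi


def instance_attention_oracle(v, mask, wa, wb, wc):
    """Loop-based gated attention over one bag; ``v``: [n, C]."""
    n = v.shape[0]
    raw = np.zeros(n)
    for j in range(n):
        gate = np.tanh(wa @ v[j]) * (1.0 / (1.0 + np.exp(-(wb @ v[j]))))
        raw[j] = float(wc[:, 0] @ gate)
    real = [j for j in range(n) if mask[j]]
    e = np.exp(raw[real] - max(raw[real]))
    alpha = np.zeros(n)
    alpha[real] = e / e.sum()
    z = sum(alpha[j] * v[j] for j in range(n))
    return alpha, z


def _spatial_module(rng, c=2, cp=1, tau=2.0, channels_kw=None):
    cfg = SpatialAttentionConfig(channels=c, c_prime=cp, tau=tau, dropout=0.0)
    return SpatialAttention(cfg, rng=rng), cfg


class TestSpatialAttention:
    def test_matches_loop_oracle(self, rng):
        mod, cfg = _spatial_module(rng)
        # hand-set (random but explicit) weights, including nonzero psi4
        params = {}
        for name in ("psi1", "psi2", "psi3", "psi4"):
            conv = getattr(mod, name)
            conv.weight.data = rng.normal(size=conv.weight.data.shape).astype(np.float32)
            conv.bias.data = rng.normal(size=conv.bias.data.shape).astype(np.float32)
            params[name] = (conv.weight.data.astype(np.float64),
                            conv.bias.data.astype(np.float64))
        h = rng.normal(size=(2, 4, 4))
        mod.eval()
        out, psi = mod(Tensor(h[None].astype(np.float32)), return_attention=True)
        exp_out, exp_psi = spatial_attention_oracle(
            h, *params["psi1"], *params["psi2"], *params["psi3"], *params["psi4"],
            cfg.tau)
        np.testing.assert_allclose(psi.data[0], exp_psi, atol=1e-5)
        np.testing.assert_allclose(out.data[0], exp_out, atol=1e-5)

    def test_zero_query_gives_uniform_attention(self, rng):
        mod, _ = _spatial_module(rng, c=3, cp=2)
        mod.psi1.weight.data[:] = 0.0
        mod.psi1.bias.data[:] = 0.0
        mod.eval()
        x = Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32))
        _, psi = mod(x, return_attention=True)
        np.testing.assert_allclose(psi.data, 1.0 / 4, atol=1e-6)

    def test_residual_identity_at_zero_init(self, rng):
        # psi4 is zero-initialised, so a fresh module is exactly the identity
        mod, _ = _spatial_module(rng, c=3, cp=2)
        mod.eval()
        x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        out = mod(Tensor(x))
        np.testing.assert_array_equal(out.data, x)

    def test_rows_sum_to_one(self, rng):
        mod, _ = _spatial_module(rng, c=4, cp=3)
        mod.eval()
        x = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        _, psi = mod(x, return_attention=True)
        assert psi.data.min() >= 0.0
        np.testing.assert_allclose(psi.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_odd_spatial_size_rejected(self, rng):
        mod, _ = _spatial_module(rng, c=2, cp=1)
        with pytest.raises(ValueError, match="even"):
            mod(Tensor(np.zeros((1, 2, 3, 4), dtype=np.float32)))


class TestPoolInstance:
    def test_constant_map(self):
        out = pool_instance(Tensor(np.full((1, 3, 2, 2), 7.0)))
        np.testing.assert_allclose(out.data, 7.0)

    def test_small_example(self):
        fm = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 2, 2)
        assert pool_instance(Tensor(fm)).data[0, 0] == pytest.approx(2.5)

    def test_matches_loop_mean(self, rng):
        fm = rng.normal(size=(1, 512, 8, 8))
        out = pool_instance(Tensor(fm)).data[0]
        manual = np.array([fm[0, c].sum() / 64 for c in range(512)])
        np.testing.assert_allclose(out, manual, atol=1e-6)


class TestInstanceAttention:
    def _module(self, rng, c=6, d=4):
        cfg = InstanceAttentionConfig(channels=c, hidden_dim=d, dropout=0.0)
        return GatedInstanceAttention(cfg, rng=rng)

    def test_matches_loop_oracle(self, rng):
        mod = self._module(rng).eval()
        mod.w_c.data = rng.normal(size=mod.w_c.data.shape).astype(np.float32)
        v = rng.normal(size=(5, 6))
        mask = np.array([1, 1, 1, 1, 0], dtype=float)
        weights, z = mod(Tensor(v), mask)
        exp_alpha, exp_z = instance_attention_oracle(
            v, mask, mod.w_a.data.astype(np.float64),
            mod.w_b.data.astype(np.float64), mod.w_c.data.astype(np.float64))
        np.testing.assert_allclose(weights.alpha, exp_alpha, atol=1e-5)
        np.testing.assert_allclose(z.data, exp_z, atol=1e-5)

    def test_identical_vectors_share_weight(self, rng):
        mod = self._module(rng).eval()
        v = np.tile(rng.normal(size=(1, 6)), (3, 1))
        weights, z = mod(Tensor(v), np.ones(3))
        np.testing.assert_allclose(weights.alpha, 1.0 / 3, atol=1e-6)
        np.testing.assert_allclose(z.data, v[0], atol=1e-6)

    def test_singleton_bag(self, rng):
        mod = self._module(rng).eval()
        v = rng.normal(size=(1, 6))
        weights, z = mod(Tensor(v), np.ones(1))
        np.testing.assert_allclose(weights.alpha, [1.0])
        np.testing.assert_allclose(z.data, v[0], atol=1e-6)

    def test_padded_slots_get_exact_zero(self, rng):
        mod = self._module(rng).eval()
        v = rng.normal(size=(4, 6))
        v[2:] = 0.0
        mask = np.array([1, 1, 0, 0], dtype=float)
        weights, _ = mod(Tensor(v), mask)
        assert weights.alpha[2] == 0.0 and weights.alpha[3] == 0.0
        assert weights.alpha[:2].sum() == pytest.approx(1.0, abs=1e-6)

    def test_permutation_equivariance(self, rng):
        mod = self._module(rng).eval()
        mod.w_c.data = rng.normal(size=mod.w_c.data.shape).astype(np.float32)
        v = rng.normal(size=(5, 6))
        perm = np.array([3, 1, 4, 0, 2])
        w1, z1 = mod(Tensor(v), np.ones(5))
        w2, z2 = mod(Tensor(v[perm]), np.ones(5))
        np.testing.assert_allclose(w1.alpha[perm], w2.alpha, atol=1e-5)
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-5)

    def test_empty_bag_rejected(self, rng):
        mod = self._module(rng)
        with pytest.raises(ValueError, match="empty bag"):
            mod(Tensor(np.zeros((3, 6))), np.zeros(3))


class TestDifferentiability:
    def test_end_to_end_gradient_check(self, rng):
        """Spatial + instance attention chain passes a finite-difference check."""
        sp, _ = _spatial_module(rng, c=2, cp=2, tau=3.0)
        for name in ("psi1", "psi2", "psi3", "psi4"):
            conv = getattr(sp, name)
            conv.weight.data = rng.normal(size=conv.weight.data.shape)
            conv.bias.data = rng.normal(size=conv.bias.data.shape)
        ia = GatedInstanceAttention(
            InstanceAttentionConfig(channels=2, hidden_dim=3, dropout=0.0), rng=rng)
        sp.eval(), ia.eval()
        mask = np.ones(2)
        probe = rng.normal(size=2)

        def run(x):
            maps = sp(Tensor(x) if not isinstance(x, Tensor) else x)
            pooled = maps.mean(axis=(2, 3))
            _, z = ia(pooled, mask)
            return z

        x0 = rng.normal(size=(2, 2, 4, 4))

        def f(xa):
            return float(run(xa).data @ probe)

        tx = Tensor(x0, requires_grad=True)
        (run(tx) * Tensor(probe)).sum().backward()
        num = numeric_grad(f, [x0], 0, eps=1e-5)
        denom = np.maximum(np.abs(num), 1e-3)
        assert (np.abs(tx.grad - num) / denom).max() < 1e-3
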