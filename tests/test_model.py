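"""Bag classifier assembly: aggregation ops, loss, variant contracts."""

import math

import numpy as np
import pytest

from sonomil import (
    Bag,
    BagPrediction,
    MILModel,
    ModelConfig,
    aggregate_max,
    aggregate_mean,
    bag_loss,
    classify,
    collate_batch,
    load_checkpoint,
    save_checkpoint,
)
from sonomil.nn import SGD
from sonomil.nn.tensor import Tensor


class TestAggregators:
    def test_mean_two_point(self):
        v = np.array([[1.0], [3.0]])
        assert aggregate_mean(v, np.ones(2)).data[0] == pytest.approx(2.0)

    def test_mean_excludes_padding(self, rng):
        real = rng.normal(size=(1, 4))
        v = np.vstack([real, np.zeros((1, 4))])
        out = aggregate_mean(v, np.array([1.0, 0.0]))
        np.testing.assert_allclose(out.data, real[0], atol=1e-12)

    def test_mean_matches_loop(self, rng):
        v = rng.normal(size=(5, 8))
        out = aggregate_mean(v, np.ones(5)).data
        manual = np.array([sum(v[j, c] for j in range(5)) / 5 for c in range(8)])
        np.testing.assert_allclose(out, manual, atol=1e-12)

    def test_max_basic_and_loop(self, rng):
        v = np.array([[1.0], [3.0]])
        assert aggregate_max(v, np.ones(2)).data[0] == pytest.approx(3.0)
        r = rng.normal(size=(5, 8))
        manual = np.array([max(r[j, c] for j in range(5)) for c in range(8)])
        np.testing.assert_allclose(aggregate_max(r, np.ones(5)).data, manual)

    def test_max_excludes_padded_zeros(self):
        v = np.array([[-3.0, -1.0], [0.0, 0.0]])
        out = aggregate_max(v, np.array([1.0, 0.0]))
        np.testing.assert_allclose(out.data, [-3.0, -1.0])

    @pytest.mark.parametrize("agg", [aggregate_mean, aggregate_max])
    def test_empty_bag_rejected(self, agg):
        with pytest.raises(ValueError, match="empty bag"):
            agg(np.zeros((2, 3)), np.zeros(2))


class TestClassify:
    def test_zero_parameters_give_uniform(self):
        probs = classify(np.zeros(4), np.zeros((4, 2)), np.zeros(2))
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_extreme_logits_stable(self):
        probs = classify(np.zeros(4), np.zeros((4, 2)), np.array([0.0, 1000.0]))
        assert np.isfinite(probs).all()
        np.testing.assert_allclose(probs, [0.0, 1.0], atol=1e-12)

    def test_closed_form(self):
        w = np.zeros((1, 2))
        probs = classify(np.zeros(1), w, np.log([1.0, 3.0]))
        np.testing.assert_allclose(probs, [0.25, 0.75], atol=1e-12)


class TestBagLoss:
    def _pred(self, p1):
        return BagPrediction(patient_id="p", probs=np.array([1 - p1, p1]),
                             malignancy_score=p1)

    def test_perfect_predictions(self):
        assert bag_loss([self._pred(1.0)], [1]) == pytest.approx(0.0)

    def test_uniform_is_ln_two(self):
        preds = [self._pred(0.5), self._pred(0.5)]
        assert bag_loss(preds, [0, 1]) == pytest.approx(math.log(2), abs=1e-12)

    def test_hand_arithmetic(self):
        preds = [self._pred(0.75), self._pred(0.5)]
        expected = (-math.log(0.75) - math.log(0.5)) / 2
        assert bag_loss(preds, [1, 0]) == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_clamped(self):
        loss = bag_loss([self._pred(0.0)], [1])
        assert np.isfinite(loss) and loss > 0

    def test_tensor_path_matches_numpy_path(self, rng):
        probs = rng.dirichlet([1, 1], size=4)
        labels = rng.integers(0, 2, size=4)
        t = bag_loss(Tensor(probs, requires_grad=True), labels)
        preds = [BagPrediction(patient_id=str(i), probs=p,
                               malignancy_score=p[1]) for i, p in enumerate(probs)]
        assert t.item() == pytest.approx(bag_loss(preds, labels), abs=1e-9)

    def test_gradient_step_decreases_loss(self, rng):
        z = Tensor(rng.normal(size=(1, 4)))
        from sonomil import nn
        head = nn.Linear(4, 2, rng=rng)
        opt = SGD(head.parameters(), momentum=0.0)
        from sonomil.nn import functional as F

        def loss_val():
            return bag_loss(F.softmax(head(z), axis=-1), [1])

        before = loss_val()
        opt.zero_grad()
        before.backward()
        opt.step(0.1)
        assert loss_val().item() < before.item()


def _toy_bags(rng, sizes, labels):
    return [Bag(patient_id=f"P{i}", instances=[f"P{i}_{j}" for j in range(n)],
                label=lbl,
                images=[rng.normal(size=(3, 64, 64)).astype(np.float32) * 0.3
                        for _ in range(n)])
            for i, (n, lbl) in enumerate(zip(sizes, labels))]


def _share_common_parts(src: MILModel, dst: MILModel):
    """Copy backbone + classifier weights so only aggregation differs."""
    state = src.state_dict()
    shared = {k: v for k, v in state.items()
              if k.startswith(("backbone.", "classifier."))}
    full = dst.state_dict()
    full.update(shared)
    dst.load_state_dict(full)


class TestForwardBag:
    @pytest.mark.parametrize("variant", ["dual_attention", "meanpool", "maxpool"])
    def test_permutation_invariance(self, rng, variant):
        model = MILModel(ModelConfig(variant=variant), seed=3).eval()
        bags = _toy_bags(rng, [4], [1])
        batch = collate_batch(bags)
        p1, _ = model.forward(batch.images, batch.mask)
        perm = np.array([2, 0, 3, 1])
        p2, _ = model.forward(batch.images[:, perm], batch.mask)
        np.testing.assert_allclose(p1.data, p2.data, atol=1e-5)

    @pytest.mark.parametrize("variant", ["dual_attention", "meanpool", "maxpool"])
    def test_padding_invariance(self, rng, variant):
        model = MILModel(ModelConfig(variant=variant), seed=3).eval()
        bags = _toy_bags(rng, [3], [0])
        batch = collate_batch(bags)
        probs, w = model.forward(batch.images, batch.mask)
        padded_imgs = np.concatenate(
            [batch.images, np.zeros_like(batch.images[:, :2])], axis=1)
        padded_mask = np.concatenate([batch.mask, np.zeros((1, 2))], axis=1)
        probs_p, w_p = model.forward(padded_imgs, padded_mask)
        np.testing.assert_array_equal(probs.data, probs_p.data)
        if w is not None:
            np.testing.assert_array_equal(w.alpha[0], w_p.alpha[0, :3])
            assert np.all(w_p.alpha[0, 3:] == 0.0)

    def test_identical_bags_get_identical_predictions(self, rng):
        model = MILModel(ModelConfig(variant="dual_attention"), seed=0).eval()
        bag = _toy_bags(rng, [3], [1])[0]
        import dataclasses
        twin = dataclasses.replace(bag, patient_id="Q0")
        batch = collate_batch([bag, twin])
        probs, _ = model.forward(batch.images, batch.mask)
        np.testing.assert_allclose(probs.data[0], probs.data[1], atol=1e-7)

    def test_single_instance_collapses_all_variants(self, rng):
        """With one instance and spatial attention at its identity init,
        mean, max and attention aggregation coincide."""
        dual = MILModel(ModelConfig(variant="dual_attention"), seed=5).eval()
        bag = _toy_bags(rng, [1], [1])[0]
        batch = collate_batch([bag])
        outs = [dual.forward(batch.images, batch.mask)[0].data]
        for variant in ("meanpool", "maxpool"):
            other = MILModel(ModelConfig(variant=variant), seed=6).eval()
            _share_common_parts(dual, other)
            outs.append(other.forward(batch.images, batch.mask)[0].data)
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-6)
        np.testing.assert_allclose(outs[0], outs[2], atol=1e-6)

    def test_shared_parts_have_identical_shapes(self):
        models = {v: MILModel(ModelConfig(variant=v), seed=0) for v in
                  ("dual_attention", "meanpool", "maxpool")}
        shapes = {}
        for v, m in models.items():
            shapes[v] = {k: tuple(p.data.shape) for k, p in m.named_parameters()
                         if k.startswith(("backbone.", "classifier."))}
        assert shapes["dual_attention"] == shapes["meanpool"] == shapes["maxpool"]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            ModelConfig(variant="median")


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, rng, tmp_path):
        model = MILModel(ModelConfig(variant="dual_attention"), seed=2).eval()
        bags = _toy_bags(rng, [2, 3], [0, 1])
        batch = collate_batch(bags)
        before = model.forward(batch.images, batch.mask)[0].data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, epoch=7, val_metric=0.91)
        reloaded, meta = load_checkpoint(path)
        assert meta["epoch"] == 7
        assert meta["fingerprint"] == model.config.fingerprint()
        after = reloaded.forward(batch.images, batch.mask)[0].data
        np.testing.assert_allclose(before, after, atol=1e-7)
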