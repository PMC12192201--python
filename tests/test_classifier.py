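"""Global classifier, bag forward, loss and the training loop."""

import numpy as np
import pytest

from foamidl.classifier import (
    BagModel,
    GlobalClassifier,
    Prediction,
    TrainingDiverged,
    ablation_variant,
    bag_forward,
    cross_entropy_loss,
    global_classifier_forward,
    train,
)
from foamidl.patch_proposal import PatchBag
from foamidl.volio import Patch, PatchCoord, ValidationError


def make_bags(rng, n, k=2, width=4, separation=3.0):
    """Labelled toy bags: positive bags shift the first patch's mean."""
    bags = []
    for i in range(n):
        label = i % 2
        patches = []
        for j in range(k):
            data = rng.standard_normal((width, width, width))
            if label == 1 and j == 0:
                data += separation
            patches.append(Patch(PatchCoord((j * width, 0, 0), width), data))
        b = PatchBag(patches=patches, subject_id=f"s{i}")
        b.label = label
        bags.append(b)
    return bags


@pytest.fixture
def toy_model():
    return BagModel.build(k=2, patch_width=4, patchnet_channels=(2, 2, 2, 2),
                          attention_hidden=2, classifier_channels=(2, 2), seed=0)


class TestGlobalClassifier:
    def test_softmax_normalised(self, rng):
        clf = GlobalClassifier(k=3, feature_width=2, conv_channels=(2, 2), rng=rng)
        pred = global_classifier_forward(rng.standard_normal((3, 2, 2, 2)), clf)
        assert pred.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic(self, rng):
        clf = GlobalClassifier(k=2, feature_width=2, conv_channels=(2, 2), rng=rng)
        G = rng.standard_normal((2, 2, 2, 2))
        p1 = global_classifier_forward(G, clf)
        p2 = global_classifier_forward(G, clf)
        assert np.array_equal(p1.logits, p2.logits)

    def test_zero_parameters_symmetric(self, rng):
        clf = GlobalClassifier(k=2, feature_width=2, conv_channels=(2, 2), rng=rng)
        for p in clf.parameters():
            p.data[:] = 0
        pred = global_classifier_forward(rng.standard_normal((2, 2, 2, 2)), clf)
        assert pred.probs == pytest.approx([0.5, 0.5])

    def test_wrong_bag_size(self, rng):
        clf = GlobalClassifier(k=3, feature_width=2, conv_channels=(2, 2))
        with pytest.raises(ValidationError):
            global_classifier_forward(rng.standard_normal((4, 2, 2, 2)), clf)


class TestBagForward:
    def test_pipeline_shape_contract(self, rng):
        model = BagModel.build(k=5, patch_width=12, patchnet_channels=(2, 3, 3, 3),
                               attention_hidden=2, classifier_channels=(4, 2), seed=1)
        bags = make_bags(rng, 1, k=5, width=12)
        pred = bag_forward(bags[0], model)
        assert 0.0 <= pred.prob_positive <= 1.0
        assert pred.logits.shape == (2,)
        assert pred.attention.k == 5

    def test_duplicate_bags_identical(self, toy_model, rng):
        bags = make_bags(rng, 2, separation=0.0)
        bags[1].patches = bags[0].patches  # same subject twice
        p1 = bag_forward(bags[0], toy_model)
        p2 = bag_forward(bags[1], toy_model)
        assert np.array_equal(p1.logits, p2.logits)

    def test_no_attention_flag_uniform_weights(self, rng):
        model = ablation_variant(2, 4, flags=("no_attention",), seed=0,
                                 patchnet_channels=(2, 2, 2, 2),
                                 attention_hidden=2, classifier_channels=(2, 2))
        bag = make_bags(rng, 1)[0]
        pred = bag_forward(bag, model)
        assert pred.probs.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(pred.attention.weights, 0.5)

    def test_bag_size_mismatch(self, toy_model, rng):
        bag = make_bags(rng, 1, k=3)[0]
        with pytest.raises(ValidationError):
            bag_forward(bag, toy_model)


class TestCrossEntropy:
    def _pred(self, p1):
        logit = np.log(p1) - np.log(1 - p1)
        return Prediction(prob_positive=p1, logits=np.array([0.0, logit]))

    def test_perfect_prediction(self):
        assert cross_entropy_loss([self._pred(1 - 1e-12)], [1]) == pytest.approx(0, abs=1e-9)

    def test_chance_is_ln2(self):
        assert cross_entropy_loss([self._pred(0.5)], [1]) == pytest.approx(np.log(2))

    def test_mean_over_batch(self):
        preds = [self._pred(1 - 1e-12), self._pred(0.5)]
        assert cross_entropy_loss(preds, [1, 1]) == pytest.approx(np.log(2) / 2, abs=1e-9)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValidationError):
            cross_entropy_loss([], [])

    def test_non_binary_label_rejected(self):
        with pytest.raises(ValidationError):
            cross_entropy_loss([self._pred(0.5)], [2])


class TestTrain:
    def test_overfits_tiny_dataset(self, toy_model, rng):
        bags = make_bags(rng, 10)
        model, history = train(toy_model, bags, bags, lr=1e-3, epochs=200,
                               batch_size=5, seed=0, patience=200)
        assert history[-1]["train_loss"] < 0.05

    def test_zero_learning_rate_is_noop(self, toy_model, rng):
        bags = make_bags(rng, 6)
        before = [p.data.copy() for p in toy_model.parameters()]
        model, _ = train(toy_model, bags, bags, lr=0.0, epochs=2,
                         batch_size=3, seed=0, patience=5)
        for a, p in zip(before, model.parameters()):
            assert np.array_equal(a, p.data)

    def test_seeded_reproducibility(self, rng):
        bags = make_bags(rng, 8)

        def run():
            m = BagModel.build(k=2, patch_width=4, patchnet_channels=(2, 2, 2, 2),
                               attention_hidden=2, classifier_channels=(2, 2), seed=0)
            return train(m, bags, bags, lr=1e-3, epochs=3, batch_size=4,
                         seed=42, patience=5)[1]

        assert run() == run()

    def test_loss_non_increasing_small_lr_single_batch(self, rng):
        """Fixed batch, lr 1e-4: the first epoch's steps do not increase loss."""
        from foamidl._engine import Adam
        from foamidl.classifier import _batch_loss

        model = BagModel.build(k=2, patch_width=4, patchnet_channels=(2, 2, 2, 2),
                               attention_hidden=2, classifier_channels=(2, 2), seed=2)
        bags = make_bags(rng, 4)
        model.train_mode()
        opt = Adam(model.parameters(), lr=1e-4)
        losses = []
        for _ in range(5):
            for m in model.modules():
                m.zero_grad()
            loss = _batch_loss(model, bags)
            losses.append(float(loss.data))
            loss.backward()
            opt.step()
        assert all(a >= b - 1e-4 for a, b in zip(losses, losses[1:]))

    def test_empty_sets_rejected(self, toy_model):
        with pytest.raises(ValidationError):
            train(toy_model, [], [], epochs=1)

    def test_nan_data_aborts_with_location(self, toy_model, rng):
        bags = make_bags(rng, 4)
        bags[0].patches[0].data[0, 0, 0] = np.nan
        with pytest.raises(TrainingDiverged, match="epoch 0"):
            train(toy_model, bags, bags, lr=1e-3, epochs=1, batch_size=4, seed=0)


class TestAblation:
    def test_no_flags_full_model(self):
        model = ablation_variant(2, 4, flags=(), patchnet_channels=(2, 2, 2, 2),
                                 attention_hidden=2, classifier_channels=(2, 2))
        assert model.ablation_flags == frozenset()
        from foamidl.patchnet import PatchNet

        assert isinstance(model.patchnet, PatchNet)

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValidationError, match="unknown ablation"):
            ablation_variant(2, 4, flags=("no_everything",))

    def test_all_three_flags_smoke(self, rng):
        """Mean-pooled fixed-embedding baseline trains and evaluates."""
        model = ablation_variant(
            2, 4, flags=("no_patchnet_cnn", "no_attention", "no_fssa"),
            attention_hidden=2, classifier_channels=(2, 2), seed=0,
        )
        bags = make_bags(rng, 8)
        model, history = train(model, bags, bags, lr=1e-3, epochs=3,
                               batch_size=4, seed=0, patience=5)
        pred = bag_forward(bags[0], model)
        assert np.isfinite(pred.prob_positive)
        assert len(history) == 3
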