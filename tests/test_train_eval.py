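"""Loss, metrics and the training loop."""

import math

import numpy as np
import pytest

from odfcanet.models import NetConfig, build_xodfcanet
from odfcanet.training import (
    TrainConfig,
    confusion_matrix,
    cross_entropy_loss,
    per_class_metrics,
    softmax,
    train,
)

SMALL_NET = NetConfig(stage_widths=(16, 32, 64, 128), blocks_per_stage=(1, 1, 1, 1),
                      stem_channels=16, odconv_n=1, odconv_gamma=0.25, ca_r=4,
                      input_size=64, seed=5)


class TestSoftmax:
    def test_uniform_for_equal_logits(self):
        np.testing.assert_allclose(softmax([0.0, 0.0, 0.0]), [1 / 3] * 3, atol=1e-12)

    def test_shift_invariance(self, rng):
        z = rng.standard_normal(5)
        np.testing.assert_allclose(softmax(z), softmax(z + 17.3), atol=1e-9)

    def test_log_ratio_logits(self):
        np.testing.assert_allclose(
            softmax(np.log([1.0, 2.0, 3.0])), [1 / 6, 2 / 6, 3 / 6], atol=1e-12
        )

    def test_sums_to_one(self, rng):
        p = softmax(rng.standard_normal((4, 7)) * 50)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-9)
        assert np.all(p >= 0)


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy_loss([0.0, 1.0, 0.0], [0, 1, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_ln3(self):
        got = cross_entropy_loss([1 / 3, 1 / 3, 1 / 3], [0, 0, 1])
        assert got == pytest.approx(math.log(3), abs=1e-9)

    def test_half_probability_ln2(self):
        got = cross_entropy_loss([0.2, 0.3, 0.5], [0, 0, 1])
        assert got == pytest.approx(-math.log(0.5), abs=1e-9)

    def test_non_onehot_rejected(self):
        with pytest.raises(ValueError, match="one-hot"):
            cross_entropy_loss([0.5, 0.5], [0.5, 0.5])

    def test_loss_nonnegative_for_random_distributions(self, rng):
        for _ in range(50):
            p = softmax(rng.standard_normal(4))
            y = np.eye(4)[rng.integers(0, 4)]
            assert cross_entropy_loss(p, y) >= 0.0


class TestMetrics:
    def test_perfect_predictions(self):
        m = confusion_matrix([0, 1, 2, 2], [0, 1, 2, 2], 3)
        np.testing.assert_array_equal(m, np.diag([1, 1, 2]))
        rep = per_class_metrics(m)
        np.testing.assert_allclose(rep.precision, 1.0)
        np.testing.assert_allclose(rep.recall, 1.0)
        np.testing.assert_allclose(rep.specificity, 1.0)
        assert rep.accuracy == 1.0

    def test_hand_computed_three_class_example(self):
        m = np.array([[9, 1, 0], [0, 8, 2], [1, 0, 9]])
        rep = per_class_metrics(m)
        assert rep.precision[0] == pytest.approx(0.9)
        assert rep.recall[0] == pytest.approx(0.9)
        assert rep.specificity[0] == pytest.approx(0.95)

    def test_two_class_enumeration(self):
        m = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(m, [[1, 1], [0, 2]])
        assert per_class_metrics(m).accuracy == pytest.approx(0.75)

    def test_entries_conserve_sample_count(self, rng):
        t = rng.integers(0, 3, 40)
        p = rng.integers(0, 3, 40)
        assert confusion_matrix(t, p, 3).sum() == 40

    def test_metrics_invariant_under_class_relabeling(self, rng):
        t = rng.integers(0, 3, 60)
        p = rng.integers(0, 3, 60)
        perm = np.array([2, 0, 1])  # class c is renamed to perm[c]
        rep = per_class_metrics(confusion_matrix(t, p, 3))
        rep_perm = per_class_metrics(confusion_matrix(perm[t], perm[p], 3))
        for fld in ("precision", "recall", "specificity"):
            np.testing.assert_allclose(
                getattr(rep_perm, fld)[perm], getattr(rep, fld), atol=1e-12
            )
        assert rep.accuracy == pytest.approx(rep_perm.accuracy)

    def test_undefined_cells_reported_as_nan_not_zero(self):
        m = np.array([[0, 0], [3, 0]])  # class 1 never predicted
        rep = per_class_metrics(m)
        assert np.isnan(rep.precision[1])
        assert np.isnan(rep.recall[0])

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([0, 1], [0], 2)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 3)


class TestTraining:
    def test_single_gradient_step_decreases_loss(self, small_synthetic_dataset):
        from odfcanet.nn import SGD
        from odfcanet.training import _batch_logits_loss

        images, labels, _ = small_synthetic_dataset
        model = build_xodfcanet(SMALL_NET)
        xb, yb = images[:2], labels[:2]
        before = _batch_logits_loss(model, xb, yb)
        opt = SGD(model.parameters(), lr=1e-4)
        opt.zero_grad()
        before.backward()
        opt.step()
        after = _batch_logits_loss(model, xb, yb)
        assert after.item() < before.item()

    def test_identical_seeds_give_identical_curves(self, small_synthetic_dataset):
        images, labels, _ = small_synthetic_dataset
        cfg = TrainConfig(epochs=2, lr=0.005, batch_size=10, seed=8)
        histories = []
        for _ in range(2):
            model = build_xodfcanet(SMALL_NET)
            _, hist = train(model, (images, labels), cfg)
            histories.append(hist)
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["train_accuracy"] == histories[1]["train_accuracy"]

    def test_small_run_reaches_perfect_training_accuracy(self, small_synthetic_dataset):
        """A tiny width-16 model separates 30 easy synthetic images in 5 epochs."""
        images, labels, _ = small_synthetic_dataset
        model = build_xodfcanet(SMALL_NET)
        cfg = TrainConfig(epochs=5, lr=0.015, momentum=0.9, batch_size=10, seed=0)
        _, hist = train(model, (images, labels), cfg)
        assert max(hist["train_accuracy"]) == 1.0

    def test_empty_training_set_rejected(self):
        model = build_xodfcanet(SMALL_NET)
        with pytest.raises(ValueError, match="empty"):
            train(model, (np.zeros((0, 3, 64, 64)), np.zeros(0, dtype=int)),
                  TrainConfig(epochs=1))

    def test_kfold_partition_properties(self):
        """8 items, k=4: every item validated exactly once, folds disjoint."""
        from sklearn.model_selection import StratifiedKFold

        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        splitter = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        seen = []
        for _, val_idx in splitter.split(np.zeros(8), labels):
            assert len(val_idx) == 2
            seen.extend(val_idx)
        assert sorted(seen) == list(range(8))

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(folds=1)
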