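"""Class weighting, the weighted loss, and the two CNN subclassifiers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atpres import subclassifiers_cnn as sc
from atpres.subclassifiers_cnn import (
    NetworkSpec,
    TrainingConfig,
    build_multi_incepresnet,
    build_multi_xception,
    class_weights,
    train,
    weighted_cross_entropy,
)

BUILDERS = [build_multi_incepresnet, build_multi_xception]


class TestClassWeights:
    def test_imbalanced_example(self):
        labels = np.array([0] * 90 + [1] * 10)
        w = class_weights(labels)
        assert w[0] == pytest.approx(0.5556, abs=1e-3)
        assert w[1] == pytest.approx(5.0, abs=1e-3)

    def test_balanced_gives_unit_weights(self):
        np.testing.assert_allclose(class_weights([0, 1] * 25), [1.0, 1.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.ones(10, dtype=int))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 1), min_size=2, max_size=400)
           .filter(lambda ls: 0 < sum(ls) < len(ls)))
    def test_conservation_identity(self, labels):
        """sum_c W_c * n_c recovers the total sample count exactly."""
        labels = np.asarray(labels)
        w = class_weights(labels)
        counts = np.bincount(labels, minlength=2)
        assert (w * counts).sum() == pytest.approx(len(labels))


class TestWeightedCrossEntropy:
    def test_perfect_predictions_near_zero(self):
        y = np.array([0, 1, 1, 0])
        probs = np.eye(2)[y]
        loss = weighted_cross_entropy(y, probs, np.array([1.0, 1.0]))
        assert 0.0 <= loss <= 4 * 1e-6

    def test_hand_evaluated_single_sample(self):
        loss = weighted_cross_entropy(
            np.array([1]), np.array([[0.5, 0.5]]), np.array([1.0, 2.0])
        )
        assert loss == pytest.approx(1.3863, abs=1e-4)

    def test_linear_in_weights(self, rng):
        y = rng.integers(0, 2, size=50)
        probs = rng.dirichlet([1, 1], size=50)
        w = np.array([0.7, 3.0])
        assert weighted_cross_entropy(y, probs, 2 * w) == pytest.approx(
            2 * weighted_cross_entropy(y, probs, w)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.zeros((3, 2)), np.zeros((4, 2)),
                                   np.ones(2))


@pytest.mark.parametrize("builder", BUILDERS)
class TestArchitectureContracts:
    def test_forward_softmax_rows(self, builder, tiny_spec, dataset_small):
        model = builder(tiny_spec, seed=0)
        inputs = model._inputs_from(dataset_small, slice(0, 4))
        probs_rows = np.exp(model.forward_logits(inputs))
        probs_rows /= probs_rows.sum(axis=1, keepdims=True)
        assert probs_rows.shape == (4, 2)
        np.testing.assert_allclose(probs_rows.sum(axis=1), 1.0, atol=1e-5)

    def test_param_count_is_function_of_spec(self, builder, tiny_spec):
        assert (builder(tiny_spec, seed=0).n_params()
                == builder(tiny_spec, seed=99).n_params())

    def test_predict_proba_contract(self, builder, tiny_spec, dataset_small):
        model = builder(tiny_spec, seed=0)
        p1 = model.predict_proba(dataset_small)
        p2 = model.predict_proba(dataset_small)
        assert p1.shape == (len(dataset_small),)
        assert ((p1 >= 0) & (p1 <= 1)).all()
        np.testing.assert_array_equal(p1, p2)

    def test_prediction_order_equivariance(self, builder, tiny_spec,
                                           dataset_small, rng):
        """Shuffling the samples shuffles the outputs, nothing else."""
        model = builder(tiny_spec, seed=0)
        perm = rng.permutation(len(dataset_small))
        p = model.predict_proba(dataset_small)
        p_perm = model.predict_proba(dataset_small.subset(perm))
        np.testing.assert_allclose(p_perm, p[perm], rtol=1e-5)


class TestTraining:
    def test_smoke_one_epoch_default_spec(self, dataset_small):
        """The default architecture trains for an epoch on ~500 samples."""
        model = build_multi_incepresnet(NetworkSpec(), seed=0)
        train(model, dataset_small, TrainingConfig(max_epochs=1, seed=0))
        assert np.isfinite(model.history["train_loss"][0])

    def test_history_bounded_and_early_stop_rule(self, tiny_spec,
                                                 dataset_small):
        cfg = TrainingConfig(max_epochs=12, early_stop_patience=3, seed=0)
        model = build_multi_xception(tiny_spec, seed=0)
        train(model, dataset_small, cfg)
        val = model.history["val_loss"]
        assert len(val) <= cfg.max_epochs <= 60
        # stops no later than patience epochs past the best epoch
        assert len(val) <= int(np.argmin(val)) + 1 + cfg.early_stop_patience

    def test_same_seed_reproduces_history(self, tiny_spec, dataset_small):
        runs = []
        for _ in range(2):
            model = build_multi_xception(tiny_spec, seed=5)
            train(model, dataset_small,
                  TrainingConfig(max_epochs=2, seed=5))
            runs.append(model.history["train_loss"])
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_single_class_data_rejected(self, tiny_spec, dataset_small):
        ds = dataset_small.subset(dataset_small.labels == 0)
        model = build_multi_xception(tiny_spec, seed=0)
        with pytest.raises(ValueError):
            train(model, ds, TrainingConfig(seed=0))

    def test_loss_decreases_on_learnable_signal(self, tiny_spec,
                                                dataset_medium):
        """Planted-signal data: the weighted loss trends downward."""
        model = build_multi_xception(tiny_spec, seed=1)
        train(model, dataset_medium, TrainingConfig(max_epochs=6, seed=1))
        losses = model.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_save_load_roundtrip(self, tiny_spec, dataset_small, tmp_path):
        model = build_multi_xception(tiny_spec, seed=0)
        train(model, dataset_small, TrainingConfig(max_epochs=1, seed=0))
        p = model.predict_proba(dataset_small)
        model.save(tmp_path / "m.npz")
        fresh = build_multi_xception(tiny_spec, seed=42)
        fresh.load_weights(tmp_path / "m.npz")
        np.testing.assert_array_equal(fresh.predict_proba(dataset_small), p)
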