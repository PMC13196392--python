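"""Classifier mechanics: architecture contracts, early stopping, thresholds, training."""

import numpy as np
import pytest

from osteoscreen.classifier import (
    Dataset,
    FeatureScaler,
    TrainConfig,
    build_model,
    early_stop_epoch,
    predict,
    select_operating_threshold,
    train_classifier,
)
from osteoscreen.nn import ArchConfig, PoolMixerNet


ARCH = ArchConfig(input_size=32, patch_size=8, embed_dim=16, depth=1, n_engineered=17)


def _random_dataset(n, seed, separable=True):
    """Tiny synthetic dataset: class 1 gets brighter context and larger eng[2]."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    images = rng.uniform(0.3, 0.5, size=(n, 2, 32, 32))
    eng = rng.normal(size=(n, 17))
    if separable:
        images[y == 1] += 0.25
        eng[y == 1, 2] += 2.5
    return Dataset(
        images=images,
        engineered=eng,
        y_vhbf=y,
        y_osteo=y,
        y_degraded=y,
        subject_ids=[f"S{i}" for i in range(n)],
    )


class TestModelContracts:
    def test_softmax_probabilities(self):
        model = build_model(ARCH, seed=0)
        rng = np.random.default_rng(0)
        out = model.forward(rng.uniform(size=(5, 2, 32, 32)), rng.normal(size=(5, 17)))
        np.testing.assert_allclose(out["probs"].sum(axis=1), 1.0, atol=1e-6)
        assert np.all(out["probs"] >= 0)

    def test_head_activations_are_sixteen_wide(self):
        model = build_model(ArchConfig())
        x = np.random.default_rng(1).uniform(size=(2, 2, 64, 64))
        out = model.forward(x, np.zeros((2, 17)))
        hA, hB = out["head_activations"]
        assert hA.shape == (2, 16) and hB.shape == (2, 16)

    def test_head_width_override_is_explicit(self):
        model = build_model(ARCH, head_width_override=8)
        out = model.forward(np.zeros((1, 2, 32, 32)), np.zeros((1, 17)))
        assert out["head_activations"][0].shape == (1, 8)

    def test_engineered_features_change_output(self):
        """Gradient flows through fusion: zeroing engineered inputs moves p."""
        model = build_model(ARCH, seed=0)
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(1, 2, 32, 32))
        eng = rng.normal(size=(1, 17)) * 3
        p1 = model.forward(x, eng)["probs"][0, 1]
        p2 = model.forward(x, np.zeros((1, 17)))["probs"][0, 1]
        assert p1 != pytest.approx(p2, abs=1e-9)

    def test_batch_equals_per_sample(self):
        model = build_model(ARCH, seed=0)
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(4, 2, 32, 32))
        eng = rng.normal(size=(4, 17))
        batch = model.forward(x, eng)["probs"]
        singles = np.vstack([model.forward(x[k : k + 1], eng[k : k + 1])["probs"] for k in range(4)])
        np.testing.assert_allclose(batch, singles, atol=1e-12)


class TestEarlyStopping:
    def test_flat_sequence_stops_after_patience(self):
        """Best at epoch k, then 40 epochs below +0.005: stop at k+40, restore k."""
        monitor = [0.5, 0.8] + [0.801] * 45
        stop, best = early_stop_epoch(monitor, 0.005, 40)
        assert best == 1
        assert stop == 41

    def test_improvement_resets_patience(self):
        monitor = [0.5] + [0.5] * 30 + [0.6] + [0.6] * 39
        stop, best = early_stop_epoch(monitor, 0.005, 40)
        assert best == 31
        assert stop is None  # only 39 stale epochs after the new best

    def test_exact_delta_counts_as_improvement(self):
        monitor = [0.5, 0.505] + [0.5] * 39
        stop, best = early_stop_epoch(monitor, 0.005, 40)
        assert best == 1 and stop is None

    def test_sub_delta_gain_does_not_reset(self):
        monitor = [0.5] + [0.5049] * 40
        stop, best = early_stop_epoch(monitor, 0.005, 40)
        assert best == 0 and stop == 40

    @pytest.mark.parametrize("patience", [1, 5, 40])
    def test_stop_is_exactly_patience_after_best(self, patience):
        monitor = [0.9] + [0.1] * 100
        stop, best = early_stop_epoch(monitor, 0.005, patience)
        assert best == 0 and stop == patience


class TestOperatingThreshold:
    def test_zero_target_accepts_everything(self):
        th, diag = select_operating_threshold([0.2, 0.4, 0.9], [0, 0, 1], min_specificity=0.0)
        assert th == 0.0 and diag["sensitivity"] == 1.0

    def test_separated_scores_pick_smallest_adequate(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        th, diag = select_operating_threshold(scores, [0, 0, 1, 1], min_specificity=1.0)
        assert th == 0.8  # the smallest candidate with specificity 1
        assert diag["sensitivity"] == 1.0

    def test_specificity_recomputed_from_confusion_matrix(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(size=200)
        labels = (scores + rng.normal(scale=0.3, size=200) > 0.6).astype(int)
        if labels.sum() in (0, 200):
            pytest.skip("degenerate draw")
        th, diag = select_operating_threshold(scores, labels, min_specificity=0.9)
        neg = np.asarray(scores)[np.asarray(labels) == 0]
        spec = float((neg < th).mean())
        assert spec >= 0.9
        assert spec == pytest.approx(diag["specificity"])

    def test_unattainable_target_returns_one(self):
        th, diag = select_operating_threshold([1.0, 1.0, 0.5], [0, 0, 1], min_specificity=0.99)
        assert th == 1.0 and diag["attained"] == 0.0


class TestScaler:
    def test_standardisation_and_imputation(self):
        raw = np.array([[60.0, 1.0, 0.9] + [0.0] * 12, [70.0, 0.0, 1.1] + [0.0] * 12,
                        [80.0, 1.0, 1.3] + [0.0] * 12])
        scaler = FeatureScaler.fit(raw)
        flags = np.zeros((3, 2))
        out = scaler.transform(raw, flags)
        assert out.shape == (3, 17)
        np.testing.assert_allclose(out[:, :3].mean(axis=0), 0.0, atol=1e-12)
        missing = np.array([[np.nan, np.nan, 1.1] + [0.0] * 12])
        out2 = scaler.transform(missing, np.array([[1.0, 1.0]]))
        assert np.isfinite(out2).all()
        # imputed age is the median (70) -> standardised to 0
        assert out2[0, 0] == pytest.approx(0.0, abs=1e-12)


class TestTraining:
    def test_single_class_split_rejected(self):
        ds = _random_dataset(20, 0)
        ds.y_vhbf = np.zeros(20, dtype=int)
        with pytest.raises(ValueError):
            train_classifier(ds, _random_dataset(10, 1), TrainConfig(max_epochs=2), arch=ARCH)

    def test_training_learns_separable_data_and_is_deterministic(self):
        cfg = TrainConfig(learning_rate=0.01, batch_size=16, max_epochs=12, seed=5)
        train = _random_dataset(60, 10)
        val = _random_dataset(24, 11)
        a = train_classifier(train, val, cfg, arch=ARCH)
        b = train_classifier(train, val, cfg, arch=ARCH)
        assert [h["val_accuracy"] for h in a.history] == pytest.approx(
            [h["val_accuracy"] for h in b.history], abs=1e-10
        )
        test = _random_dataset(30, 12)
        pred = predict(a, test)
        from osteoscreen.evaluate import auc

        assert auc(pred["p_vhbf"], test.y_vhbf) >= 0.9
        assert pred["p_vhbf"].shape == (30,)
        np.testing.assert_allclose(pred["p_vhbf"] + pred["p_not"], 1.0, atol=1e-9)

    def test_best_epoch_weights_restored(self):
        cfg = TrainConfig(learning_rate=0.01, batch_size=16, max_epochs=8, seed=5)
        trained = train_classifier(_random_dataset(40, 1), _random_dataset(16, 2), cfg, arch=ARCH)
        accs = [h["val_accuracy"] for h in trained.history]
        _, best = early_stop_epoch(accs, cfg.early_stop_min_delta, cfg.early_stop_patience_epochs)
        assert trained.best_epoch == best

    def test_grid_search_subset_returns_best(self):
        from osteoscreen.classifier import grid_search

        base = TrainConfig(max_epochs=4, seed=5)
        best, board = grid_search(
            _random_dataset(40, 1),
            _random_dataset(16, 2),
            base_config=base,
            lr_subset=[0.01, 0.0000003],
            batch_subset=[16],
            arch=ARCH,
        )
        assert len(board) == 2
        best_row = max(board, key=lambda r: r["val_accuracy"])
        assert best.config.learning_rate == best_row["learning_rate"]

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = TrainConfig(learning_rate=0.01, batch_size=16, max_epochs=3, seed=5)
        trained = train_classifier(_random_dataset(40, 1), _random_dataset(16, 2), cfg, arch=ARCH)
        trained.operating_threshold = 0.37
        path = tmp_path / "clf.pkl"
        trained.save(path)
        from osteoscreen.classifier import TrainedClassifier

        loaded = TrainedClassifier.load(path)
        test = _random_dataset(10, 3)
        np.testing.assert_allclose(
            predict(loaded, test)["p_vhbf"], predict(trained, test)["p_vhbf"], atol=1e-12
        )
        assert loaded.operating_threshold == 0.37
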