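import numpy as np
import pytest

from flyconf import (
    PreprocessSpec,
    ReferenceNet,
    TrainConfig,
    evaluate_accuracy,
    smoothed_cross_entropy,
    train_classifier,
)
from flyconf.classifier import cosine_warm_restart_factor


class TestSmoothedCrossEntropy:
    def test_zero_smoothing_perfect_prediction_zero_loss(self):
        assert smoothed_cross_entropy([0.0, 1.0, 0.0], 1, smoothing=0.0) == pytest.approx(0.0)

    def test_uniform_prediction_two_classes(self):
        # q = (0.95, 0.05); -(0.95 + 0.05) log 0.5 = log 2
        assert smoothed_cross_entropy([0.5, 0.5], 0, smoothing=0.1) == pytest.approx(np.log(2))

    @pytest.mark.parametrize("k,eps", [(2, 0.0), (5, 0.1), (15, 0.3)])
    def test_uniform_prediction_gives_log_k_for_any_smoothing(self, k, eps):
        p = np.full(k, 1 / k)
        assert smoothed_cross_entropy(p, 0, smoothing=eps) == pytest.approx(np.log(k))

    def test_zero_probability_clamped_finite(self):
        loss = smoothed_cross_entropy([1.0, 0.0], 0, smoothing=0.1)
        assert np.isfinite(loss)

    def test_invalid_smoothing_rejected(self):
        with pytest.raises(ValueError):
            smoothed_cross_entropy([0.5, 0.5], 0, smoothing=1.0)


class TestCosineWarmRestarts:
    def test_full_rate_at_start_and_after_restart(self):
        assert cosine_warm_restart_factor(0) == pytest.approx(1.0)
        assert cosine_warm_restart_factor(10, period=10, mult=2) == pytest.approx(1.0)

    def test_half_rate_at_period_midpoint(self):
        assert cosine_warm_restart_factor(5, period=10) == pytest.approx(0.5)

    def test_period_doubles_after_restart(self):
        # second cycle spans epochs 10..30; its midpoint is epoch 20
        assert cosine_warm_restart_factor(20, period=10, mult=2) == pytest.approx(0.5)


class TestReferenceNet:
    @pytest.fixture
    def net(self):
        return ReferenceNet(n_classes=4, input_size=16, seed=0)

    def test_valid_probability_vector(self, net):
        rng = np.random.default_rng(0)
        p = net.predict_proba(rng.normal(size=(16, 16, 3)))
        assert p.shape == (4,)
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_parameter_budget(self):
        assert ReferenceNet(n_classes=15, input_size=64).n_parameters < 200_000

    def test_deterministic_without_dropout(self, net):
        x = np.random.default_rng(1).normal(size=(16, 16, 3))
        np.testing.assert_array_equal(net.predict_proba(x), net.predict_proba(x))

    def test_dropout_stochastic_across_states_deterministic_within(self, net):
        x = np.random.default_rng(1).normal(size=(16, 16, 3))
        a = net.predict_proba(x, rng=np.random.default_rng(0), dropout=True)
        b = net.predict_proba(x, rng=np.random.default_rng(0), dropout=True)
        c = net.predict_proba(x, rng=np.random.default_rng(7), dropout=True)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_one_dropout_mask_per_weighted_layer(self, net):
        x = np.random.default_rng(1).normal(size=(1, 16, 16, 3))
        _, cache = net.forward(x, rng=np.random.default_rng(0), dropout=True, want_cache=True)
        conv_masks = [c[3] for c in cache["convs"]]
        n_masks = sum(m is not None for m in conv_masks) + (cache["fmask"] is not None)
        assert n_masks == 4  # three convs + the linear head

    def test_dropout_requires_rng(self, net):
        x = np.zeros((16, 16, 3))
        with pytest.raises(ValueError):
            net.predict_proba(x, dropout=True)

    def test_save_load_round_trip(self, net, tmp_path):
        path = tmp_path / "ckpt.npz"
        net.save(path)
        net2 = ReferenceNet.load(path)
        x = np.random.default_rng(2).normal(size=(16, 16, 3))
        np.testing.assert_array_equal(net.predict_proba(x), net2.predict_proba(x))

    def test_input_size_must_be_divisible_by_8(self):
        with pytest.raises(ValueError):
            ReferenceNet(n_classes=3, input_size=50)


class TestTraining:
    def test_separable_data_reaches_high_accuracy(self, separable_manifest):
        net = ReferenceNet(n_classes=2, input_size=16, seed=0)
        spec = PreprocessSpec(target_size=(16, 16))
        result = train_classifier(
            separable_manifest, net, TrainConfig(max_epochs=10, seed=0), preprocess_spec=spec
        )
        acc = evaluate_accuracy(net, separable_manifest, "validation", spec)
        assert acc > 0.95
        assert result.best_epoch >= 0

    def test_zero_epochs_rejected(self, separable_manifest):
        net = ReferenceNet(n_classes=2, input_size=16)
        with pytest.raises(ValueError, match="max_epochs"):
            train_classifier(separable_manifest, net, TrainConfig(max_epochs=0))

    def test_class_count_mismatch_rejected(self, separable_manifest):
        net = ReferenceNet(n_classes=5, input_size=16)
        with pytest.raises(ValueError, match="classes"):
            train_classifier(separable_manifest, net, TrainConfig(max_epochs=1))

    def test_empty_split_rejected(self, separable_manifest):
        train_only = separable_manifest.with_records(
            [r for r in separable_manifest.records if r.split == "train"]
        )
        net = ReferenceNet(n_classes=2, input_size=16)
        with pytest.raises(ValueError, match="split"):
            train_classifier(train_only, net, TrainConfig(max_epochs=1))

    def test_identical_seeds_identical_first_epoch(self, separable_manifest):
        spec = PreprocessSpec(target_size=(16, 16))
        losses = []
        for _ in range(2):
            net = ReferenceNet(n_classes=2, input_size=16, seed=3)
            res = train_classifier(
                separable_manifest, net, TrainConfig(max_epochs=1, seed=11), preprocess_spec=spec
            )
            losses.append(res.log[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_training_loss_decreases_early(self, separable_manifest):
        spec = PreprocessSpec(target_size=(16, 16))
        net = ReferenceNet(n_classes=2, input_size=16, seed=0)
        res = train_classifier(
            separable_manifest,
            net,
            TrainConfig(max_epochs=4, label_smoothing=0.0, seed=0),
            preprocess_spec=spec,
        )
        assert res.log[-1]["train_loss"] < res.log[0]["train_loss"]

    def test_log_schema(self, separable_manifest, tmp_path):
        spec = PreprocessSpec(target_size=(16, 16))
        net = ReferenceNet(n_classes=2, input_size=16, seed=0)
        res = train_classifier(
            separable_manifest, net, TrainConfig(max_epochs=2, seed=0), preprocess_spec=spec
        )
        assert set(res.log[0]) == {"epoch", "train_loss", "val_loss", "epoch_seconds"}
        log_path = tmp_path / "log.csv"
        res.write_log(log_path)
        assert log_path.read_text().startswith("epoch,train_loss,val_loss,epoch_seconds")
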