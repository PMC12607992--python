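"""Regression network: training contracts, prediction bounds, checkpoints."""

import numpy as np
import pytest

from fiberorder import network, synth
from fiberorder._net import ConvNet
from fiberorder.network import (
    ModelSpec,
    TrainingConfig,
    evaluate,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)


def tiny_spec() -> ModelSpec:
    layers = [
        {"kind": "conv", "filters": 6, "kernel": 5, "stride": 2},
        {"kind": "pool", "size": 2},
        {"kind": "dense", "width": 16},
        {"kind": "dense", "width": 1},
    ]
    return ModelSpec.from_layers(32, layers)


@pytest.fixture(scope="module")
def tiny_trained(small_dataset):
    model, history = train(
        small_dataset,
        tiny_spec(),
        TrainingConfig(epochs=4, seed=3, plateau_tol=-1.0),
    )
    return model, history


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        rng = np.random.default_rng(0)
        layers = [
            {"kind": "conv", "filters": 3, "kernel": 3, "stride": 2},
            {"kind": "pool", "size": 2},
            {"kind": "conv", "filters": 4, "kernel": 3, "stride": 1},
            {"kind": "pool", "size": 2},
            {"kind": "dense", "width": 5},
            {"kind": "dense", "width": 1},
        ]
        net = ConvNet(28, layers, rng)
        x = rng.standard_normal((4, 28, 28)).astype(np.float32)
        y = rng.uniform(0.2, 0.8, 4).astype(np.float32)
        pred, cache = net.forward(x, want_cache=True)
        dpred = (2.0 * (pred - y) / len(y)).astype(np.float32)
        grads = net.backward(cache, dpred)
        eps = 1e-3
        for key in grads:
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in net.params[key].shape)
                orig = net.params[key][idx]
                net.params[key][idx] = orig + eps
                lp = float(np.mean((net.forward(x) - y) ** 2))
                net.params[key][idx] = orig - eps
                lm = float(np.mean((net.forward(x) - y) ** 2))
                net.params[key][idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = float(grads[key][idx])
                assert ana == pytest.approx(num, abs=max(1e-4, 0.02 * abs(num)))


class TestTraining:
    def test_constant_labels_learned(self, fast_config):
        ds = synth.generate_dataset(
            40,
            config_template=synth.GeneratorConfig(
                **{**fast_config.__dict__, "order_degree": 0.5}
            ),
            label_law="fixed",
            seed=17,
        )
        model, _ = train(
            ds,
            tiny_spec(),
            TrainingConfig(epochs=40, seed=0, learning_rate=2e-3, plateau_tol=-1.0),
        )
        preds = [predict(model, img.pixels) for img in ds.images[:10]]
        assert np.allclose(preds, 0.5, atol=0.02)

    def test_training_is_seed_deterministic(self, small_dataset):
        cfg = TrainingConfig(epochs=3, seed=5, plateau_tol=-1.0)
        _, h1 = train(small_dataset, tiny_spec(), cfg)
        _, h2 = train(small_dataset, tiny_spec(), cfg)
        assert h1.val_loss == h2.val_loss
        assert h1.train_loss == h2.train_loss

    def test_non_finite_loss_aborts_with_diagnostic(self, small_dataset):
        from dataclasses import replace

        images = list(small_dataset.images[:12])
        bad = images[0].pixels.copy()
        bad[0, 0] = np.nan
        images[0] = replace(images[0], pixels=bad)
        broken = synth.LabeledDataset(
            images=images,
            labels_table=small_dataset.labels_table.iloc[:12],
            train_indices=np.arange(10),
            test_indices=np.arange(10, 12),
            config=small_dataset.config,
            seed=0,
        )
        with pytest.raises(network.TrainingDivergedError, match="learning_rate"):
            train(broken, tiny_spec(), TrainingConfig(epochs=2, seed=0))

    def test_history_contract(self, tiny_trained):
        _, history = tiny_trained
        assert history.epochs_run == len(history.val_loss) == len(history.train_loss)
        assert all(np.isfinite(v) and v >= 0 for v in history.val_loss)

    def test_plateau_rule_stops_training(self, small_dataset):
        # a huge tolerance forces the plateau as soon as the rule is armed
        cfg = TrainingConfig(epochs=20, seed=1, plateau_tol=10.0, plateau_patience=3)
        _, history = train(small_dataset, tiny_spec(), cfg)
        assert history.converged_epoch == 4
        assert history.epochs_run == 4


class TestPredict:
    def test_output_strictly_inside_unit_interval(self, tiny_trained):
        model, _ = tiny_trained
        rng = np.random.default_rng(0)
        for img in (np.zeros((128, 128)), np.ones((128, 128)), rng.random((128, 128))):
            p = predict(model, img)
            assert 0.0 < p < 1.0

    def test_prediction_rotation_invariance(self, tiny_trained, small_dataset):
        model, _ = tiny_trained
        img = small_dataset.images[0].pixels
        base = predict(model, img)
        for k in (1, 2, 3):
            assert predict(model, np.rot90(img, k=k)) == pytest.approx(base, abs=0.05)


class TestEvaluate:
    def test_split_disjointness_enforced(self, tiny_trained, small_dataset):
        model, _ = tiny_trained
        broken = synth.LabeledDataset(
            images=small_dataset.images,
            labels_table=small_dataset.labels_table,
            train_indices=small_dataset.train_indices,
            test_indices=small_dataset.train_indices[:5],
            config=small_dataset.config,
            seed=small_dataset.seed,
        )
        with pytest.raises(ValueError):
            evaluate(model, broken)

    def test_perfect_predictor_scores_zero(self, small_dataset, monkeypatch):
        model, _ = train(
            small_dataset, tiny_spec(), TrainingConfig(epochs=1, seed=0, plateau_tol=-1)
        )
        truth = {i: small_dataset.images[i].label for i in range(len(small_dataset))}
        labels = small_dataset.labels(small_dataset.test_indices)
        monkeypatch.setattr(
            network, "predict_many", lambda m, imgs: labels.copy()
        )
        metrics = evaluate(model, small_dataset)
        assert metrics.mean_absolute_error == pytest.approx(0.0, abs=1e-12)
        assert metrics.max_relative_error == pytest.approx(0.0, abs=1e-12)
        assert metrics.calibration_slope == pytest.approx(1.0, abs=1e-9)
        assert metrics.calibration_intercept == pytest.approx(0.0, abs=1e-9)

    def test_relative_errors_restricted_to_band(self, tiny_trained, small_dataset):
        model, _ = tiny_trained
        metrics = evaluate(model, small_dataset)
        labels = small_dataset.labels(small_dataset.test_indices)
        expected_n = int(np.sum((labels >= 0.3) & (labels <= 0.7)))
        assert metrics.n_relative == expected_n


class TestCheckpoint:
    def test_roundtrip_is_bit_exact(self, tiny_trained, tmp_path):
        model, _ = tiny_trained
        path = save_checkpoint(model, tmp_path / "ckpt")
        loaded = load_checkpoint(path)
        for key, arr in model.net.params.items():
            assert np.array_equal(loaded.net.params[key], arr)
        assert loaded.spec == model.spec
        assert loaded.history.val_loss == model.history.val_loss
        img = np.random.default_rng(1).random((128, 128))
        assert predict(loaded, img) == predict(model, img)

    def test_schema_version_checked(self, tiny_trained, tmp_path):
        import json

        model, _ = tiny_trained
        path = save_checkpoint(model, tmp_path / "ckpt")
        sidecar = path.with_suffix(".json")
        data = json.loads(sidecar.read_text())
        data["schema_version"] = 999
        sidecar.write_text(json.dumps(data))
        with pytest.raises(ValueError):
            load_checkpoint(path)

    def test_missing_sidecar_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "nothing")
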