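"""Architecture specs, training behavior and classical baselines."""

import numpy as np
import pytest

from dysvoice.models import (DEFAULT_GRIDS, NeuralSequenceClassifier,
                             TrainConfig, build_model, fit_classical)


class TestBuildModel:
    def test_dnn_stack_matches_published_row(self):
        spec = build_model("dnn", (40, 128))
        kinds = [layer["kind"] for layer in spec.layers]
        assert kinds == ["flatten", "dense", "dropout", "dense", "dropout",
                        "dense", "dense"]
        widths = [l["units"] for l in spec.layers if l["kind"] == "dense"]
        assert widths == [256, 128, 64, 1]

    def test_every_deep_spec_ends_with_single_sigmoid(self):
        for name in ("bilstm", "cnn_lstm", "cnn_gru", "dnn"):
            final = build_model(name).final_layer()
            assert final == {"kind": "dense", "units": 1,
                             "activation": "sigmoid"}

    def test_reshape_stage_gives_40_timesteps_of_512(self):
        spec = build_model("bilstm", (40, 128))
        reshape = next(l for l in spec.layers if l["kind"] == "reshape")
        assert reshape["timesteps"] == 40
        assert reshape["features"] == 512  # 10*32*64 / 40

    def test_conv_kernels_per_architecture(self):
        kernels = {name: [tuple(l["kernel"]) for l in
                          build_model(name).layers if l["kind"] == "conv2d"]
                   for name in ("bilstm", "cnn_lstm", "cnn_gru")}
        assert kernels["bilstm"] == [(3, 3), (2, 3)]
        assert kernels["cnn_lstm"] == [(3, 3), (3, 3)]
        assert kernels["cnn_gru"] == [(2, 3), (3, 3)]

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_model("transformer")

    def test_dnn_parameter_count_hand_computed(self):
        clf = NeuralSequenceClassifier("dnn", epochs=1, random_state=0)
        X = np.random.default_rng(0).standard_normal((4, 40, 128))
        clf.fit(X, np.array([0, 1, 0, 1]))
        flat = 40 * 128
        expected = (flat * 256 + 256) + (256 * 128 + 128) \
            + (128 * 64 + 64) + (64 * 1 + 1)
        assert clf.n_parameters_ == expected

    def test_bilstm_concatenates_directions(self):
        # a BiLSTM(64, return_sequences) layer emits width 128 = 2 x 64
        clf = NeuralSequenceClassifier("bilstm", epochs=1, random_state=0)
        X = np.random.default_rng(0).standard_normal((4, 40, 128))
        clf.fit(X, np.array([0, 1, 0, 1]))
        recurrent = [l for l in clf._net.layers
                     if l.__class__.__name__ == "_Recurrent"]
        first = recurrent[0]
        out = first(__import__("dysvoice._autograd", fromlist=["Tensor"])
                    .Tensor(np.zeros((2, 5, 512))), None, False)
        assert out.data.shape == (2, 5, 128)


@pytest.fixture(scope="module")
def separable_grids():
    rng = np.random.default_rng(3)
    n = 20
    X = rng.standard_normal((n, 40, 128)) * 0.1
    y = np.tile([0, 1], n // 2)
    X[y == 1, :, :24] += 1.0
    return X, y


class TestTraining:
    def test_overfits_separable_toy_data(self, separable_grids):
        X, y = separable_grids
        clf = NeuralSequenceClassifier("dnn", epochs=30, random_state=0,
                                       val_fraction=0.0)
        clf.fit(X, y)
        assert clf.score(X, y) >= 0.95

    def test_loss_finite_and_decreases_to_best(self, separable_grids):
        X, y = separable_grids
        clf = NeuralSequenceClassifier("dnn", epochs=15, random_state=0,
                                       val_fraction=0.0)
        clf.fit(X, y)
        losses = clf.history_["loss"]
        assert np.all(np.isfinite(losses))
        assert min(losses) < losses[0]
        assert len(losses) == 15

    def test_same_seed_identical_training(self, separable_grids):
        X, y = separable_grids
        runs = [NeuralSequenceClassifier("dnn", epochs=5, random_state=9)
                .fit(X, y).history_["loss"][-1] for _ in range(2)]
        assert abs(runs[0] - runs[1]) < 1e-6

    def test_single_class_rejected(self, separable_grids):
        X, _ = separable_grids
        with pytest.raises(ValueError):
            NeuralSequenceClassifier("dnn", epochs=1).fit(X, np.zeros(len(X)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            NeuralSequenceClassifier("bilstm", epochs=1).fit(
                np.zeros((4, 10, 10)), np.array([0, 1, 0, 1]))

    def test_probabilities_valid_and_duplicate_consistent(self, separable_grids):
        X, y = separable_grids
        clf = NeuralSequenceClassifier("dnn", epochs=5, random_state=0)
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert np.all((proba > 0) & (proba < 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        dup = np.concatenate([X[:1], X[:1]])
        p = clf.predict_proba(dup)
        np.testing.assert_array_equal(p[0], p[1])

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            NeuralSequenceClassifier("dnn").predict(np.zeros((1, 40, 128)))

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(split=1.5)


@pytest.fixture(scope="module")
def separable_features():
    rng = np.random.default_rng(1)
    n = 40
    y = np.tile([0, 1], n // 2)
    X = rng.standard_normal((n, 5))
    X[:, 0] += 4.0 * y
    return X, y


class TestClassical:
    def test_logreg_separable_accuracy(self, separable_features):
        X, y = separable_features
        model = fit_classical("logreg", X, y, seed=0)
        assert (model.predict(X) == y).mean() >= 0.95

    def test_sigmoid_closed_forms(self, separable_features):
        # P = 1 / (1 + exp(-(w.x + b))): margin 0 -> 0.5, ln 3 -> 0.75
        X, y = separable_features
        model = fit_classical("logreg", X, y, seed=0)
        pipe = model.best_estimator_
        clf = pipe.named_steps["clf"]
        scaler = pipe.named_steps["scale"]
        w, b = clf.coef_.ravel(), clf.intercept_[0]
        for margin, expected in ((0.0, 0.5), (np.log(3.0), 0.75)):
            # craft a standardized input with the requested margin
            z = np.zeros_like(w)
            z[0] = (margin - b) / w[0]
            x = z * scaler.scale_ + scaler.mean_
            assert pipe.predict_proba(x[None, :])[0, 1] == \
                pytest.approx(expected, abs=1e-9)

    def test_grid_with_single_point_selected(self, separable_features):
        X, y = separable_features
        model = fit_classical("logreg", X, y, hyper_grid={"clf__C": [0.37]},
                              seed=0)
        assert model.best_params_ == {"clf__C": 0.37}

    def test_xgboost_prediction_is_tree_sum(self, separable_features):
        # additive ensemble: margin equals the sum of per-tree leaf values
        X, y = separable_features
        model = fit_classical("xgboost", X, y,
                              hyper_grid={"clf__n_estimators": [10]}, seed=0)
        booster = model.best_estimator_.named_steps["clf"]
        import xgboost as xgb
        dmat = xgb.DMatrix(X)
        raw = booster.get_booster().predict(dmat, output_margin=True)
        per_tree = booster.get_booster().predict(dmat, pred_leaf=False,
                                                 pred_contribs=True)
        np.testing.assert_allclose(per_tree.sum(axis=1), raw, atol=1e-4)

    def test_empty_grid_rejected(self, separable_features):
        X, y = separable_features
        with pytest.raises(ValueError):
            fit_classical("svm", X, y, hyper_grid={}, seed=0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_classical("forest", np.zeros((4, 2)), [0, 1, 0, 1])
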