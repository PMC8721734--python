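"""Kernel SVM: kernel formulas, solver contract, persistence."""

import numpy as np
import pytest

from snaresap import (
    FeatureMatrix,
    NormalizationParams,
    SVMConfig,
    load_model,
    predict,
    save_model,
    train,
)
from snaresap.classifier import (
    ModelFormatError,
    decision_function,
    kernel_eval,
    kernel_matrix,
)


class TestKernels:
    def test_rbf_zero_distance_is_one(self):
        cfg = SVMConfig(kernel="rbf", gamma=0.5)
        x = np.array([1.0, -2.0, 3.0])
        assert kernel_eval(cfg, x, x) == 1.0

    def test_linear_dot_product(self):
        cfg = SVMConfig(kernel="linear")
        x = np.array([1.0, 2.0, 2.0])
        assert kernel_eval(cfg, x, x) == 9.0

    def test_polynomial_hand_value(self):
        cfg = SVMConfig(kernel="polynomial", gamma=1.0, coef0=0.0, degree=2)
        assert kernel_eval(cfg, [1.0, 0.0], [2.0, 0.0]) == 4.0

    def test_sigmoid_tanh(self):
        cfg = SVMConfig(kernel="sigmoid", gamma=0.5, coef0=1.0)
        assert kernel_eval(cfg, [2.0], [3.0]) == pytest.approx(np.tanh(4.0))

    def test_rbf_hand_value(self):
        cfg = SVMConfig(kernel="rbf", gamma=0.1)
        assert kernel_eval(cfg, [0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.exp(-2.5))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kernel_eval(SVMConfig(), [1.0], [1.0, 2.0])

    @pytest.mark.parametrize("kernel", ["linear", "polynomial", "rbf", "sigmoid"])
    def test_matrix_agrees_with_scalar_eval(self, kernel, rng):
        cfg = SVMConfig(kernel=kernel, gamma=0.3, coef0=0.5, degree=3)
        A, B = rng.normal(size=(4, 6)), rng.normal(size=(3, 6))
        K = kernel_matrix(cfg, A, B)
        for i in range(4):
            for j in range(3):
                assert K[i, j] == pytest.approx(kernel_eval(cfg, A[i], B[j]), abs=1e-12)


class TestConfig:
    def test_defaults_are_tuned_pipeline(self):
        cfg = SVMConfig()
        assert (cfg.kernel, cfg.C, cfg.gamma) == ("rbf", 11.0, 0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kernel": "quadratic"},
            {"C": 0.0},
            {"kernel": "rbf", "gamma": 0.0},
            {"degree": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SVMConfig(**kwargs)

    def test_linear_kernel_allows_zero_gamma(self):
        SVMConfig(kernel="linear", gamma=0.0)


class TestTrain:
    def test_separable_clusters_perfect_training_accuracy(self, separable_matrix):
        model = train(separable_matrix, SVMConfig())
        labels, _ = predict(model, separable_matrix.X)
        assert np.array_equal(labels, separable_matrix.y)

    def test_single_class_rejected(self):
        M = FeatureMatrix(X=np.ones((3, 2)), y=[1, 1, 1], feature_ids=[0, 1])
        with pytest.raises(ValueError, match="both classes"):
            train(M, SVMConfig())

    def test_non_finite_rejected(self):
        M = FeatureMatrix(
            X=np.array([[1.0], [np.nan]]), y=[1, -1], feature_ids=[0]
        )
        with pytest.raises(ValueError, match="non-finite"):
            train(M, SVMConfig())

    def test_linear_max_margin_boundary_between_clusters(self):
        """1-D points {0,1} vs {3,4}: the hard-margin boundary is the
        midpoint 2, so the decision must change sign inside (1, 3)."""
        M = FeatureMatrix(
            X=np.array([[0.0], [1.0], [3.0], [4.0]]),
            y=[-1, -1, 1, 1],
            feature_ids=[0],
        )
        model = train(M, SVMConfig(kernel="linear", C=1000.0))
        lo = decision_function(model, [[1.0]])[0]
        hi = decision_function(model, [[3.0]])[0]
        assert lo < 0 < hi
        # brute-force margin maximization puts the crossing at 2
        assert decision_function(model, [[2.0]])[0] == pytest.approx(0.0, abs=1e-3)

    def test_kkt_conditions(self, separable_matrix):
        cfg = SVMConfig()
        model = train(separable_matrix, cfg)
        alpha_y = model.dual_coefs
        assert np.all(np.abs(alpha_y) <= cfg.C + 1e-9)  # 0 <= alpha_i <= C
        assert abs(alpha_y.sum()) <= 1e-6  # sum alpha_i y_i = 0

    def test_decision_matches_solver(self, strong_signal_matrix):
        """Our kernel-expansion decision values must equal libsvm's."""
        from sklearn.svm import SVC

        M = strong_signal_matrix
        cfg = SVMConfig()
        model = train(M, cfg)
        svc = SVC(C=cfg.C, kernel="rbf", gamma=cfg.gamma)
        svc.fit(M.X, M.y)
        ours = decision_function(model, M.X[:25])
        theirs = svc.decision_function(M.X[:25])
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_shrinking_c_never_raises_training_accuracy(self, separable_matrix):
        accs = []
        for C in (0.01, 1.0, 11.0):
            model = train(separable_matrix, SVMConfig(C=C))
            labels, _ = predict(model, separable_matrix.X)
            accs.append(np.mean(labels == separable_matrix.y))
        assert accs[0] <= accs[1] <= accs[2]


class TestPredict:
    def test_tie_score_goes_positive(self, separable_matrix):
        model = train(separable_matrix, SVMConfig())
        model.bias = -decision_function(model, separable_matrix.X[:1])[0] + model.bias
        labels, scores = predict(model, separable_matrix.X[:1])
        assert scores[0] == 0.0 and labels[0] == 1

    def test_row_order_equivariance(self, separable_matrix, rng):
        model = train(separable_matrix, SVMConfig())
        perm = rng.permutation(separable_matrix.n_samples)
        _, s1 = predict(model, separable_matrix.X)
        _, s2 = predict(model, separable_matrix.X[perm])
        assert np.array_equal(s1[perm], s2)

    def test_feature_mismatch_names_missing(self, separable_matrix):
        model = train(separable_matrix, SVMConfig())
        smaller = FeatureMatrix(
            X=separable_matrix.X[:, :3],
            y=separable_matrix.y,
            feature_ids=separable_matrix.feature_ids[:3],
        )
        with pytest.raises(KeyError, match="3"):
            predict(model, smaller)

    def test_scaler_applied_from_raw_features(self, separable_matrix):
        """A model trained on scaled features reproduces its training-time
        transform when fed raw features."""
        from snaresap import apply_scaler, fit_scaler

        scaler = fit_scaler(separable_matrix, "minmax")
        scaled = apply_scaler(separable_matrix, scaler)
        model = train(
            scaled, SVMConfig(), scaler, scaler_feature_ids=separable_matrix.feature_ids
        )
        _, from_raw = predict(model, separable_matrix)
        _, from_scaled = predict(model, scaled.X)
        assert np.allclose(from_raw, from_scaled)


class TestPersistence:
    def test_round_trip_identical_scores(self, tmp_path, separable_matrix):
        from snaresap import apply_scaler, fit_scaler

        scaler = fit_scaler(separable_matrix, "minmax")
        scaled = apply_scaler(separable_matrix, scaler)
        model = train(scaled, SVMConfig(), scaler, separable_matrix.feature_ids)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        _, s1 = predict(model, separable_matrix)
        _, s2 = predict(loaded, separable_matrix)
        assert np.array_equal(s1, s2)  # bit-identical after JSON round trip

    def test_corrupted_file(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_wrong_format(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ModelFormatError, match="not a"):
            load_model(path)

    def test_version_mismatch(self, tmp_path, separable_matrix):
        import json

        model = train(separable_matrix, SVMConfig())
        path = tmp_path / "model.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        doc["version"] = 999
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)

    def test_no_scaler_loads_identity(self, tmp_path, separable_matrix):
        model = train(separable_matrix, SVMConfig())
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.scaler.method == "none"
        assert isinstance(loaded.scaler, NormalizationParams)
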