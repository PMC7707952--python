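"""RBF nucleus classifier: standardization, activations, training recipe,
determinism, and the analytic two-Gaussian oracle."""

import json

import numpy as np
import pytest
from scipy.stats import norm

from cytodx.rbf import (RBFConfig, RBFModel, fit_rbf, fit_standardizer,
                        predict_nucleus, rbf_activations, rbf_widths,
                        solve_output_weights)


class TestStandardizer:
    def test_two_point_example(self):
        std, z = fit_standardizer(np.array([[0.0], [2.0]]))
        assert std.mean[0] == 1.0 and std.sd[0] == 1.0
        np.testing.assert_allclose(z.ravel(), [-1.0, 1.0])

    def test_identity_on_standardized_data(self, rng):
        x = rng.standard_normal((500, 4))
        x = (x - x.mean(0)) / x.std(0)
        std, z = fit_standardizer(x)
        np.testing.assert_allclose(z, x, atol=1e-12)

    def test_round_trip(self, rng):
        x = rng.normal(5, 3, (100, 6))
        std, z = fit_standardizer(x)
        np.testing.assert_allclose(std.inverse_transform(z), x, atol=1e-9)

    def test_constant_column_dropped(self, rng):
        x = np.column_stack([rng.standard_normal(50), np.full(50, 7.0)])
        std, z = fit_standardizer(x, feature_names=["a", "b"])
        assert std.dropped == ["b"]
        assert z.shape[1] == 1


class TestActivations:
    def test_closed_forms(self):
        centers = np.array([[0.0, 0.0], [3.0, 4.0]])
        widths = np.array([1.0, 5.0])
        phi = rbf_activations(np.array([0.0, 0.0]), centers, widths)
        assert phi[0, 0] == pytest.approx(1.0)          # at the center
        assert phi[0, 1] == pytest.approx(np.exp(-0.5))  # distance == width

    def test_matches_scalar_recomputation(self, rng):
        x = rng.standard_normal((5, 3))
        centers = rng.standard_normal((4, 3))
        widths = rng.uniform(0.5, 2.0, 4)
        phi = rbf_activations(x, centers, widths)
        for i in range(5):
            for j in range(4):
                d2 = ((x[i] - centers[j]) ** 2).sum()
                assert phi[i, j] == pytest.approx(
                    np.exp(-d2 / (2 * widths[j] ** 2)))

    def test_interpolation_limit_reproduces_targets(self, rng):
        x = rng.standard_normal((20, 3))
        y = rng.integers(0, 2, 20).astype(float)
        phi = rbf_activations(x, x, np.full(20, 1e-2))
        w = solve_output_weights(phi, y, ridge_lambda=0.0)
        scores = np.column_stack([np.ones(20), phi]) @ w
        np.testing.assert_allclose(scores, y, atol=1e-6)


class TestFit:
    def test_separable_blobs_perfect_training_accuracy(self, rng):
        x = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (100, 2))])
        y = np.array(["benign"] * 100 + ["malignant"] * 100)
        model = fit_rbf(x, y, RBFConfig(k_grid=(2,), seed=0))
        assert (model.predict(x) == y).mean() == 1.0

    def test_two_gaussian_accuracy_near_bayes(self, rng):
        # centers ±1, unit variance: the Bayes rule (sign of x) has
        # accuracy Φ(1) ≈ 0.8413
        xtr = np.concatenate([rng.normal(-1, 1, 2000),
                              rng.normal(1, 1, 2000)])[:, None]
        ytr = np.array(["benign"] * 2000 + ["malignant"] * 2000)
        model = fit_rbf(xtr, ytr, RBFConfig(seed=5))
        xte = np.concatenate([rng.normal(-1, 1, 5000),
                              rng.normal(1, 1, 5000)])[:, None]
        yte = np.array(["benign"] * 5000 + ["malignant"] * 5000)
        acc = (model.predict(xte) == yte).mean()
        assert acc == pytest.approx(norm.cdf(1.0), abs=0.03)

    def test_deterministic_and_order_invariant(self, rng):
        x = rng.standard_normal((300, 4))
        y = np.where(rng.random(300) < 0.4, "malignant", "benign")
        cfg = RBFConfig(k_grid=(5, 10), seed=7)
        m1 = fit_rbf(x, y, cfg)
        m2 = fit_rbf(x, y, cfg)
        perm = rng.permutation(300)
        m3 = fit_rbf(x[perm], y[perm], cfg)
        assert m1.k == m2.k == m3.k
        np.testing.assert_array_equal(m1.output_weights, m2.output_weights)
        np.testing.assert_array_equal(m1.output_weights, m3.output_weights)
        assert m1.selection_record == m3.selection_record

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((50, 2))
        with pytest.raises(ValueError):
            fit_rbf(x, np.array(["benign"] * 50), RBFConfig(k_grid=(2,)))

    def test_score_is_continuous(self, rng):
        x = rng.standard_normal((100, 3))
        y = np.where(x[:, 0] > 0, "malignant", "benign")
        model = fit_rbf(x, y, RBFConfig(k_grid=(4,), seed=1))
        x0 = rng.standard_normal(3)
        s0 = model.decision_function(x0[None])[0]
        s1 = model.decision_function((x0 + 1e-9)[None])[0]
        assert abs(s1 - s0) < 1e-6


class TestPredict:
    def test_tie_goes_malignant(self, rng):
        x = rng.standard_normal((60, 2))
        y = np.where(x[:, 0] > 0, "malignant", "benign")
        model = fit_rbf(x, y, RBFConfig(k_grid=(3,), seed=2))
        model.decision_cut = float(model.decision_function(x[:1])[0])
        assert predict_nucleus(model, x[0]).label == "malignant"

    def test_batch_equals_elementwise(self, rng):
        x = rng.standard_normal((60, 2))
        y = np.where(x[:, 0] > 0, "malignant", "benign")
        model = fit_rbf(x, y, RBFConfig(k_grid=(3,), seed=2))
        batch = model.predict(x)
        single = [predict_nucleus(model, xi).label for xi in x]
        assert list(batch) == single

    def test_feature_count_mismatch_named(self, rng):
        x = rng.standard_normal((60, 3))
        y = np.where(x[:, 0] > 0, "malignant", "benign")
        model = fit_rbf(x, y, RBFConfig(k_grid=(3,), seed=2),
                        feature_names=["area", "iod", "sd_od"])
        with pytest.raises(ValueError, match="area"):
            predict_nucleus(model, np.zeros(2))


class TestSerialization:
    def test_json_round_trip_bit_exact(self, rng):
        x = rng.standard_normal((120, 3))
        y = np.where(x.sum(1) > 0, "malignant", "benign")
        model = fit_rbf(x, y, RBFConfig(k_grid=(4,), seed=9))
        clone = RBFModel.from_json(model.to_json())
        np.testing.assert_array_equal(clone.centers, model.centers)
        np.testing.assert_array_equal(clone.widths, model.widths)
        np.testing.assert_array_equal(clone.output_weights, model.output_weights)
        np.testing.assert_array_equal(
            clone.decision_function(x), model.decision_function(x))

    def test_config_from_json(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps({"k_grid": [3, 6], "seed": 42}))
        cfg = RBFConfig.from_json(path)
        assert cfg.k_grid == (3, 6) and cfg.seed == 42


def test_widths_single_center_falls_back_to_point_spread(rng):
    x = rng.standard_normal((50, 2))
    w = rbf_widths(x.mean(0, keepdims=True), x)
    from scipy.spatial.distance import cdist
    assert w[0] == pytest.approx(cdist(x, x.mean(0, keepdims=True)).mean())


def test_stratified_holdout_preserves_class_ratio(rng):
    from cytodx.rbf import _stratified_holdout
    y = np.array([1.0] * 30 + [0.0] * 70)
    val = _stratified_holdout(y, 0.2, np.random.default_rng(0))
    assert val.sum() == 20
    assert y[val].sum() == pytest.approx(6, abs=1)
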