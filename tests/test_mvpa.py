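"""Kernel construction, LOSOCV mechanics (no leakage), metric arithmetic,
and chance-level calibration on pure noise."""

import numpy as np
import pytest
from sklearn.svm import SVC

from conftest import gaussian_features
from gbcmvpa.mvpa import (CVResult, FeatureMatrix, ModelSpec, build_linear_kernel,
                          center_gram, compute_metrics, fit_predict, losocv_folds,
                          run_losocv)
from gbcmvpa.permutation import compute_weight_map


class TestLinearKernel:
    def test_orthogonal_unit_rows_uncentered(self):
        X = np.eye(2)
        K, mu = build_linear_kernel(X, center=False)
        np.testing.assert_allclose(K, np.eye(2))
        np.testing.assert_array_equal(mu, 0)

    def test_centered_kernel_rows_sum_to_zero(self, rng):
        X = rng.standard_normal((7, 4))
        K, _ = build_linear_kernel(X)
        np.testing.assert_allclose(K.sum(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_hand_computed_entries(self):
        X = np.array([[1.0, 2.0], [3.0, -1.0], [0.0, 0.5]])
        K, _ = build_linear_kernel(X, center=False)
        np.testing.assert_allclose(K, X @ X.T)
        assert K[0, 1] == pytest.approx(1 * 3 + 2 * -1)

    def test_centering_uses_training_rows_only(self, rng):
        X = rng.standard_normal((6, 3))
        train = np.array([0, 1, 2])
        K, mu = build_linear_kernel(X, train)
        np.testing.assert_allclose(mu, X[:3].mean(axis=0))
        Xc = X - mu
        np.testing.assert_allclose(K, Xc @ Xc.T, atol=1e-12)

    def test_empty_train_set_raises(self, rng):
        with pytest.raises(ValueError):
            build_linear_kernel(rng.standard_normal((4, 2)), np.array([], dtype=int))

    def test_center_gram_identity(self, rng):
        X = rng.standard_normal((9, 5))
        G = X @ X.T
        for i in range(9):
            train = np.delete(np.arange(9), i)
            K_direct, _ = build_linear_kernel(X, train)
            np.testing.assert_allclose(center_gram(G, train), K_direct, atol=1e-9)


class TestFitPredict:
    def test_separable_svm(self):
        X = np.array([[-1.0], [1.0], [0.5]])
        y = np.array(["neg", "pos", "pos"])
        K, _ = build_linear_kernel(X, np.array([0, 1]), center=False)
        pred, scores = fit_predict(ModelSpec(algorithm="svm"), K, y,
                                   np.array([0, 1]), np.array([2]))
        assert pred[0] == "pos"
        assert scores[0, 1] > 0

    def test_gpc_symmetric_point_is_uncertain(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0], [0.0]])
        y = np.array(["a", "a", "b", "b", "?"])
        K, _ = build_linear_kernel(X, np.arange(4), center=True)
        _, scores = fit_predict(ModelSpec(algorithm="gpc-binary"), K, y,
                                np.arange(4), np.array([4]))
        assert scores[0, 1] == pytest.approx(0.5, abs=0.01)

    def test_single_class_training_raises(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["a", "a", "b"])
        K, _ = build_linear_kernel(X)
        with pytest.raises(ValueError):
            fit_predict(ModelSpec(algorithm="svm"), K, y, np.array([0, 1]), np.array([2]))


class TestLOSOCV:
    def test_each_subject_held_out_once(self):
        feats = gaussian_features(4, 6, seed=2)
        cv = run_losocv(feats, ModelSpec(algorithm="svm"))
        assert sorted(cv.subject_ids) == sorted(feats.subject_ids)
        assert len(losocv_folds(8)) == 8
        assert cv.scores.shape == (8, 2)

    def test_single_subject_class_raises(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        feats = FeatureMatrix(X=X, subject_ids=[f"s{i}" for i in range(5)],
                              labels=np.array(["a", "a", "a", "a", "b"]))
        with pytest.raises(ValueError):
            run_losocv(feats, ModelSpec(algorithm="svm"))

    def test_no_leakage_from_held_out_subject(self):
        # corrupting the held-out row must not change that fold's model
        feats = gaussian_features(5, 4, seed=3)
        model = ModelSpec(algorithm="svm")
        wmap1 = compute_weight_map(feats, model)
        X2 = feats.X.copy()
        X2[0] = 1e3  # garbage in subject 0's features
        feats2 = FeatureMatrix(X=X2, subject_ids=feats.subject_ids, labels=feats.labels)
        from gbcmvpa.mvpa import _fit_fold, _losocv_kernels
        k1 = _losocv_kernels(feats.X, True)
        k2 = _losocv_kernels(feats2.X, True)
        train = np.delete(np.arange(10), 0)
        fm1 = _fit_fold(model, k1[0], feats.labels, train, feats.classes())
        fm2 = _fit_fold(model, k2[0], feats2.labels, train, feats2.classes())
        np.testing.assert_allclose(fm1.alpha, fm2.alpha, atol=1e-8)

    def test_strongly_separable_is_perfect(self):
        feats = gaussian_features(8, 10, shift_cols=np.arange(5), shift=6.0, seed=4)
        rep = compute_metrics(run_losocv(feats, ModelSpec(algorithm="svm")))
        assert rep.balanced_accuracy == 1.0

    def test_three_separated_clusters_multiclass_gpc(self, rng):
        # three clusters at distance ~5 in feature space
        centers = np.array([[5.0, 0.0], [0.0, 5.0], [-5.0, -5.0]])
        X = np.vstack([c + rng.standard_normal((6, 2)) * 0.5 for c in centers])
        feats = FeatureMatrix(X=X, subject_ids=[f"s{i}" for i in range(18)],
                              labels=np.repeat(["a", "b", "c"], 6))
        rep = compute_metrics(run_losocv(feats, ModelSpec(algorithm="gpc-multiclass")))
        assert rep.total_accuracy == 1.0

    def test_kernel_svm_matches_primal_linear_svm(self, rng):
        X = rng.standard_normal((14, 6))
        y = np.repeat(["a", "b"], 7)
        mu = X.mean(axis=0)
        K, _ = build_linear_kernel(X, center=True)
        pred_kernel, _ = fit_predict(ModelSpec(algorithm="svm"), K, y,
                                     np.arange(10), np.arange(10, 14))
        primal = SVC(C=1.0, kernel="linear").fit(X[:10] - mu, y[:10])
        np.testing.assert_array_equal(pred_kernel, primal.predict(X[10:] - mu))


class TestMetrics:
    def binary_cv(self, tp, fn, tn, fp):
        y_true = np.array(["neg"] * (tn + fp) + ["pos"] * (tp + fn))
        y_pred = np.array(["neg"] * tn + ["pos"] * fp + ["pos"] * tp + ["neg"] * fn)
        n = len(y_true)
        scores = np.column_stack([-(y_pred == "pos").astype(float),
                                  (y_pred == "pos").astype(float)])
        return CVResult([f"s{i}" for i in range(n)], y_true, y_pred, scores,
                        np.array(["neg", "pos"]))

    def test_printed_binary_metric_pair(self):
        # 31/41 positives and 43/43 negatives correct
        rep = compute_metrics(self.binary_cv(tp=31, fn=10, tn=43, fp=0))
        assert 100 * rep.per_class.loc["pos", "sensitivity"] == pytest.approx(75.61, abs=0.005)
        assert rep.per_class.loc["pos", "specificity"] == 1.0
        assert 100 * rep.balanced_accuracy == pytest.approx(87.80, abs=0.005)

    def test_perfect_predictions(self):
        rep = compute_metrics(self.binary_cv(tp=5, fn=0, tn=5, fp=0))
        assert rep.balanced_accuracy == 1.0 and rep.total_accuracy == 1.0
        assert (rep.per_class == 1.0).all().all()
        assert rep.roc_auc == 1.0

    def test_fourclass_target_sensitivity(self):
        # 29 of 41 class-1 subjects correct -> 70.73 %
        y_true = np.array(["c1"] * 41 + ["c2"] * 20)
        y_pred = np.array(["c1"] * 29 + ["c2"] * 12 + ["c2"] * 20)
        cv = CVResult([f"s{i}" for i in range(61)], y_true, y_pred,
                      np.zeros((61, 2)), np.array(["c1", "c2"]))
        rep = compute_metrics(cv)
        assert 100 * rep.per_class.loc["c1", "sensitivity"] == pytest.approx(70.73, abs=0.005)

    def test_balanced_accuracy_is_mean_recall_multiclass(self):
        y_true = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 2)
        y_pred = np.array(["a", "a", "b", "b", "b", "b", "b", "c", "c", "c"])
        cv = CVResult([f"s{i}" for i in range(10)], y_true, y_pred,
                      np.zeros((10, 3)), np.array(["a", "b", "c"]))
        rep = compute_metrics(cv)
        assert rep.balanced_accuracy == pytest.approx((2 / 4 + 3 / 4 + 2 / 2) / 3)

    def test_roc_auc_invariant_to_monotone_score_transform(self, rng):
        y_true = np.repeat(["a", "b"], 10)
        scores = rng.standard_normal(20)
        def report(s):
            sc = np.column_stack([-s, s])
            cv = CVResult([f"s{i}" for i in range(20)], y_true,
                          np.where(s > 0, "b", "a"), sc, np.array(["a", "b"]))
            return compute_metrics(cv).roc_auc
        assert report(scores) == pytest.approx(report(np.exp(scores)), abs=1e-12)


class TestNullCalibration:
    def test_binary_chance_level_over_seeds(self):
        # LOSOCV balanced accuracy on pure noise, 24 seeds x 16 subjects:
        # mean stays inside the 95 % binomial band around 0.5
        bas = []
        for seed in range(24):
            feats = gaussian_features(8, 40, seed=seed)
            rep = compute_metrics(run_losocv(feats, ModelSpec(algorithm="svm")))
            bas.append(rep.balanced_accuracy)
        n_total = 24 * 16
        half_width = 1.96 * np.sqrt(0.25 / n_total)
        assert abs(np.mean(bas) - 0.5) < half_width

    def test_fourclass_chance_level_over_seeds(self):
        bas = []
        for seed in range(24):
            feats = gaussian_features(6, 40, n_classes=4, seed=seed)
            rep = compute_metrics(run_losocv(feats, ModelSpec(algorithm="gpc-multiclass")))
            bas.append(rep.balanced_accuracy)
        chance = 0.25
        n_total = 24 * 24
        half_width = 1.96 * np.sqrt(chance * (1 - chance) / n_total)
        assert abs(np.mean(bas) - chance) < half_width


class TestContainers:
    def test_duplicate_subject_ids_raise(self):
        with pytest.raises(ValueError):
            CVResult(["s1", "s1"], np.array(["a", "b"]), np.array(["a", "b"]),
                     np.zeros((2, 2)), np.array(["a", "b"]))

    def test_nonfinite_features_raise(self):
        X = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError):
            FeatureMatrix(X=X, subject_ids=["s1"], labels=np.array(["a"]))

    def test_unknown_algorithm_raises(self):
        with pytest.raises(ValueError):
            ModelSpec(algorithm="forest")
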