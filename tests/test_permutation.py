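"""Permutation inference: counting rule, null calibration, weight-map
reconstruction against a primal solver, and cluster extraction vs a
flood-fill oracle."""

import numpy as np
import pytest
from sklearn.svm import SVC

from conftest import gaussian_features
from gbcmvpa.mvpa import FeatureMatrix, ModelSpec
from gbcmvpa.permutation import (PermutationParams, WeightMap, compute_weight_map,
                                 empirical_p, extract_clusters, format_p,
                                 permutation_analysis, permutation_test_performance,
                                 voxelwise_weight_significance)


class TestCountingRule:
    def test_observed_above_all_nulls(self):
        assert empirical_p(np.full(1000, 0.5), 0.9) == 0.0
        assert format_p(0.0, 1000) == "< 0.001"

    def test_ties_count_as_extreme(self):
        assert empirical_p(np.full(100, 0.7), 0.7) == 1.0

    def test_smoothed_estimator(self):
        assert empirical_p(np.full(99, 0.5), 0.9, smoothed=True) == pytest.approx(1 / 100)

    def test_p_values_are_multiples_of_inverse_nperm(self, rng):
        null = rng.random(40)
        for obs in rng.random(10):
            p = empirical_p(null, obs)
            assert 0.0 <= p <= 1.0
            assert (p * 40) == pytest.approx(round(p * 40))


class TestPerformancePermutation:
    def test_separable_features_significant(self):
        feats = gaussian_features(8, 20, shift_cols=np.arange(8), shift=4.0, seed=1)
        res = permutation_test_performance(feats, ModelSpec(algorithm="svm"),
                                           PermutationParams(n_perm=60, seed=9))
        assert res.p_values["balanced_accuracy"] <= 1 / 60 + 1e-12
        assert res.observed.balanced_accuracy == 1.0

    def test_same_seed_reproduces_null(self):
        feats = gaussian_features(5, 10, seed=2)
        params = PermutationParams(n_perm=25, seed=77)
        r1 = permutation_test_performance(feats, ModelSpec(algorithm="svm"), params)
        r2 = permutation_test_performance(feats, ModelSpec(algorithm="svm"), params)
        np.testing.assert_array_equal(r1.null_metrics["balanced_accuracy"],
                                      r2.null_metrics["balanced_accuracy"])

    def test_null_p_distribution_uniform(self):
        # 120 pure-noise mini-runs, 40 permutations each: P(p <= 0.05) = 2/40
        hits = 0
        n_runs = 120
        for seed in range(n_runs):
            feats = gaussian_features(4, 12, seed=seed)
            res = permutation_test_performance(
                feats, ModelSpec(algorithm="svm"),
                PermutationParams(n_perm=40, seed=1000 + seed))
            hits += res.p_values["balanced_accuracy"] <= 0.05
        expected = 2 / 40
        half_width = 3 * np.sqrt(expected * (1 - expected) / n_runs)
        assert abs(hits / n_runs - expected) < half_width

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            PermutationParams(n_perm=0).validate()


class TestWeightMaps:
    def test_two_subject_sign(self):
        feats = FeatureMatrix(X=np.array([[-1.0], [1.0]]), subject_ids=["s1", "s2"],
                              labels=np.array(["a", "b"]))
        wmap = compute_weight_map(feats, ModelSpec(algorithm="svm"), whole_sample_refit=True)
        assert wmap.weights[0] > 0  # class "b" (positive) has the larger mean

    def test_dual_reconstruction_matches_primal_solver(self, rng):
        X = rng.standard_normal((20, 10))
        y = np.repeat(["a", "b"], 10)
        X[10:, :3] += 1.5
        feats = FeatureMatrix(X=X, subject_ids=[f"s{i}" for i in range(20)], labels=y)
        wmap = compute_weight_map(feats, ModelSpec(algorithm="svm"), whole_sample_refit=True)
        primal = SVC(C=1.0, kernel="linear").fit(X - X.mean(0), y)
        np.testing.assert_allclose(wmap.weights, primal.coef_[0], atol=1e-6)

    def test_duplicated_voxel_splits_weight_symmetrically(self, rng):
        # duplicating a feature column splits its weight equally between
        # the two copies (the margin objective treats them exchangeably)
        X = rng.standard_normal((16, 6))
        X[8:, 0] += 2.0
        y = np.repeat(["a", "b"], 8)
        ids = [f"s{i}" for i in range(16)]
        w1 = compute_weight_map(FeatureMatrix(X=X, subject_ids=ids, labels=y),
                                ModelSpec(algorithm="svm")).weights
        Xdup = np.column_stack([X, X[:, 0]])
        w2 = compute_weight_map(FeatureMatrix(X=Xdup, subject_ids=ids, labels=y),
                                ModelSpec(algorithm="svm")).weights
        assert w2[0] == pytest.approx(w2[-1], abs=1e-8)
        assert np.sign(w2[0]) == np.sign(w1[0])
        # the combined contribution stays on the original's scale
        assert 0.5 * abs(w1[0]) < abs(w2[0] + w2[-1]) < 2.0 * abs(w1[0])

    def test_multiclass_weight_map_rejected(self):
        feats = gaussian_features(3, 4, n_classes=3, seed=0)
        with pytest.raises(ValueError):
            compute_weight_map(feats, ModelSpec(algorithm="gpc-multiclass"))


@pytest.fixture(scope="module")
def planted_run():
    rng = np.random.default_rng(21)
    n_per, V = 20, 500
    planted = np.arange(40)
    X = rng.standard_normal((2 * n_per, V))
    X[n_per:, planted] += 2.0  # d = 2 in the planted columns
    X = np.column_stack([X, np.full(2 * n_per, 3.0)])  # constant voxel at the end
    feats = FeatureMatrix(X=X, subject_ids=[f"s{i}" for i in range(2 * n_per)],
                          labels=np.repeat(["a", "b"], n_per))
    wmap = voxelwise_weight_significance(feats, ModelSpec(algorithm="svm"),
                                         PermutationParams(n_perm=1000, seed=5))
    return wmap, planted, V


class TestVoxelSignificance:

    def test_planted_region_recovered(self, planted_run):
        wmap, planted, V = planted_run
        frac_planted = np.mean(wmap.p_values[planted] <= 0.001)
        others = np.setdiff1d(np.arange(V), planted)
        frac_noise = np.mean(wmap.p_values[others] <= 0.001)
        assert frac_planted >= 0.5
        assert frac_noise <= 0.005

    def test_constant_voxel_has_zero_weight_and_p_one(self, planted_run):
        wmap, _, _ = planted_run
        assert wmap.weights[-1] == pytest.approx(0.0, abs=1e-10)
        assert wmap.p_values[-1] == 1.0

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((16, 2000))
        feats = FeatureMatrix(X=X, subject_ids=[f"s{i}" for i in range(16)],
                              labels=np.repeat(["a", "b"], 8))
        wmap = voxelwise_weight_significance(feats, ModelSpec(algorithm="svm"),
                                             PermutationParams(n_perm=1000, seed=6))
        # strict p < 0.001 hits 1/1001 of voxels in expectation
        frac = np.mean(wmap.p_values < 0.001)
        assert frac <= 0.004


class TestClusterExtraction:
    def params(self, **kw):
        defaults = dict(min_cluster_voxels=30, voxel_p_threshold=0.001, n_perm=10)
        defaults.update(kw)
        return PermutationParams(**defaults)

    def blob_maps(self, size, shape=(10, 10, 10), sign=1.0):
        p = np.ones(shape)
        w = np.zeros(shape)
        coords = np.argwhere(np.ones(shape, dtype=bool))[:size]
        # a compact blob: fill a cube region, first `size` voxels in C order
        filled = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    if filled < size:
                        p[i, j, k] = 0.0
                        w[i, j, k] = sign
                        filled += 1
        return p, w

    def test_31_voxel_blob_survives(self):
        p, w = self.blob_maps(31)
        assert len(extract_clusters(p, w, self.params())) == 1

    def test_30_voxel_blob_discarded(self):
        p, w = self.blob_maps(30)
        assert len(extract_clusters(p, w, self.params())) == 0

    def test_touching_opposite_signs_split(self):
        p = np.ones((12, 12, 12))
        w = np.zeros((12, 12, 12))
        p[2:6, 2:6, 2:6] = 0.0
        w[2:6, 2:6, 2:6] = 1.0     # 64 voxels positive
        p[6:10, 2:6, 2:6] = 0.0
        w[6:10, 2:6, 2:6] = -1.0   # 64 voxels negative, face-touching
        cs = extract_clusters(p, w, self.params())
        assert len(cs) == 2
        assert {c.sign for c in cs.clusters} == {"positive", "negative"}

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        supra = rng.random((15, 15, 15)) < 0.2
        p = np.where(supra, 0.0, 1.0)
        w = np.ones_like(p)
        cs = extract_clusters(p, w, self.params(min_cluster_voxels=0,
                                                connectivity=connectivity))
        sizes = sorted(c.size for c in cs.clusters)
        assert sizes == sorted(len(c) for c in flood_fill_components(supra, connectivity))

    def test_threshold_monotonicity(self, rng):
        p = rng.random((8, 8, 8))
        w = rng.standard_normal((8, 8, 8))
        counts = []
        for thr in (0.001, 0.01, 0.05, 0.2):
            cs = extract_clusters(p, w, self.params(voxel_p_threshold=thr,
                                                    min_cluster_voxels=0))
            counts.append(sum(c.size for c in cs.clusters))
        assert counts == sorted(counts)

    def test_cluster_table_columns(self):
        p, w = self.blob_maps(40)
        df = extract_clusters(p, w, self.params(), voxel_size_mm=3.0).to_frame()
        assert list(df.columns)[:3] == ["cluster_id", "size", "sign"]
        assert df.loc[0, "size"] == 40


def flood_fill_components(binary, connectivity):
    """Independent BFS component labelling oracle."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if any(x < 0 or x >= s for x, s in zip(nb, binary.shape)):
                    continue
                if binary[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(comp)
    return comps


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


class TestCountingRuleProperties:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(null=hnp.arrays(np.float64, st.integers(1, 60),
                           elements=st.floats(-5, 5, allow_nan=False)),
           obs=st.floats(-5, 5, allow_nan=False))
    def test_p_is_a_multiple_of_inverse_nperm_in_unit_interval(self, null, obs):
        p = empirical_p(null, obs)
        assert 0.0 <= p <= 1.0
        assert p * null.size == pytest.approx(round(p * null.size), abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(null=hnp.arrays(np.float64, st.integers(1, 40),
                           elements=st.floats(-5, 5, allow_nan=False)),
           obs=st.floats(-5, 5, allow_nan=False),
           shift=st.floats(0, 3, allow_nan=False))
    def test_p_monotone_in_observed_value(self, null, obs, shift):
        assert empirical_p(null, obs + shift) <= empirical_p(null, obs)
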