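"""MDS, landscape PCA, permutation tests, SVM/SVR, baselines."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import wormtda as w
from wormtda.series import TimeSeries
from wormtda.stats import (
    LabeledFeatures,
    classical_mds,
    coordinatewise_std,
    landscape_pca,
    pairwise_permutation_tests,
    permutation_test,
    posture_std_baseline,
    speed_baseline,
    svm_classify,
    svr_estimate,
)


class TestClassicalMDS:
    def test_equilateral_triangle_recovered(self):
        D = np.ones((3, 3)) - np.eye(3)
        Y = classical_mds(D, 2)
        got = pdist(Y)
        assert np.allclose(got, 1.0, atol=1e-9)

    def test_planar_points_reproduced(self, rng):
        X = rng.normal(size=(8, 2))
        D = squareform(pdist(X))
        Y = classical_mds(D, 2)
        assert np.allclose(pdist(Y), pdist(X), atol=1e-8)

    def test_duplicate_samples_coincide(self):
        X = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1]])
        D = squareform(pdist(X))
        Y = classical_mds(D, 2)
        assert np.allclose(Y[1], Y[2], atol=1e-9)

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            classical_mds(np.zeros((3, 4)))


class TestLandscapePCA:
    def test_affine_line_explained_by_one_component(self, rng):
        direction = rng.normal(size=20)
        X = np.outer(np.linspace(0, 1, 9), direction) + rng.normal(size=20)
        F = LabeledFeatures(X, ["a"] * 9)
        _, _, cumvar = landscape_pca(F, 1)
        assert cumvar[0] == pytest.approx(1.0, abs=1e-8)

    def test_cumulative_variance_reaches_one(self, rng):
        X = rng.normal(size=(6, 10))
        F = LabeledFeatures(X, ["a"] * 6)
        _, _, cumvar = landscape_pca(F, 5)
        assert cumvar[-1] == pytest.approx(1.0, abs=1e-10)

    def test_projection_of_mean_is_mean_of_projections(self, rng):
        X = rng.normal(size=(10, 12))
        F = LabeledFeatures(X, ["a"] * 5 + ["b"] * 5)
        comps, projs, _ = landscape_pca(F, 2)
        class_mean_proj = (X[:5].mean(axis=0) - X.mean(axis=0)) @ comps.T
        assert np.allclose(class_mean_proj, projs[:5].mean(axis=0), atol=1e-10)

    def test_k_beyond_rank_warns(self, rng):
        X = np.outer(rng.normal(size=4), rng.normal(size=10))
        F = LabeledFeatures(X, ["a"] * 4)
        with pytest.warns(UserWarning):
            landscape_pca(F, 3)


class TestCoordinatewiseStd:
    def test_identical_samples_zero(self):
        F = LabeledFeatures(np.ones((4, 5)), ["a"] * 4)
        assert np.allclose(coordinatewise_std(F)["a"], 0.0)

    def test_two_sample_delta(self):
        X = np.zeros((2, 4))
        X[1, 2] = 1.0
        F = LabeledFeatures(X, ["a", "a"])
        out = coordinatewise_std(F)["a"]
        expected = np.zeros(4)
        expected[2] = 1 / np.sqrt(2)
        assert np.allclose(out, expected)

    def test_single_sample_class_raises(self):
        F = LabeledFeatures(np.zeros((3, 2)), ["a", "a", "b"])
        with pytest.raises(ValueError):
            coordinatewise_std(F)


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        A = np.tile([1.0, 2.0], (3, 1))
        assert permutation_test(A, A, n_perm=100, seed=0) == 1.0

    def test_separated_groups_tiny_p(self, rng):
        A = rng.normal(0, 1, size=(10, 3))
        B = rng.normal(10, 1, size=(10, 3))
        p = permutation_test(A, B, n_perm=1000, seed=0)
        assert p <= 0.001

    def test_p_in_unit_interval_and_deterministic(self, rng):
        A = rng.normal(size=(5, 2))
        B = rng.normal(size=(5, 2))
        p1 = permutation_test(A, B, n_perm=500, seed=3)
        p2 = permutation_test(A, B, n_perm=500, seed=3)
        assert p1 == p2 and 0 < p1 <= 1

    def test_null_uniformity_ks_band(self):
        """Under an exchangeable null the p-value is ~uniform: empirical CDF
        within the 95% Kolmogorov-Smirnov band over 200 replicates."""
        rng = np.random.default_rng(0)
        pvals = []
        for rep in range(200):
            X = rng.normal(size=(10, 2))
            pvals.append(permutation_test(X[:5], X[5:], n_perm=200, seed=rep))
        pvals = np.sort(pvals)
        n = len(pvals)
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        band = 1.36 / np.sqrt(n)  # KS 95%
        dev = max(np.abs(ecdf_hi - pvals).max(), np.abs(pvals - ecdf_lo).max())
        assert dev <= band + 0.25 / 200  # discreteness slack of 1/n_perm scale

    def test_monotone_in_separation(self, rng):
        noise_a = rng.normal(size=(8, 4))
        noise_b = rng.normal(size=(8, 4))
        ps = []
        for sep in (0.5, 1.5, 3.0, 6.0):
            A = noise_a
            B = noise_b + sep
            ps.append(permutation_test(A, B, n_perm=2000, seed=9))
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_bad_inputs(self, rng):
        A = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            permutation_test(A[:1], A, n_perm=10)
        with pytest.raises(ValueError):
            permutation_test(A, A, n_perm=0)


class TestSVM:
    def test_separable_classes_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        F = LabeledFeatures(X, ["a"] * 10 + ["b"] * 10)
        acc, conf = svm_classify(F, folds=5, repeats=3, seed=0)
        assert acc == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.normal(size=(40, 3))
        labels = (["a", "b", "c", "d"] * 10)[:40]
        F = LabeledFeatures(X, labels)
        acc, _ = svm_classify(F, folds=5, repeats=5, seed=1)
        # chance = 0.25; binomial 99% band for 40 samples, 5 repeats
        assert acc < 0.5

    def test_confusion_rows_sum_to_class_counts(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(2, 1, (10, 2))])
        F = LabeledFeatures(X, ["a"] * 10 + ["b"] * 10)
        _, conf = svm_classify(F, folds=5, repeats=2, seed=0)
        assert conf.sum(axis=1).tolist() == [10, 10]

    def test_pairwise_table_covers_all_pairs(self, rng):
        X = rng.normal(size=(12, 3))
        F = LabeledFeatures(X, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        table = pairwise_permutation_tests(F, n_perm=50, seed=0)
        assert set(table) == {("a", "b"), ("a", "c"), ("b", "c")}


class TestSVR:
    def test_linear_target_small_out_of_fold_error(self, rng):
        x = np.linspace(0, 3, 40)
        X = np.c_[x, rng.normal(0, 0.01, 40)]
        F = LabeledFeatures(X, ["a"] * 40, numeric_targets=x)
        pred = svr_estimate(F, folds=5, repeats=3, seed=0)
        rmse = np.sqrt(np.mean((pred - x) ** 2))
        assert rmse <= 0.15  # within the epsilon-insensitive tube scale

    def test_permuted_targets_uncorrelated(self, rng):
        X = rng.normal(size=(40, 3))
        t = rng.permutation(np.repeat([0.5, 1, 2, 3], 10))
        F = LabeledFeatures(X, ["a"] * 40, numeric_targets=t)
        pred = svr_estimate(F, folds=5, repeats=2, seed=0)
        r = np.corrcoef(pred, t)[0, 1] if pred.std() > 0 else 0.0
        assert abs(r) < 0.3

    def test_prediction_length_and_missing_targets(self, rng):
        X = rng.normal(size=(20, 2))
        F = LabeledFeatures(X, ["a"] * 20, numeric_targets=np.arange(20.0))
        assert len(svr_estimate(F, folds=4, repeats=1, seed=0)) == 20
        F2 = LabeledFeatures(X, ["a"] * 20)
        with pytest.raises(ValueError):
            svr_estimate(F2)


class TestBaselines:
    def test_speed_constant_zero(self):
        series = TimeSeries(np.ones((5, 3)))
        assert speed_baseline(series) == 0.0

    def test_speed_alternating(self):
        delta = np.array([3.0, 4.0])
        frames = np.array([[0, 0], delta] * 4)
        assert speed_baseline(TimeSeries(frames)) == pytest.approx(5.0)

    def test_speed_scales_linearly(self, rng):
        X = rng.normal(size=(10, 4))
        assert speed_baseline(TimeSeries(3 * X)) == pytest.approx(
            3 * speed_baseline(TimeSeries(X))
        )

    def test_posture_std_constant_zero(self):
        assert np.allclose(posture_std_baseline(TimeSeries(np.ones((6, 4)))), 0.0)

    def test_posture_std_sinusoid_amplitude(self):
        t = np.arange(200)
        A = 0.7
        x = A * np.sin(2 * np.pi * t / 20)  # 10 whole periods
        series = TimeSeries(np.c_[x, np.zeros(200)])
        out = posture_std_baseline(series)
        assert out[0] == pytest.approx(A / np.sqrt(2), rel=5e-3)
        assert out.shape == (2,)

    def test_short_series_raise(self):
        with pytest.raises(ValueError):
            speed_baseline(TimeSeries(np.ones((1, 2))))
        with pytest.raises(ValueError):
            posture_std_baseline(TimeSeries(np.ones((1, 2))))
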