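import numpy as np
import pytest

import canospec as cs
from canospec.enhance import (
    FEATURE_ATTRS, KMeansResult, TreeNode, build_isolation_tree, c_psi,
    kmeans_fit, path_length,
)
from canospec.errors import DegenerateInputError
from canospec.types import ClusterCodebook, PointCloud


class TestCPsi:
    def test_piecewise_values(self):
        assert c_psi(2) == 1.0
        assert c_psi(1) == 0.0
        assert c_psi(0) == 0.0
        # c(4) = 2 (1 + 1/2 + 1/3) - 2 * 3 / 4
        assert c_psi(4) == pytest.approx(2 * (1 + 0.5 + 1 / 3) - 1.5, abs=1e-12)

    def test_exact_harmonic_sum_for_moderate_n(self):
        h = sum(1.0 / i for i in range(1, 1000))
        assert c_psi(1000) == pytest.approx(2 * h - 2 * 999 / 1000, rel=1e-12)


class TestPathLength:
    def test_single_record_tree_is_zero(self):
        assert path_length([0.0], TreeNode(n_samples=1)) == 0.0

    def test_balanced_two_leaf_tree(self):
        tree = TreeNode(n_samples=2, feature=0, threshold=0.5,
                        left=TreeNode(1), right=TreeNode(1))
        assert path_length([0.0], tree) == 1.0
        assert path_length([1.0], tree) == 1.0

    def test_hand_built_seven_node_tree_matches_manual_traversal(self):
        # depth-2 tree with a truncated leaf of size 3 on the right-right path
        tree = TreeNode(
            n_samples=6, feature=0, threshold=0.0,
            left=TreeNode(2, feature=1, threshold=1.0,
                          left=TreeNode(1), right=TreeNode(1)),
            right=TreeNode(4, feature=1, threshold=-1.0,
                           left=TreeNode(1), right=TreeNode(3)),
        )
        assert path_length([-1.0, 0.0], tree) == 2.0            # left, left
        assert path_length([-1.0, 2.0], tree) == 2.0            # left, right
        assert path_length([1.0, 0.0], tree) == 2.0 + c_psi(3)  # truncated node
        assert path_length([1.0, -2.0], tree) == 2.0

    def test_feature_dimension_mismatch(self):
        tree = TreeNode(n_samples=2, feature=3, threshold=0.0,
                        left=TreeNode(1), right=TreeNode(1))
        with pytest.raises(DegenerateInputError):
            path_length([0.0], tree)


class TestAnomalyScore:
    def test_closed_form_score_levels(self, rng):
        # forests where E[h] is forced to c(psi) and 2 c(psi) give 0.5 / 0.25
        psi = 16
        c = c_psi(psi)

        def fixed_tree(depth):
            # a chain tree every record traverses to its single-leaf end
            node = TreeNode(n_samples=1)
            for _ in range(depth):
                node = TreeNode(n_samples=2, feature=0, threshold=np.inf,
                                left=node, right=TreeNode(1))
            return node

        depth = int(round(c))
        trees = [fixed_tree(depth)]
        got = cs.anomaly_score([0.0], trees, psi)
        assert got == pytest.approx(2 ** (-depth / c))

    def test_mean_point_scores_below_planted_outlier(self, rng):
        X = rng.normal(size=(500, 5))
        det = cs.IsolationForestDetector(random_state=0).fit(X)
        s_center = det.score_samples(X.mean(axis=0, keepdims=True))[0]
        s_out = det.score_samples(np.full((1, 5), 10.0))[0]
        assert s_center < s_out
        assert 0 < s_center < 1 and 0 < s_out < 1

    def test_empty_forest_raises(self):
        with pytest.raises(DegenerateInputError):
            cs.anomaly_score([0.0], [], 16)


class TestRemoveOutliers:
    def _cloud(self, rng, n=2000, n_out=100):
        base = rng.normal(size=(n, 7))
        out_idx = rng.choice(n, n_out, replace=False)
        base[out_idx] += 10 * rng.choice([-1.0, 1.0], size=(n_out, 7))
        return PointCloud(
            x=base[:, 0], y=base[:, 1], z=base[:, 2], r=base[:, 3],
            g=base[:, 4], b=base[:, 5], nir=base[:, 6],
        ), out_idx

    def test_planted_ten_sigma_outlier_recall(self, rng):
        cloud, out_idx = self._cloud(rng)
        kept, removed = cs.remove_outliers(cloud, contamination=0.05, seed=1)
        removed_set = set(np.round(removed.x, 12))
        hit = np.isin(np.round(cloud.x[out_idx], 12), list(removed_set))
        assert hit.mean() >= 0.9

    def test_zero_contamination_is_identity(self, rng):
        cloud, _ = self._cloud(rng, n=100, n_out=5)
        kept, removed = cs.remove_outliers(cloud, contamination=0)
        assert len(kept) == 100 and len(removed) == 0

    def test_partition_conserves_points(self, rng):
        cloud, _ = self._cloud(rng, n=500, n_out=20)
        kept, removed = cs.remove_outliers(cloud, contamination=0.05, seed=2)
        assert len(kept) + len(removed) == 500
        assert len(removed) == int(np.ceil(0.05 * 500))

    def test_deterministic_for_fixed_seed(self, rng):
        cloud, _ = self._cloud(rng, n=400, n_out=20)
        a = cs.remove_outliers(cloud, contamination=0.05, seed=3)[0]
        b = cs.remove_outliers(cloud, contamination=0.05, seed=3)[0]
        assert np.array_equal(a.x, b.x)

    def test_small_sample_warns_and_uses_n(self, rng):
        cloud, _ = self._cloud(rng, n=100, n_out=5)
        with pytest.warns(UserWarning):
            cs.remove_outliers(cloud, contamination=0.1, seed=0)

    def test_sklearn_isolation_forest_agrees_on_ranking(self, rng):
        # independent cross-check: both implementations should give planted
        # outliers systematically higher anomaly rank than inliers
        from sklearn.ensemble import IsolationForest

        X = rng.normal(size=(600, 4))
        X[:30] += 8.0
        mine = cs.IsolationForestDetector(random_state=0).fit(X).score_samples(X)
        theirs = -IsolationForest(random_state=0).fit(X).score_samples(X)
        top_mine = set(np.argsort(mine)[-30:])
        top_theirs = set(np.argsort(theirs)[-30:])
        assert len(top_mine & top_theirs) >= 27


class TestKMeans:
    def test_four_point_example_attains_exhaustive_optimum(self):
        res = kmeans_fit([0.0, 0.0, 10.0, 10.0], 2, seed=1)
        assert res.centers.tolist() == [0.0, 10.0]
        assert res.sse == 0.0

    def test_k_equals_distinct_gives_zero_sse(self):
        res = kmeans_fit([1.0, 2.0, 5.0], 3, seed=0)
        assert res.sse == pytest.approx(0.0)

    def test_k_above_distinct_rejected(self):
        with pytest.raises(DegenerateInputError):
            kmeans_fit([1.0, 1.0, 2.0], 3)

    def test_lloyd_sse_non_increasing(self, rng):
        v = rng.normal(size=300) * 3 + np.repeat([0, 15], 150)
        res = kmeans_fit(v, 4, seed=5, n_init=1)
        h = np.array(res.history)
        assert np.all(np.diff(h) <= 1e-9)

    def test_matches_sklearn_on_separated_clusters(self, rng):
        from sklearn.cluster import KMeans

        v = np.concatenate([rng.normal(m, 0.3, 100) for m in (0, 10, 20)])
        mine = kmeans_fit(v, 3, seed=0).centers
        sk = np.sort(KMeans(3, n_init=10, random_state=0).fit(
            v.reshape(-1, 1)).cluster_centers_.ravel())
        np.testing.assert_allclose(mine, sk, atol=1e-6)


class TestSse:
    def test_hand_sum(self):
        assert cs.sse([0.0, 1.0], [0.5]) == pytest.approx(0.5)

    def test_centers_equal_data_gives_zero(self):
        assert cs.sse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_superset_of_centers_never_increases_sse(self, rng):
        v = rng.normal(size=100)
        small = [0.0]
        big = [0.0, 1.0, -1.0]
        assert cs.sse(v, big) <= cs.sse(v, small)


class TestElbow:
    def test_three_separated_gaussians(self):
        r = np.random.default_rng(7)
        v = np.concatenate([r.normal(m, 0.5, 200) for m in (0, 10, 20)])
        k, hist = cs.elbow_select_k(v, range(2, 13), seed=0)
        assert k == 3
        assert hist[3] < hist[2]

    def test_eight_mode_mixture(self):
        r = np.random.default_rng(1)
        modes = np.linspace(7.5, 14.0, 8)
        v = np.concatenate([r.normal(m, 0.12, 400) for m in modes])
        k, _ = cs.elbow_select_k(v, range(2, 13), seed=0)
        assert k == 8

    def test_degenerate_single_value_falls_back_to_lower_bound(self):
        with pytest.warns(UserWarning):
            k, _ = cs.elbow_select_k(np.full(50, 5.0), range(2, 13))
        assert k == 2

    def test_out_of_range_k_rejected(self):
        with pytest.raises(DegenerateInputError):
            cs.elbow_select_k([1.0, 2.0], range(1, 25))


class TestPseudoLabels:
    def _codebook(self):
        return ClusterCodebook([7.9, 10.6, 12.0])

    def test_nearest_center_ascending_labels(self):
        cb = self._codebook()
        assert cb.encode([8.0]).tolist() == [1]
        assert cb.encode([11.9]).tolist() == [3]

    def test_equidistant_value_takes_lower_label(self):
        cb = self._codebook()
        midpoint = (7.9 + 10.6) / 2
        assert cb.encode([midpoint]).tolist() == [1]

    def test_decode_encode_within_half_gap(self, rng):
        cb = self._codebook()
        v = rng.uniform(7.9, 12.0, 500)
        err = np.abs(cb.decode(cb.encode(v)) - v)
        half_gap = np.diff(cb.centers).max() / 2
        assert err.max() <= half_gap + 1e-12

    def test_label_order_tracks_center_order(self, rng):
        centers = np.sort(rng.uniform(5, 15, 6))
        cb = ClusterCodebook(centers)
        labels = cb.encode(centers)
        assert labels.tolist() == [1, 2, 3, 4, 5, 6]

    def test_missing_nir_is_an_error(self):
        cloud = PointCloud(x=[0.0], y=[0.0], z=[0.0])
        with pytest.raises(DegenerateInputError):
            cs.encode_pseudo_labels(cloud, self._codebook())


class TestNormalizeAndSplit:
    def test_two_point_zscore_population_sd(self):
        cloud = PointCloud(x=[0.0, 2.0], y=[1.0, 1.0], z=[5.0, 7.0])
        out = cs.normalize_features(cloud)
        assert out.x.tolist() == [-1.0, 1.0]
        assert out.y.tolist() == [0.0, 0.0]  # zero-variance guard
        assert abs(out.z.mean()) < 1e-12

    def test_rgb_scaled_to_unit(self):
        cloud = PointCloud(x=[0.0, 1.0], y=[0.0, 1.0], z=[0.0, 1.0],
                           r=[255.0, 0.0], g=[128.0, 0.0], b=[0.0, 255.0])
        out = cs.normalize_features(cloud, rgb_max=255.0)
        assert out.r.tolist() == [1.0, 0.0]

    def test_split_sizes_and_conservation(self, rng):
        cloud = PointCloud(x=rng.normal(size=1000), y=rng.normal(size=1000),
                           z=rng.normal(size=1000))
        tr, te, va = cs.split_dataset(cloud, (0.8, 0.1, 0.1), seed=4)
        assert (len(tr), len(te), len(va)) == (800, 100, 100)
        allx = np.concatenate([tr.x, te.x, va.x])
        assert np.array_equal(np.sort(allx), np.sort(cloud.x))

    def test_split_deterministic(self, rng):
        cloud = PointCloud(x=rng.normal(size=50), y=rng.normal(size=50),
                           z=rng.normal(size=50))
        a = cs.split_dataset(cloud, seed=9)[0]
        b = cs.split_dataset(cloud, seed=9)[0]
        assert np.array_equal(a.x, b.x)

    def test_bad_ratios_rejected(self, rng):
        cloud = PointCloud(x=rng.normal(size=10), y=rng.normal(size=10),
                           z=rng.normal(size=10))
        with pytest.raises(DegenerateInputError):
            cs.split_dataset(cloud, (0.5, 0.2, 0.2))
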