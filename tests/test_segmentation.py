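import numpy as np
import pytest

import canospec as cs
from canospec.errors import DegenerateInputError
from canospec.segmentation import make_blocks


def _separable(rng, n, margin=1.5):
    """Spatially mixed two-class set: xy carry no class signal; the color
    channels are linearly separable with a margin."""
    y = rng.integers(1, 3, n)
    X = np.column_stack([
        rng.uniform(0, 20, n), rng.uniform(0, 20, n), rng.normal(0, 1, n),
        rng.normal(0, 0.5, n), rng.normal(0, 0.5, n), rng.normal(0, 0.5, n),
    ])
    X[:, 3] += np.where(y == 1, -margin, margin)
    return X, y


class TestMakeBlocks:
    def test_whole_cloud_fits_one_block(self, rng):
        xy = rng.uniform(0, 10, (500, 2))
        blocks = make_blocks(xy, n_points=500, seed=0)
        assert len(blocks) == 1
        assert sorted(blocks[0].tolist()) == list(range(500))

    def test_small_cloud_padded_by_resampling(self, rng):
        xy = rng.uniform(0, 10, (100, 2))
        blocks = make_blocks(xy, n_points=256, seed=0)
        assert len(blocks) == 1 and len(blocks[0]) == 256
        assert set(blocks[0]) == set(range(100))

    def test_every_point_covered_at_least_once(self, rng):
        xy = rng.uniform(0, 20, (3000, 2))
        blocks = make_blocks(xy, n_points=512, seed=1)
        covered = np.unique(np.concatenate(blocks))
        assert covered.size == 3000
        assert all(len(b) == 512 for b in blocks)

    def test_fixed_seed_identical_blocks(self, rng):
        xy = rng.uniform(0, 20, (2000, 2))
        a = make_blocks(xy, 512, seed=3)
        b = make_blocks(xy, 512, seed=3)
        assert all(np.array_equal(p, q) for p, q in zip(a, b))

    def test_empty_cloud_rejected(self):
        with pytest.raises(DegenerateInputError):
            make_blocks(np.empty((0, 2)), 64)


class TestTraining:
    def test_separable_two_class_validation_accuracy(self, rng):
        X, y = _separable(rng, 4096)
        Xv, yv = _separable(rng, 1024)
        m = cs.PointNetSegmenter(epochs=30, n_points=512, random_state=0)
        m.fit(X, y, validation=(Xv, yv))
        assert m.history_["val_oacc"][-1] >= 0.95

    def test_loss_decreases_over_first_epochs(self, rng):
        X, y = _separable(rng, 2048)
        m = cs.PointNetSegmenter(epochs=5, n_points=256, random_state=0).fit(X, y)
        losses = m.history_["train_loss"]
        assert losses[4] < losses[0]

    def test_label_permutation_permutes_predictions(self, rng):
        X, y = _separable(rng, 2048)
        m1 = cs.PointNetSegmenter(epochs=30, n_points=256, random_state=0).fit(X, y)
        perm = {1: 2, 2: 1}
        y2 = np.vectorize(perm.get)(y)
        m2 = cs.PointNetSegmenter(epochs=30, n_points=256, random_state=0).fit(X, y2)
        p1 = m1.predict(X)
        p2 = m2.predict(X)
        # both runs approximate the same decision function, so predictions
        # agree up to residual training noise
        agreement = np.mean(np.vectorize(perm.get)(p1) == p2)
        assert agreement >= 0.9

    def test_single_class_training_warns(self, rng):
        X = rng.normal(size=(256, 6))
        with pytest.warns(UserWarning):
            cs.PointNetSegmenter(epochs=1, n_points=64).fit(X, np.ones(256))

    def test_invalid_hyperparameters_rejected(self, rng):
        X, y = _separable(rng, 64)
        with pytest.raises(DegenerateInputError):
            cs.PointNetSegmenter(lr=0.0, epochs=1).fit(X, y)


class TestPredict:
    def test_output_length_and_determinism(self, rng):
        X, y = _separable(rng, 1024)
        m = cs.PointNetSegmenter(epochs=10, n_points=256, random_state=0).fit(X, y)
        p1 = m.predict(X)
        p2 = m.predict(X)
        assert p1.shape == (1024,)
        assert np.array_equal(p1, p2)
        assert set(np.unique(p1)) <= {1, 2}

    def test_point_order_invariance_within_a_block(self, rng):
        X, y = _separable(rng, 256)
        m = cs.PointNetSegmenter(epochs=10, n_points=256, random_state=0).fit(X, y)
        Xs = (X - m.feat_mean_) / m.feat_scale_
        logits = m.predict_block_logits(Xs[None, ...])[0]
        perm = rng.permutation(256)
        logits_perm = m.predict_block_logits(Xs[perm][None, ...])[0]
        np.testing.assert_allclose(logits_perm, logits[perm], atol=1e-9)

    def test_schema_mismatch_rejected(self, rng):
        X, y = _separable(rng, 256)
        m = cs.PointNetSegmenter(epochs=1, n_points=64, random_state=0).fit(X, y)
        with pytest.raises(DegenerateInputError):
            m.predict(X[:, :4])

    def test_save_load_round_trip(self, rng, tmp_path):
        X, y = _separable(rng, 512)
        m = cs.PointNetSegmenter(epochs=10, n_points=128, random_state=0).fit(X, y)
        m.save(tmp_path / "model.npz")
        m2 = cs.PointNetSegmenter.load(tmp_path / "model.npz")
        assert np.array_equal(m.predict(X), m2.predict(X))

    def test_get_set_params_round_trip(self):
        m = cs.PointNetSegmenter(lr=0.01, epochs=7)
        params = m.get_params()
        assert params["lr"] == 0.01
        m.set_params(epochs=9)
        assert m.epochs == 9


class TestMetrics:
    def test_hand_counted_example(self):
        cm = np.array([[2, 1], [0, 3]])
        assert cs.oacc(cm) == pytest.approx(5 / 6)
        assert cs.miou(cm) == pytest.approx((2 / 3 + 3 / 4) / 2)

    def test_perfect_prediction(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        cm = cs.confusion(y, y, labels=[1, 2, 3])
        assert np.array_equal(cm, np.diag([2, 2, 2]))
        assert cs.oacc(cm) == 1.0 and cs.miou(cm) == 1.0

    def test_counts_conserve_and_match_pairwise_oracle(self):
        for seed in range(50):
            r = np.random.default_rng(seed)
            t = r.integers(1, 4, 200)
            p = r.integers(1, 4, 200)
            cm = cs.confusion(t, p, labels=[1, 2, 3])
            assert cm.sum() == 200
            # exhaustive pair-count oracle
            for i, a in enumerate([1, 2, 3]):
                for j, b in enumerate([1, 2, 3]):
                    assert cm[i, j] == np.sum((t == a) & (p == b))
            assert cs.oacc(cm) == pytest.approx(np.mean(t == p))
            ious = []
            for i, a in enumerate([1, 2, 3]):
                inter = np.sum((t == a) & (p == a))
                union = np.sum((t == a) | (p == a))
                if union:
                    ious.append(inter / union)
            assert cs.miou(cm) == pytest.approx(np.mean(ious))

    def test_oacc_invariant_to_simultaneous_permutation(self):
        cm = np.array([[5, 2, 1], [0, 7, 1], [2, 2, 9]])
        perm = [2, 0, 1]
        assert cs.oacc(cm[np.ix_(perm, perm)]) == pytest.approx(cs.oacc(cm))

    def test_miou_bounded_and_empty_class_skipped(self):
        cm = np.array([[3, 0, 0], [0, 2, 0], [0, 0, 0]])
        with pytest.warns(UserWarning):
            v = cs.miou(cm)
        assert 0.0 <= v <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DegenerateInputError):
            cs.confusion([1, 2], [1], labels=[1, 2])
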