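"""The boosted-tree / leaf-one-hot / logistic-regression cascade."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from sklearn.base import clone

from lncdlink import (BoostedEnsemble, GBDTLRClassifier, RegressionTree,
                      boost, encode_leaves, fit_tree, init_score, leaf_values,
                      logloss, lr_fit, predict_pair, residuals, roc_auc)


class TestInitScore:
    def test_balanced_labels_give_zero(self):
        assert init_score([0, 1, 0, 1]) == 0.0

    def test_three_to_one_half_log_three(self):
        assert init_score([1, 1, 1, 0]) == pytest.approx(0.5 * np.log(3))
        assert init_score([1, 1, 1, 0]) == pytest.approx(0.5493, abs=1e-4)

    def test_antisymmetric(self):
        assert init_score([1, 0, 0, 0]) == pytest.approx(-init_score([1, 1, 1, 0]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            init_score([1, 1, 1])


class TestResiduals:
    def test_worked_values_at_zero_score(self):
        r = residuals(np.array([1.0, -1.0]), np.zeros(2))
        np.testing.assert_allclose(r, [0.5, -0.5])

    def test_fitted_point_residual_vanishes(self):
        r = residuals(np.array([1.0]), np.array([50.0]))
        assert r[0] == pytest.approx(0.0, abs=1e-20)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            residuals(np.ones(3), np.zeros(2))


class TestFitTree:
    def test_constant_residuals_single_leaf(self, rng):
        X = rng.random((20, 3))
        tree = fit_tree(X, np.full(20, 0.3), max_depth=3, min_leaf=2)
        assert tree.n_leaves == 1

    def test_perfect_split_found_at_root(self):
        X = np.array([[0.0, 9.0], [0.2, 1.0], [0.8, 5.0], [1.0, 3.0]])
        r = np.array([-1.0, -1.0, 1.0, 1.0])
        tree = fit_tree(X, r, max_depth=2, min_leaf=1)
        assert tree.feature[0] == 0
        assert tree.threshold[0] == pytest.approx(0.5)

    def test_depth_one_is_a_stump(self, rng):
        X = rng.random((30, 4))
        r = rng.normal(size=30)
        tree = fit_tree(X, r, max_depth=1, min_leaf=1)
        assert tree.n_leaves <= 2

    def test_matches_exhaustive_split_oracle(self, rng):
        """Root split equals the best (feature, boundary) by brute force."""
        for trial in range(10):
            X = rng.random((15, 3))
            r = rng.normal(size=15)
            tree = fit_tree(X, r, max_depth=1, min_leaf=2)
            if tree.n_leaves == 1:
                continue
            best_gain, best = -np.inf, None
            n = len(r)
            for f in range(3):
                vs = np.unique(X[:, f])
                for lo, hi in zip(vs, vs[1:]):
                    thr = 0.5 * (lo + hi)
                    m = X[:, f] <= thr
                    if m.sum() < 2 or (~m).sum() < 2:
                        continue
                    gain = (r[m].sum() ** 2 / m.sum()
                            + r[~m].sum() ** 2 / (~m).sum() - r.sum() ** 2 / n)
                    if gain > best_gain + 1e-12:
                        best_gain, best = gain, (f, thr)
            assert (tree.feature[0], tree.threshold[0]) == pytest.approx(best)

    def test_min_leaf_respected(self, rng):
        X = rng.random((40, 2))
        r = rng.normal(size=40)
        tree = fit_tree(X, r, max_depth=4, min_leaf=7)
        counts = np.bincount(tree.apply(X), minlength=tree.n_leaves)
        assert counts.min() >= 7


class TestLeafValues:
    def test_zero_residuals_give_zero(self):
        c = leaf_values(np.zeros(4, dtype=int), 1, np.ones(4),
                        np.full(4, 1e3))
        assert c[0] == pytest.approx(0.0, abs=1e-6)

    def test_single_positive_at_zero_score(self):
        c = leaf_values(np.zeros(1, dtype=int), 1, np.array([1.0]), np.zeros(1))
        assert c[0] == pytest.approx(0.5 / (0.5 * 1.5))

    def test_symmetric_leaf_cancels(self):
        c = leaf_values(np.zeros(2, dtype=int), 1, np.array([1.0, -1.0]),
                        np.zeros(2))
        assert c[0] == pytest.approx(0.0)

    def test_newton_step_tracks_argmin_where_the_step_is_small(self, rng):
        """In the regime the one-step approximation is built for (optimal
        leaf step below ~0.15, residuals not saturated), the closed form
        lands within 0.15 of exact numeric minimisation of the leaf loss."""
        checked = 0
        while checked < 100:
            n = int(rng.integers(2, 21))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            if np.unique(y).size < 2:
                continue
            theta = rng.normal(0.0, 1.0, n)

            def f(c):
                return np.logaddexp(0.0, -y * (theta + c)).sum()

            res = minimize_scalar(f, bounds=(-6, 6), method="bounded",
                                  options={"xatol": 1e-10})
            if abs(res.x) > 0.15:
                continue
            r = residuals(y, theta)
            den = (np.abs(r) * (2 - np.abs(r))).sum()
            c_newton = r.sum() / den
            assert abs(c_newton - res.x) <= 0.15
            checked += 1


def two_blob_data(rng, n=120, gap=3.0):
    X = np.vstack([rng.normal(0, 0.5, (n // 2, 2)),
                   rng.normal(gap, 0.5, (n // 2, 2))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestBoost:
    def test_training_loss_monotone_non_increasing(self, rng):
        X, y = two_blob_data(rng, gap=1.5)
        ens = boost(X, y, n_estimators=40, learning_rate=0.1, max_depth=2)
        for prev, nxt in zip(ens.train_losses, ens.train_losses[1:]):
            assert nxt <= prev + 1e-12

    def test_separable_toy_fits_perfectly(self, rng):
        X, y = two_blob_data(rng, gap=4.0)
        ens = boost(X, y, n_estimators=50, learning_rate=0.1, max_depth=2)
        scores = ens.decision_function(X)
        assert ((scores > 0).astype(int) == y).all()
        assert roc_auc(scores, y)[0] == 1.0

    def test_decision_is_init_plus_shrunk_leaf_sums(self, rng):
        X, y = two_blob_data(rng)
        ens = boost(X, y, n_estimators=10, learning_rate=0.1, max_depth=2)
        replay = np.full(len(y), ens.init)
        for tree in ens.trees:
            replay += ens.learning_rate * tree.values[tree.apply(X)]
        np.testing.assert_array_equal(replay, ens.decision_function(X))

    def test_empty_ensemble_scores_init_everywhere(self):
        ens = BoostedEnsemble(init=0.25, learning_rate=0.1, trees=[])
        np.testing.assert_array_equal(ens.decision_function(np.zeros((3, 2))),
                                      np.full(3, 0.25))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            boost(rng.random((10, 2)), np.ones(10, dtype=int), n_estimators=2)


def manual_two_tree_ensemble():
    """Left tree with 3 leaves (split f0 then f1), right tree with 2 (split f1)."""
    t1 = RegressionTree(
        feature=np.array([0, -1, 1, -1, -1]),
        threshold=np.array([0.5, 0.0, 0.5, 0.0, 0.0]),
        left=np.array([1, -1, 3, -1, -1]),
        right=np.array([2, -1, 4, -1, -1]),
        leaf_of_node=np.array([-1, 0, -1, 1, 2]),
        values=np.zeros(3),
    )
    t2 = RegressionTree(
        feature=np.array([1, -1, -1]),
        threshold=np.array([0.5, 0.0, 0.0]),
        left=np.array([1, -1, -1]),
        right=np.array([2, -1, -1]),
        leaf_of_node=np.array([-1, 0, 1]),
        values=np.zeros(2),
    )
    return BoostedEnsemble(init=0.0, learning_rate=0.1, trees=[t1, t2])


class TestEncodeLeaves:
    def test_worked_five_bit_code(self):
        """First leaf of the 3-leaf tree + second leaf of the 2-leaf tree."""
        ens = manual_two_tree_ensemble()
        x = np.array([[0.0, 1.0]])  # tree1 -> leaf 0; tree2 -> leaf 1
        np.testing.assert_array_equal(encode_leaves(ens, x)[0],
                                      [1, 0, 0, 0, 1])

    def test_exactly_one_bit_per_tree(self, rng):
        X, y = two_blob_data(rng)
        ens = boost(X, y, n_estimators=7, learning_rate=0.1, max_depth=3)
        codes = encode_leaves(ens, X)
        np.testing.assert_array_equal(codes.sum(axis=1), np.full(len(y), 7))

    def test_same_leaves_same_codes(self):
        ens = manual_two_tree_ensemble()
        a = encode_leaves(ens, np.array([[0.1, 0.9]]))
        b = encode_leaves(ens, np.array([[0.3, 0.7]]))
        np.testing.assert_array_equal(a, b)


class TestLogisticHead:
    def test_zero_weight_head_predicts_half(self):
        ens = manual_two_tree_ensemble()
        head = lr_fit(np.array([[1, 0, 0, 0, 1], [0, 1, 0, 1, 0]]),
                      [1, 0], max_steps=0)
        assert predict_pair(ens, head, np.array([0.0, 1.0])) == 0.5

    def test_initial_loss_is_log_two(self, rng):
        codes = rng.integers(0, 2, (30, 6)).astype(float)
        y = rng.integers(0, 2, 30)
        head = lr_fit(codes, y, max_steps=1)
        assert head.initial_loss == pytest.approx(np.log(2))

    def test_separable_codes_reach_full_accuracy(self):
        codes = np.array([[1, 0]] * 10 + [[0, 1]] * 10, dtype=float)
        y = np.array([1] * 10 + [0] * 10)
        head = lr_fit(codes, y, max_steps=2000)
        p = head.predict_proba(codes)
        assert (((p >= 0.5).astype(int)) == y).all()

    def test_trained_loss_not_above_initial(self, rng):
        codes = rng.integers(0, 2, (50, 8)).astype(float)
        y = (codes[:, 0] + rng.random(50) * 0.5 > 0.7).astype(int)
        head = lr_fit(codes, y)
        assert head.final_loss <= head.initial_loss + 1e-12

    def test_non_binary_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            lr_fit(rng.random((4, 2)), [0, 1, 2, 1])

    def test_probability_and_complement_sum_to_one(self, rng):
        codes = rng.integers(0, 2, (20, 5)).astype(float)
        y = rng.integers(0, 2, 20)
        y[0], y[1] = 0, 1
        head = lr_fit(codes, y, max_steps=50)
        p = head.predict_proba(codes)
        np.testing.assert_allclose(p + (1 - p), 1.0)

    def test_positive_weight_bit_raises_probability(self):
        head_theta = np.array([1.5, -0.5, 0.0])
        from lncdlink.gbdt_lr import LogisticHead
        head = LogisticHead(head_theta, 0.0, 0, 0.0, 0.0, 0.0)
        lo = head.predict_proba(np.array([[0.0, 1.0]]))[0]
        hi = head.predict_proba(np.array([[1.0, 1.0]]))[0]
        assert hi > lo


class TestCascadeEstimator:
    def test_fit_predict_and_determinism(self, rng):
        X, y = two_blob_data(rng)
        clf1 = GBDTLRClassifier(n_estimators=20).fit(X, y)
        clf2 = GBDTLRClassifier(n_estimators=20).fit(X, y)
        p1 = clf1.predict_proba(X)
        p2 = clf2.predict_proba(X)
        np.testing.assert_array_equal(p1, p2)
        assert clf1.predict(X).shape == y.shape

    def test_sklearn_clone_compatible(self):
        clf = GBDTLRClassifier(n_estimators=5, max_depth=2)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()

    def test_json_round_trip_reproduces_predictions_bit_exactly(self, rng):
        X, y = two_blob_data(rng, n=80)
        clf = GBDTLRClassifier(n_estimators=15).fit(X, y)
        restored = GBDTLRClassifier.from_json(clf.to_json())
        Xq = rng.random((40, 2)) * 4
        np.testing.assert_array_equal(clf.predict_proba(Xq),
                                      restored.predict_proba(Xq))

    def test_rejects_multiclass(self, rng):
        X = rng.random((9, 2))
        with pytest.raises(ValueError):
            GBDTLRClassifier(n_estimators=2).fit(X, [0, 1, 2] * 3)
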