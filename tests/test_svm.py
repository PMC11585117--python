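import numpy as np
import pytest
from scipy.optimize import minimize

import mokl
from mokl.svm import (GridSearchResult, MKLClassifier, grid_search, svm_concat,
                      train_svm)
from mokl.kernels import gaussian_kernel, linear_kernel


def qp_dual_oracle(K, y, C):
    """Solve the binary SVM dual with a generic QP solver (SLSQP)."""
    n = len(y)

    def neg_dual(a):
        ay = a * y
        return -(a.sum() - 0.5 * ay @ K @ ay)

    cons = [{"type": "eq", "fun": lambda a: a @ y}]
    res = minimize(neg_dual, np.full(n, C / 2), method="SLSQP",
                   bounds=[(0, C)] * n, constraints=cons,
                   options={"maxiter": 500, "ftol": 1e-12})
    assert res.success
    a = res.x
    ay = a * y
    sv = (a > 1e-6) & (a < C - 1e-6)
    b = np.mean([y[i] - ay @ K[:, i] for i in np.nonzero(sv)[0]])
    return ay, b


class TestTrainSvm:
    def test_separable_training_accuracy(self):
        X = np.array([[0.0, 0], [0.1, 0], [5.0, 5], [5.1, 5]])
        y = np.array([0, 0, 1, 1])
        K = linear_kernel(X)
        model = train_svm(K, y, cost=1.0)
        assert np.all(model.svc.predict(K.values) == y)

    def test_label_flip_negates_scores(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.where(rng.random(20) > 0.5, 1, -1)
        y[:2] = [1, -1]
        K = gaussian_kernel(X, 0.5)
        s1 = train_svm(K, y, 1.0).svc.decision_function(K.values)
        s2 = train_svm(K, -y, 1.0).svc.decision_function(K.values)
        # agreement is limited by the solver's own stopping tolerance (1e-3)
        np.testing.assert_allclose(s1, -s2, atol=5e-3)

    def test_decision_sign_matches_qp_oracle(self, rng):
        # two separable blobs
        X = np.vstack([rng.normal(-2, 1, size=(10, 2)),
                       rng.normal(2, 1, size=(10, 2))])
        y = np.array([-1.0] * 10 + [1.0] * 10)
        K = linear_kernel(X)
        model = train_svm(K, y, cost=1.0)
        scores = model.svc.decision_function(K.values)
        ay, b = qp_dual_oracle(K.values, y, 1.0)
        oracle_scores = K.values @ ay + b
        np.testing.assert_array_equal(np.sign(scores), np.sign(oracle_scores))

    def test_dual_constraint_satisfied(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.where(X[:, 0] > 0, 1, -1)
        model = train_svm(gaussian_kernel(X, 0.3), y, cost=2.0)
        ay = np.zeros(30)
        ay[model.support] = model.dual_coef[0]
        assert abs(ay.sum()) < 1e-6           # sum alpha_i y_i = 0
        assert np.all(np.abs(ay) <= 2.0 + 1e-8)

    def test_single_class_rejected(self):
        K = linear_kernel(np.eye(3))
        with pytest.raises(ValueError, match="single class"):
            train_svm(K, np.zeros(3), 1.0)

    def test_non_psd_rejected(self):
        V = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="PSD"):
            train_svm(V, np.array([0, 1]), 1.0)


class TestPredictPath:
    def test_predict_training_set_separable(self):
        rng = np.random.default_rng(7)
        blocks = [np.vstack([rng.normal(-3, 0.5, (10, 4)),
                             rng.normal(3, 0.5, (10, 4))]) for _ in range(2)]
        y = np.array([0] * 10 + [1] * 10)
        clf = MKLClassifier("naive", sigma=0.1, cost=10.0).fit(blocks, y)
        np.testing.assert_array_equal(clf.predict(blocks), y)

    def test_duplicate_test_row_identical_predictions(self, scenario_a):
        blocks, labels, _ = scenario_a
        y = labels.encoded()
        clf = MKLClassifier("naive", sigma=1e-2).fit(blocks, y)
        test = [np.vstack([b.values[3], b.values[3]]) for b in blocks]
        pred, scores = mokl.predict(clf, test)
        assert pred[0] == pred[1]
        assert scores[0] == pytest.approx(scores[1], abs=1e-12)

    def test_hand_computed_dual_expansion(self):
        # 1-D separable pair x=0 (class -1), x=2 (class +1), linear kernel:
        # the maximum-margin solution is f(x) = x - 1 with alpha = 0.5.
        X = np.array([[0.0], [2.0]])
        y = np.array([-1, 1])
        clf = MKLClassifier("naive", kernel="linear", cost=1.0,
                            scale=False).fit([X], y)
        score = clf.decision_function([np.array([[1.5]])])
        assert score[0] == pytest.approx(0.5, abs=1e-6)
        assert clf.decision_function([np.array([[1.0]])])[0] == \
            pytest.approx(0.0, abs=1e-6)


class TestSvmConcat:
    def test_single_block_equals_plain_fit(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.where(X[:, 0] > 0, 1, 0)
        c1 = svm_concat([X], y, cost=1.0, sigma=0.2)
        c2 = MKLClassifier("naive", sigma=0.2, cost=1.0).fit([X], y)
        np.testing.assert_allclose(c1.decision_function([X]),
                                   c2.decision_function([X]), atol=1e-10)

    def test_block_order_invariance(self, rng):
        blocks = [rng.normal(size=(15, 3)) for _ in range(3)]
        y = np.where(rng.random(15) > 0.5, 1, 0)
        y[:2] = [0, 1]
        c1 = svm_concat(blocks, y, sigma=0.1)
        c2 = svm_concat(blocks[::-1], y, sigma=0.1)
        np.testing.assert_allclose(c1.decision_function(blocks),
                                   c2.decision_function(blocks[::-1]),
                                   atol=1e-10)

    def test_kernel_equals_gaussian_on_concatenation(self, rng):
        blocks = [rng.normal(size=(10, 3)) for _ in range(3)]
        y = np.where(rng.random(10) > 0.5, 1, 0)
        y[:2] = [0, 1]
        clf = svm_concat(blocks, y, sigma=0.2)
        Xcat = np.hstack([mokl.standardize(b) for b in blocks])
        expected = gaussian_kernel(Xcat, 0.2).values
        got = clf._cross(blocks)   # self cross-kernel = training kernel
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestNaiveEquivalence:
    def test_fuse_then_train_equals_average_kernel(self, scenario_a):
        blocks, labels, _ = scenario_a
        y = labels.encoded()
        clf = MKLClassifier("naive", sigma=1e-2, cost=1.0).fit(blocks, y)
        Ks = [gaussian_kernel(mokl.standardize(b.values), 1e-2).values
              for b in blocks]
        avg = sum(Ks) / 3
        model = train_svm(avg, y, cost=1.0)
        np.testing.assert_allclose(
            clf.model_.svc.decision_function(avg),
            model.svc.decision_function(avg), atol=1e-8)


class TestGridSearch:
    def test_single_cell_selected(self, scenario_a):
        blocks, labels, _ = scenario_a
        y = labels.encoded()
        gs = grid_search([b.values[:60] for b in blocks], y[:60], "naive",
                        c_grid=[5], sigma_grid=[1e-3], folds=3, seed=0)
        assert gs.best_c == 5 and gs.best_sigma == 1e-3

    def test_duplicated_grid_same_selection(self, scenario_a):
        blocks, labels, _ = scenario_a
        y = labels.encoded()
        sub = [b.values[:80] for b in blocks]
        g1 = grid_search(sub, y[:80], "naive", [1, 10], [1e-3, 1e-2],
                         folds=3, seed=1)
        g2 = grid_search(sub, y[:80], "naive", [1, 10, 10, 1], [1e-2, 1e-3, 1e-3],
                         folds=3, seed=1)
        assert (g1.best_c, g1.best_sigma) == (g2.best_c, g2.best_sigma)
        np.testing.assert_allclose(g1.cv_accuracy, g2.cv_accuracy)

    def test_selection_matches_exhaustive_refit_oracle(self, scenario_a):
        # re-run the identical fold/fit protocol by hand and check argmax +
        # deterministic tie-breaking (smallest C then smallest sigma)
        from sklearn.model_selection import StratifiedKFold
        blocks, labels, _ = scenario_a
        y = labels.encoded()[:90]
        sub = [b.values[:90] for b in blocks]
        c_grid, s_grid = [1.0, 10.0], [1e-3, 1e-2]
        gs = grid_search(sub, y, "naive", c_grid, s_grid, folds=3, seed=0)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        splits = list(skf.split(np.zeros(len(y)), y))
        acc = np.zeros((2, 2))
        for i, C in enumerate(c_grid):
            for j, s in enumerate(s_grid):
                scores = []
                for tr, va in splits:
                    clf = MKLClassifier("naive", sigma=s, cost=C).fit(
                        [X[tr] for X in sub], y[tr])
                    scores.append(np.mean(clf.predict([X[va] for X in sub])
                                          == y[va]))
                acc[i, j] = np.mean(scores)
        np.testing.assert_allclose(gs.cv_accuracy, acc, atol=1e-12)
        best = np.argwhere(acc == acc.max())
        bi, bj = min(map(tuple, best))
        assert (gs.best_c, gs.best_sigma) == (c_grid[bi], s_grid[bj])

    def test_determinism(self, scenario_a):
        blocks, labels, _ = scenario_a
        y = labels.encoded()[:80]
        sub = [b.values[:80] for b in blocks]
        g1 = grid_search(sub, y, "naive", [1, 5], [1e-3], folds=3, seed=3)
        g2 = grid_search(sub, y, "naive", [1, 5], [1e-3], folds=3, seed=3)
        np.testing.assert_array_equal(g1.cv_accuracy, g2.cv_accuracy)
        assert g1.fold_kernel_hashes == g2.fold_kernel_hashes

    def test_no_leakage_from_validation_folds(self, scenario_a):
        # corrupting validation-fold rows with a label-correlated feature
        # must leave every fold-training kernel bit-identical
        from sklearn.model_selection import StratifiedKFold
        blocks, labels, _ = scenario_a
        y = labels.encoded()[:90]
        sub = [b.values[:90].copy() for b in blocks]
        gs_clean = grid_search(sub, y, "naive", [1], [1e-3], folds=3, seed=0)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        _, probe_val = list(skf.split(np.zeros(len(y)), y))[0]
        poisoned = [X.copy() for X in sub]
        for X in poisoned:
            X[probe_val, 0] = 1000.0 * (2 * y[probe_val] - 1)
        gs_poisoned = grid_search(poisoned, y, "naive", [1], [1e-3],
                                  folds=3, seed=0)
        assert gs_clean.fold_kernel_hashes[(0, 1e-3)] == \
            gs_poisoned.fold_kernel_hashes[(0, 1e-3)]

    def test_empty_grid_rejected(self, scenario_a):
        blocks, labels, _ = scenario_a
        with pytest.raises(ValueError, match="empty"):
            grid_search([b.values for b in blocks], labels.encoded(),
                        "naive", [], [1e-3])
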