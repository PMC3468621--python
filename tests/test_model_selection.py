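import numpy as np
import pytest

from illposed.model_selection import (
    ConfusionCounts,
    accuracy,
    confusion_counts,
    draw_training_ids,
    evaluate_on_test,
    fit_predict_method,
    kfold_grid_search,
    make_split,
)


def _labels(n_cn, n_ad):
    return np.r_[np.zeros(n_cn, int), np.ones(n_ad, int)]


def _separated(rng, n=60, d=4, sep=3.0):
    half = n // 2
    X = rng.normal(size=(n, d))
    X[half:] += sep / np.sqrt(d)
    return X, _labels(half, half)


class TestMakeSplit:
    def test_bookkeeping(self):
        y = _labels(100, 100)
        plan = make_split(y, n_test_per_class=25, seed=3)
        assert len(plan.test_ids) == 50
        assert len(plan.train_pool_ids) == 150
        assert not set(plan.test_ids) & set(plan.train_pool_ids)
        assert (y[list(plan.test_ids)] == 1).sum() == 25

    def test_balanced_training_draw(self):
        y = _labels(100, 100)
        plan = make_split(y, n_test_per_class=25, seed=3)
        train = draw_training_ids(plan, y, sample_size=40, iteration_seed=9)
        assert len(train) == 40
        assert (y[train] == 1).sum() == 20

    def test_same_seed_same_split(self):
        y = _labels(60, 60)
        a = make_split(y, 10, seed=5)
        b = make_split(y, 10, seed=5)
        assert a.test_ids == b.test_ids
        t1 = draw_training_ids(a, y, 20, 77)
        t2 = draw_training_ids(b, y, 20, 77)
        np.testing.assert_array_equal(t1, t2)

    def test_no_training_draw_touches_test_over_100_iterations(self):
        y = _labels(80, 80)
        plan = make_split(y, 20, seed=1)
        test = set(plan.test_ids)
        for it in range(100):
            train = draw_training_ids(plan, y, 30, it)
            assert not test & set(map(int, train))

    def test_insufficient_subjects(self):
        with pytest.raises(ValueError):
            make_split(_labels(10, 10), n_test_per_class=10, seed=0)

    def test_odd_sample_size_rejected(self):
        y = _labels(30, 30)
        plan = make_split(y, 5, seed=0)
        with pytest.raises(ValueError, match="even"):
            draw_training_ids(plan, y, 15, 0)


class TestAccuracy:
    def test_perfect(self):
        assert accuracy(ConfusionCounts(50, 50, 0, 0)) == 1.0

    def test_arithmetic(self):
        assert accuracy(ConfusionCounts(TP=40, TN=45, FP=5, FN=10)) == 0.85

    def test_swap_symmetry(self):
        c = ConfusionCounts(TP=12, TN=30, FP=7, FN=1)
        swapped = ConfusionCounts(TP=c.TN, TN=c.TP, FP=c.FN, FN=c.FP)
        assert accuracy(c) == accuracy(swapped)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_counts_from_labels(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([1, 0, 0, 1, 1])
        c = confusion_counts(y, p)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 1, 1, 1)
        assert c.total == 5


class TestKfoldGridSearch:
    def test_single_value_grid(self, rng):
        X, y = _separated(rng)
        cv = kfold_grid_search(X, y, "rlr", grid=(0.1,), k=5, seed=0)
        assert cv.selected_value == 0.1
        assert cv.fold_accuracies.shape == (1, 5)

    def test_null_model_loses_on_separated_problem(self, rng):
        X, y = _separated(rng, n=80, sep=4.0)
        cv = kfold_grid_search(X, y, "rlr", grid=(1e6, 0.01), k=5, seed=0)
        assert cv.selected_value == 0.01
        assert cv.mean_accuracy_at_selected > 0.9

    def test_tie_prefers_more_regularization_rlr(self, rng):
        # two huge lambdas both give the null model -> identical folds
        X, y = _separated(rng, n=40)
        cv = kfold_grid_search(X, y, "rlr", grid=(1e5, 1e6), k=4, seed=0)
        assert cv.selected_value == 1e6

    def test_tie_prefers_smaller_C_svm(self, rng):
        X, y = _separated(rng, n=40, sep=5.0)
        cv = kfold_grid_search(X, y, "svm", grid=(1.0, 2.0), k=4, seed=0)
        # strongly separated: both C give identical accuracy -> smaller C
        if np.allclose(cv.fold_accuracies[0], cv.fold_accuracies[1]):
            assert cv.selected_value == 1.0

    def test_selected_maximizes_mean_accuracy(self, rng):
        X, y = _separated(rng, n=60, sep=1.0)
        grid = (1e6, 1.0, 0.01)
        cv = kfold_grid_search(X, y, "rlr", grid=grid, k=5, seed=1)
        means = cv.fold_accuracies.mean(axis=1)
        assert means[list(grid).index(cv.selected_value)] == means.max()

    def test_needs_enough_samples(self, rng):
        X, y = _separated(rng, n=8)
        with pytest.raises(ValueError):
            kfold_grid_search(X, y, "rlr", grid=(0.1,), k=10, seed=0)

    def test_stratified_folds_have_both_classes(self, rng):
        from illposed.model_selection import _stratified_folds

        y = _labels(12, 8)
        folds = _stratified_folds(y, 4, seed=0)
        assert sorted(np.concatenate(folds).tolist()) == list(range(20))
        for held in folds:
            assert set(y[held]) == {0, 1}


class TestEvaluateOnTest:
    def test_perfect_model(self):
        y = _labels(50, 50)
        counts, acc = evaluate_on_test(y, y)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (50, 50, 0, 0)
        assert acc == 1.0

    def test_constant_class_one_model(self):
        y = _labels(50, 50)
        counts, acc = evaluate_on_test(y, np.ones_like(y))
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (50, 0, 50, 0)
        assert acc == 0.5

    def test_accuracy_equals_mean_correctness(self, rng):
        y = rng.integers(0, 2, 30)
        p = rng.integers(0, 2, 30)
        _, acc = evaluate_on_test(y, p)
        assert acc == pytest.approx(np.mean(y == p))

    def test_leakage_guard(self):
        y = _labels(3, 3)
        with pytest.raises(ValueError, match="leakage"):
            evaluate_on_test(y, y, train_ids=[1, 2], test_ids=[2, 3])


class TestFitPredictMethod:
    @pytest.mark.parametrize("method", ["lrc", "rlr", "svm_soft", "svm_hard"])
    def test_methods_run_and_score(self, method, rng):
        # n < d with a strong effect: the interpolation regime where all
        # methods, including the threshold-0.5 LRC, classify well
        X, y = _separated(rng, n=40, d=120, sep=10.0)
        Xt, yt = _separated(rng, n=20, d=120, sep=10.0)
        out = fit_predict_method(
            method, X, y, Xt, yt,
            rlr_grid=(0.1, 0.01), svm_grid=(2.0**-8, 1.0), cv_k=5, cv_seed=0,
        )
        assert 0.0 <= out.accuracy <= 1.0
        if method == "lrc":
            # centered training columns put the pseudo-inverse decision
            # values at ~+-0.5, so the 0.5 threshold caps the LRC below
            # the other methods even on a separable problem
            assert out.accuracy > 0.6
        else:
            assert out.accuracy > 0.8  # trivially separable
        if method in ("rlr", "svm_soft"):
            assert out.selected_hyperparameter is not None
        else:
            assert out.selected_hyperparameter is None

    def test_permutation_invariance_of_accuracy(self, rng):
        # at fixed hyperparameters every method's test predictions are
        # invariant to a joint permutation of training rows and labels
        from illposed.classifiers import fit_lrc, fit_rlr, fit_svm, predict_lrc, predict_rlr, predict_svm
        from illposed.kernel_conditioning import cross_kernel, linear_kernel

        X, y = _separated(rng, n=40, d=10, sep=1.0)
        Xt, yt = _separated(rng, n=30, d=10, sep=1.0)
        perm = rng.permutation(len(y))
        Xp, yp = X[perm], y[perm]

        a = predict_lrc(fit_lrc(linear_kernel(X), y, X), Xt)[0]
        b = predict_lrc(fit_lrc(linear_kernel(Xp), yp, Xp), Xt)[0]
        np.testing.assert_array_equal(a, b)

        a = predict_rlr(fit_rlr(X, y, lam=0.1, tol=1e-9), Xt)[0]
        b = predict_rlr(fit_rlr(Xp, yp, lam=0.1, tol=1e-9), Xt)[0]
        np.testing.assert_array_equal(a, b)

        a = predict_svm(fit_svm(linear_kernel(X), y, C=0.05), cross_kernel(Xt, X))[0]
        b = predict_svm(fit_svm(linear_kernel(Xp), yp, C=0.05), cross_kernel(Xt, Xp))[0]
        np.testing.assert_array_equal(a, b)

    def test_unknown_method(self, rng):
        X, y = _separated(rng, n=20)
        with pytest.raises(ValueError, match="unknown method"):
            fit_predict_method("forest", X, y, X, y)
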