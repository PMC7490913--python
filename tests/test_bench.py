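import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hisskit.bench import (
    DEFAULT_GRIDS,
    CVResult,
    SizingModel,
    UnreachableTargetError,
    compare_classifiers_anova,
    confusion_and_accuracy,
    estimator_factory,
    fit_sizing_model,
    kfold_cv,
    learning_curve,
    predict_requirements,
    train_baseline,
)


class _Oracle:
    """Perfect classifier for a known deterministic feature->label rule."""

    def __init__(self, fn=lambda row: int(row[0] > 0)):
        self._fn = fn

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self._fn(row) for row in X])


def _toy_separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-3, 0.5, (n // 2, 2)), rng.normal(3, 0.5, (n // 2, 2))])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestConfusionAndAccuracy:
    def test_perfect_predictions(self):
        y = [0, 1, 2, 3, 4]
        cm, acc, tpr = confusion_and_accuracy(y, y)
        assert acc == 1.0
        assert np.all(cm.counts == np.eye(5, dtype=int))
        assert tpr == {k: 1.0 for k in range(5)}

    def test_four_of_five_correct(self):
        y_true = [0, 0, 1, 1, 1]
        y_pred = [0, 0, 1, 1, 0]
        cm, acc, _ = confusion_and_accuracy(y_true, y_pred, c=2)
        assert acc == pytest.approx(0.8)
        assert cm.counts.tolist() == [[2, 0], [1, 2]]

    def test_absent_class_tpr_omitted(self):
        _, _, tpr = confusion_and_accuracy([0, 1, 1], [0, 1, 0], c=5)
        assert 4 not in tpr and 2 not in tpr
        assert set(tpr) == {0, 1}

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_and_accuracy([0, 1], [0])

    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 4)),
                    min_size=1, max_size=60))
    def test_accuracy_equals_match_fraction(self, pairs):
        # independent oracle: plain element-wise comparison
        y_true = [a for a, _ in pairs]
        y_pred = [b for _, b in pairs]
        _, acc, _ = confusion_and_accuracy(y_true, y_pred)
        assert acc == pytest.approx(np.mean(np.array(y_true) == np.array(y_pred)))


class TestKFoldCV:
    def test_fold_sizes_100_by_5(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = (X[:, 0] > 0).astype(int)
        result = kfold_cv(_Oracle, X, y, k=5, rng=rng)
        assert len(result.fold_accuracies) == 5

    def test_perfect_classifier(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        y = (X[:, 0] > 0).astype(int)
        result = kfold_cv(_Oracle, X, y, k=5, rng=rng)
        assert result.mean == 1.0 and result.sd == 0.0

    def test_same_seed_reproducible(self):
        X, y = _toy_separable()
        a = kfold_cv(estimator_factory("svm_linear", seed=0), X, y, k=5,
                     rng=np.random.default_rng(4))
        b = kfold_cv(estimator_factory("svm_linear", seed=0), X, y, k=5,
                     rng=np.random.default_rng(4))
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            kfold_cv(_Oracle, np.zeros((3, 1)), np.array([0, 1, 0]), k=5)

    def test_shuffle_invariance_in_distribution(self):
        # mean CV accuracy is stable under instance shuffling when the
        # stratified split is re-seeded
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        factory = estimator_factory("ebdt", {"n_estimators": 6}, seed=0)

        def mean_over_seeds(Xv, yv):
            return np.mean([
                kfold_cv(factory, Xv, yv, k=5, rng=np.random.default_rng(s)).mean
                for s in range(20)
            ])

        perm = np.random.default_rng(9).permutation(60)
        assert abs(mean_over_seeds(X, y) - mean_over_seeds(X[perm], y[perm])) < 0.03


class TestTrainBaseline:
    def test_separable_toy_perfect(self):
        X, y = _toy_separable()
        est = train_baseline("svm_linear", X, y, rng=np.random.default_rng(0))
        assert np.mean(est.predict(X) == y) == 1.0

    def test_ann_softmax_sums_to_one(self):
        X, y = _toy_separable()
        y = y + (X[:, 1] > 3).astype(int)  # 3 classes for a softmax output
        est = train_baseline("ann", X, y, hyper_grid=[{"hidden_layer_sizes": (5,)}],
                             rng=np.random.default_rng(0), cv_folds=2)
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_baseline("svm_linear", np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_unknown_kind(self):
        X, y = _toy_separable()
        with pytest.raises(ValueError, match="svm_linear"):
            train_baseline("random_forest", X, y)

    def test_fixed_seed_reproducible(self):
        X, y = _toy_separable()
        a = train_baseline("svm_linear", X, y, rng=np.random.default_rng(11))
        b = train_baseline("svm_linear", X, y, rng=np.random.default_rng(11))
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        assert a.get_params()["svc__C"] == b.get_params()["svc__C"]

    def test_ebdt_grid_is_printed_range(self):
        assert [g["n_estimators"] for g in DEFAULT_GRIDS["ebdt"]] == \
            list(range(6, 21, 2))


class TestLearningCurve:
    def test_eleven_points_for_printed_sizes(self, noisy_cohort):
        _, X, y, _ = noisy_cohort
        points = learning_curve(
            estimator_factory("ebdt", {"n_estimators": 6}, seed=0), X, y,
            train_sizes=range(30, 81, 5), repeats=2, test_size=20,
            rng=np.random.default_rng(0))
        assert len(points) == 11
        assert [p.train_size for p in points] == list(range(30, 81, 5))

    def test_single_repeat_reproducible(self, noisy_cohort):
        _, X, y, _ = noisy_cohort
        kwargs = dict(train_sizes=[40], repeats=1, test_size=20)
        a = learning_curve(estimator_factory("ebdt", {"n_estimators": 6}, seed=0),
                           X, y, rng=np.random.default_rng(5), **kwargs)
        b = learning_curve(estimator_factory("ebdt", {"n_estimators": 6}, seed=0),
                           X, y, rng=np.random.default_rng(5), **kwargs)
        assert a[0].test_mean == b[0].test_mean

    def test_stratified_small_size_covers_classes(self, noisy_cohort):
        _, X, y, _ = noisy_cohort
        rng = np.random.default_rng(0)
        from hisskit.bench import _stratified_subset
        pool = np.arange(len(y))
        for _ in range(10):
            idx = _stratified_subset(y, pool, 30, rng)
            assert set(np.unique(y[idx])) == set(np.unique(y))

    def test_infeasible_sizes(self, noisy_cohort):
        _, X, y, _ = noisy_cohort
        with pytest.raises(ValueError):
            learning_curve(_Oracle, X, y, train_sizes=[95], test_size=20)


class TestAnova:
    def test_identical_groups(self):
        f, p = compare_classifiers_anova([[0.9, 0.8, 0.85], [0.9, 0.8, 0.85]])
        assert f == 0.0 and p == 1.0

    def test_separated_groups(self):
        f, p = compare_classifiers_anova([[0.50, 0.51, 0.49], [0.90, 0.91, 0.89]])
        assert p < 1e-5

    def test_permutation_invariant(self):
        groups = [[0.7, 0.75], [0.8, 0.85], [0.6, 0.65]]
        f1, _ = compare_classifiers_anova(groups)
        f2, _ = compare_classifiers_anova(groups[::-1])
        assert f1 == pytest.approx(f2)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_classifiers_anova([[0.9], [0.8, 0.7]])


def _quadratic_grid(coef, patients, experts):
    rows = []
    for p in patients:
        for e in experts:
            acc = (coef[0] + coef[1] * p + coef[2] * e + coef[3] * p * p
                   + coef[4] * e * e + coef[5] * p * e)
            rows.append((p, e, acc))
    return rows


class TestSizingModel:
    COEF = (0.5, 1e-3, 2e-2, -1e-6, -1e-3, 1e-5)

    def test_exact_quadratic_r2_one(self):
        grid = _quadratic_grid(self.COEF, [50, 100, 150, 200], [3, 5, 7, 9])
        model = fit_sizing_model(grid)
        assert model.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(model.coefficients, self.COEF, atol=1e-10)

    def test_constant_grid_zero_slopes(self):
        grid = [(p, e, 0.8) for p in (50, 100, 150) for e in (3, 5, 7)]
        model = fit_sizing_model(grid)
        np.testing.assert_allclose(model.coefficients[1:], 0.0, atol=1e-9)

    def test_row_permutation_invariant(self):
        grid = _quadratic_grid(self.COEF, [50, 100, 150], [3, 5, 7])
        a = fit_sizing_model(grid)
        b = fit_sizing_model(grid[::-1])
        np.testing.assert_allclose(a.coefficients, b.coefficients)

    def test_rank_deficient_rejected(self):
        grid = [(100, e, 0.8) for e in (3, 4, 5, 6, 7, 8)]  # no patient spread
        with pytest.raises(ValueError):
            fit_sizing_model(grid)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_sizing_model([(50, 3, 0.8), (100, 5, 0.9)])


class TestPredictRequirements:
    MONOTONE = SizingModel(
        coefficients=np.array([0.5, 1.5e-3, 2e-2, 0.0, 0.0, 0.0]),
        r_squared=1.0, ss_total=0.0, ss_residual=0.0)

    def test_trivial_target_returns_search_minimum(self):
        assert predict_requirements(self.MONOTONE, 0.01) == (1, 1)

    def test_monotone_targets_order_component_wise(self):
        p1, e1 = predict_requirements(self.MONOTONE, 0.80)
        p2, e2 = predict_requirements(self.MONOTONE, 0.95)
        assert p2 >= p1 and e2 >= e1

    def test_unreachable_target(self):
        capped = SizingModel(coefficients=np.array([0.5, 0, 0, 0, 0, 0]),
                             r_squared=1.0, ss_total=0.0, ss_residual=0.0)
        with pytest.raises(UnreachableTargetError):
            predict_requirements(capped, 0.9999)

    def test_bad_target(self):
        with pytest.raises(ValueError):
            predict_requirements(self.MONOTONE, 1.5)
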