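import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from gaitrsp.classification import (
    _FoldCache,
    compare_sensor_sets,
    enumerate_sensor_sets,
    fit_lda,
    predict,
    repeated_cv_evaluation,
    sequential_forward_selection,
    stratified_folds,
    SelectionResult,
)
from gaitrsp.features import FeatureTable


def make_table(X, y, names=None):
    ids = [f"s{i}" for i in range(len(y))]
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return FeatureTable(
        pd.DataFrame(X, index=ids, columns=names), pd.Series(y, index=ids), {}
    )


class TestEnumerateSensorSets:
    def test_four_sensors_give_fifteen_subsets(self):
        subsets = enumerate_sensor_sets()
        assert len(subsets) == 15
        assert len(set(subsets)) == 15
        sizes = [len(s) for s in subsets]
        assert sizes == sorted(sizes)

    @pytest.mark.parametrize("n,expected", [(1, 1), (3, 7)])
    def test_subset_counts(self, n, expected):
        assert len(enumerate_sensor_sets(("back", "thigh", "shank", "foot")[:n])) == expected

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            enumerate_sensor_sets(())


class TestLda:
    def test_separable_clouds_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_lda(X, y)
        assert np.all(predict(model, X) == y)

    def test_constant_features_predict_majority(self):
        X = np.ones((9, 2))
        y = np.array(["a"] * 2 + ["b"] * 5 + ["c"] * 2)
        model = fit_lda(X, y, ridge=1e-6)
        assert np.all(predict(model, X) == "b")

    def test_three_classes_give_two_discriminant_functions(self, rng):
        X = rng.normal(0, 1, (30, 5))
        y = np.array(["a", "b", "c"] * 10)
        model = fit_lda(X, y)
        assert model.scalings.shape == (5, 2)

    def test_agrees_with_gaussian_bayes_oracle(self):
        """Predictions match an explicit shared-covariance Gaussian density
        oracle on 20 random small instances."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            k, d, n = rng.integers(2, 4), rng.integers(2, 5), 30
            centers = rng.normal(0, 2, (k, d))
            y = rng.integers(0, k, n)
            while len(np.unique(y)) < k or np.bincount(y, minlength=k).min() < 2:
                y = rng.integers(0, k, n)
            X = centers[y] + rng.normal(0, 1, (n, d))
            model = fit_lda(X, y, ridge=0.0)
            # oracle: argmax of class log-density + log-prior, using the same
            # pooled covariance definition evaluated via scipy densities
            means = np.array([X[y == c].mean(axis=0) for c in range(k)])
            S = sum(
                (X[y == c] - means[c]).T @ (X[y == c] - means[c]) for c in range(k)
            ) / (n - k)
            priors = np.bincount(y) / n
            logp = np.column_stack(
                [
                    stats.multivariate_normal.logpdf(X, means[c], S) + np.log(priors[c])
                    for c in range(k)
                ]
            )
            assert np.array_equal(predict(model, X), np.argmax(logp, axis=1))

    def test_agrees_with_sklearn_lda(self, rng):
        X = rng.normal(0, 1, (40, 4)) + np.repeat(np.eye(4)[:2] * 2, 20, axis=0)[:40]
        y = np.array(["a", "b"] * 20)
        ours = predict(fit_lda(X, y, ridge=0.0), X)
        sk = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert np.array_equal(ours, sk)

    def test_single_class_or_tiny_class_rejected(self, rng):
        X = rng.normal(0, 1, (6, 2))
        with pytest.raises(ValueError, match="2 classes"):
            fit_lda(X, ["a"] * 6)
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_lda(X, ["a"] * 5 + ["b"])


class TestStratifiedFolds:
    def test_folds_partition_subjects_and_preserve_proportions(self, rng):
        y = np.array(["Non"] * 10 + ["Low"] * 20 + ["High"] * 9)
        folds = stratified_folds(y, 10, rng)
        allidx = np.sort(np.concatenate(folds))
        assert np.array_equal(allidx, np.arange(39))
        for c, total in (("Non", 10), ("Low", 20), ("High", 9)):
            per_fold = [np.sum(y[f] == c) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1
            assert sum(per_fold) == total

    def test_more_folds_than_subjects_capped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="capping"):
            folds = stratified_folds(np.array(["a", "a", "b", "b"]), 10, rng)
        assert len(folds) == 4


class TestSequentialForwardSelection:
    def planted_table(self, n=30, noise_features=6, seed=0):
        rng = np.random.default_rng(seed)
        y = np.resize(["Non", "Low", "High"], n)
        codes = pd.Series(y).map({"Non": 0, "Low": 1, "High": 2}).to_numpy()
        X = rng.normal(0, 1, (n, noise_features + 1))
        X[:, 3] = codes + rng.normal(0, 0.01, n)  # feature f3 determines class
        return make_table(X, y)

    def test_planted_feature_selected_first_and_error_reaches_zero(self, rng):
        table = self.planted_table()
        folds = stratified_folds(table.labels.to_numpy(), 5, rng)
        res = sequential_forward_selection(table, folds)
        assert res.selected_feature_names[0] == "f3"
        assert res.cv_error_trajectory[-1] == 0.0
        assert res.mean_accuracy == 1.0

    def test_error_trajectory_strictly_decreasing(self, rng):
        rng2 = np.random.default_rng(9)
        X = rng2.normal(0, 1, (30, 8))
        X[:, 0] += np.resize([0, 1.0, 2.0], 30)
        table = make_table(X, np.resize(["a", "b", "c"], 30))
        folds = stratified_folds(table.labels.to_numpy(), 5, rng)
        res = sequential_forward_selection(table, folds)
        assert np.all(np.diff(res.cv_error_trajectory) < 0)

    def test_selection_is_deterministic_for_fixed_seed(self):
        table = self.planted_table(seed=4)
        a = repeated_cv_evaluation(table, n_iterations=3, n_folds=5, seed=13)
        b = repeated_cv_evaluation(table, n_iterations=3, n_folds=5, seed=13)
        assert np.array_equal(a.iteration_accuracies, b.iteration_accuracies)
        assert a.iteration_selected == b.iteration_selected

    def test_greedy_never_beats_exhaustive_oracle(self, rng):
        """Exhaustive search over all <=3-feature subsets lower-bounds the
        greedy CV error; with a single decisive feature the two coincide."""
        table = self.planted_table(n=24, noise_features=5, seed=7)
        y = table.labels.to_numpy()
        folds = stratified_folds(y, 4, rng)
        res = sequential_forward_selection(table, folds)
        X = table.features.to_numpy()
        classes, codes = np.unique(y, return_inverse=True)
        cache = _FoldCache(codes, folds, len(classes))
        from gaitrsp.classification import _cv_wrong

        best_oracle = min(
            _cv_wrong(X[:, list(sub)], cache, 1e-6)
            for r in (1, 2, 3)
            for sub in itertools.combinations(range(X.shape[1]), r)
        )
        greedy_err = res.cv_error_trajectory[-1] * len(y)
        assert greedy_err >= best_oracle
        assert best_oracle == 0 and greedy_err == 0  # planted feature: both perfect

    def test_single_iteration_equals_one_sfs_pass(self):
        table = self.planted_table(seed=2)
        rep = repeated_cv_evaluation(table, n_iterations=1, n_folds=5, seed=21)
        rng = np.random.default_rng([21, 0])
        folds = stratified_folds(table.labels.to_numpy(), 5, rng)
        single = sequential_forward_selection(table, folds)
        assert rep.mean_accuracy == single.mean_accuracy
        assert rep.selected_feature_names == single.selected_feature_names

    def test_empty_feature_table_rejected(self):
        table = make_table(np.zeros((6, 1)), ["a", "b"] * 3).subset([])
        with pytest.raises(ValueError, match="no candidate"):
            sequential_forward_selection(table, [np.array([0, 1])])

    def test_permuted_labels_stay_near_chance_in_nested_mode(self):
        """Label-permutation null: held-out (nested) accuracy must not
        exceed the majority-class rate by more than 3 permutation SDs."""
        rng = np.random.default_rng(31)
        n = 24
        X = rng.normal(0, 1, (n, 8))
        y = np.resize(["a", "a", "b", "c"], n)  # majority rate 0.5
        accs = []
        for p in range(4):
            table = make_table(X, rng.permutation(y))
            res = repeated_cv_evaluation(table, n_iterations=2, n_folds=4,
                                         seed=50 + p, mode="nested")
            accs.append(res.mean_accuracy)
        spread = max(np.std(accs, ddof=1), 0.02)
        assert np.mean(accs) <= 0.5 + 3 * spread


class TestCompareSensorSets:
    def result(self, sensor_set, accs):
        accs = np.asarray(accs, dtype=float)
        return SelectionResult(
            sensor_set=sensor_set,
            selected_feature_names=[],
            cv_error_trajectory=[],
            iteration_accuracies=accs,
            iteration_selected=[[]] * len(accs),
            mean_accuracy=float(accs.mean()),
            sd_accuracy=float(accs.std(ddof=1)),
        )

    def test_identical_accuracy_vectors_give_p_of_one(self):
        accs = [0.7, 0.72, 0.68, 0.7]
        rep = compare_sensor_sets([self.result(("back",), accs), self.result(("thigh",), accs)])
        assert rep.pairwise.iloc[0].p == 1.0
        assert rep.equivalent_sets == [("thigh",)] or rep.equivalent_sets == [("back",)]

    def test_clearly_different_means_are_significant(self, rng):
        a = self.result(("thigh",), 0.80 + 0.02 * rng.standard_normal(10))
        b = self.result(("foot",), 0.50 + 0.02 * rng.standard_normal(10))
        rep = compare_sensor_sets([a, b])
        assert rep.pairwise.iloc[0].p < 0.05
        assert rep.best_set == ("thigh",)
        # closed-form check of the LSD t statistic
        g1, g2 = a.iteration_accuracies, b.iteration_accuracies
        mse = (((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()) / 18
        t_expected = (g1.mean() - g2.mean()) / np.sqrt(mse * 0.2)
        assert rep.pairwise.iloc[0].t == pytest.approx(t_expected, abs=1e-12)

    def test_anova_f_matches_scipy_on_three_groups(self, rng):
        groups = [0.6 + 0.05 * rng.standard_normal(10),
                  0.7 + 0.05 * rng.standard_normal(10),
                  0.65 + 0.05 * rng.standard_normal(10)]
        results = [self.result((n,), g) for n, g in zip("abc", groups)]
        rep = compare_sensor_sets(results)
        f_ref, p_ref = stats.f_oneway(*groups)
        assert rep.anova_f == pytest.approx(f_ref, abs=1e-10)
        assert rep.anova_p == pytest.approx(p_ref, abs=1e-10)

    def test_unequal_iteration_counts_rejected(self):
        with pytest.raises(ValueError, match="equal iteration"):
            compare_sensor_sets(
                [self.result(("a",), [0.7] * 10), self.result(("b",), [0.7] * 9)]
            )
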