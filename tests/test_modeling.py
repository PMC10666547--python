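import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxprio.categorization import assign_ghs, ghs_schema, kmeans_schema
from toxprio.categorization import KMeansCategorizer
from toxprio.modeling import (HyperparameterGrid, default_classification_grid,
                              default_regression_grid, fit_final, grid_search,
                              load_model, predict_category_direct, predict_lc50,
                              save_model, select_by_relative_importance,
                              split_train_test, two_step_categorize)


@pytest.fixture(scope="module")
def toy_regression(request):
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(80, 6)), columns=[f"d{j}" for j in range(6)])
    y = 2.0 * X["d0"].to_numpy() - X["d1"].to_numpy()
    return X, y


class TestSplit:
    def test_sizes_and_partition(self):
        tr, te = split_train_test(10, frac=0.9, seed=0)
        assert len(tr) == 9 and len(te) == 1
        assert sorted([*tr, *te]) == list(range(10))

    def test_reproducible(self):
        assert np.array_equal(split_train_test(50, seed=7)[0],
                              split_train_test(50, seed=7)[0])

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(10, frac=0.01, seed=0)
        with pytest.raises(ValueError):
            split_train_test(1, frac=0.9, seed=0)


class TestGrids:
    def test_regression_grid_spans_printed_ranges(self):
        g = default_regression_grid()
        assert g.n_trees[0] == 100 and g.n_trees[-1] == 1000 and len(g.n_trees) == 10
        assert g.min_leaf == tuple(range(1, 22, 2))

    def test_classification_grid_spans_printed_ranges(self):
        g = default_classification_grid()
        assert g.n_trees[0] == 200 and g.n_trees[-1] == 2000 and len(g.n_trees) == 20
        assert g.min_leaf[0] == 1 and g.min_leaf[-1] == 21

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperparameterGrid(n_trees=(), min_leaf=(1,))
        with pytest.raises(ValueError):
            HyperparameterGrid(n_trees=(0,), min_leaf=(1,))


class TestGridSearch:
    def test_single_cell_returned(self, toy_regression):
        X, y = toy_regression
        gs = grid_search(X, y, "regression",
                         HyperparameterGrid(n_trees=(50,), min_leaf=(3,)), seed=1)
        assert (gs.best_n_trees, gs.best_min_leaf) == (50, 3)
        assert len(gs.best_cv_scores) == 3
        assert (gs.importances >= 0).all()

    def test_informative_variables_rank_highest(self, toy_regression):
        X, y = toy_regression
        gs = grid_search(X, y, "regression",
                         HyperparameterGrid(n_trees=(100,), min_leaf=(2,)), seed=1)
        top2 = set(gs.importances.sort_values(ascending=False).index[:2])
        assert top2 == {"d0", "d1"}

    def test_single_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 3)))
        with pytest.raises(ValueError):
            grid_search(X, np.repeat("a", 30), "classification",
                        HyperparameterGrid(n_trees=(20,), min_leaf=(1,)), seed=0)


class TestRelativeImportanceSelection:
    def test_hand_computed_selection(self):
        imp = {"a": 0.50, "b": 0.30, "c": 0.004}
        # relative: 1.0, 0.6, 0.008 -> first two pass the 1% rule
        assert select_by_relative_importance(imp) == ["a", "b"]

    def test_all_equal_selected(self):
        assert select_by_relative_importance({"a": 0.2, "b": 0.2}) == ["a", "b"]

    def test_exact_threshold_excluded(self):
        imp = {"a": 1.0, "b": 0.01}
        assert select_by_relative_importance(imp, threshold=0.01) == ["a"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            select_by_relative_importance({"a": 0.0, "b": 0.0})

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_free(self, c):
        imp = pd.Series({"a": 0.5, "b": 0.3, "c": 0.004})
        assert (select_by_relative_importance(imp * c)
                == select_by_relative_importance(imp))


class TestFitFinalAndPredict:
    def test_same_seed_identical_predictions(self, toy_regression):
        X, y = toy_regression
        models = [fit_final(X, y, X.columns, 50, 2, "regression", seed=9)
                  for _ in range(2)]
        p = [predict_lc50(m, X) for m in models]
        assert np.array_equal(p[0], p[1])

    def test_noise_free_training_fit_is_strong(self, toy_regression):
        X, y = toy_regression
        m = fit_final(X, y, X.columns, 100, 1, "regression", seed=0)
        assert m.train_score >= (m.oob_score or 0.0)
        assert m.train_score > 0.8

    def test_predictions_bounded_by_training_responses(self, toy_regression):
        X, y = toy_regression
        m = fit_final(X, y, X.columns, 50, 2, "regression", seed=0)
        far = X * 100.0  # far outside training space: trees cannot extrapolate
        p = predict_lc50(m, far)
        assert p.min() >= y.min() and p.max() <= y.max()

    def test_missing_column_named_in_error(self, toy_regression):
        X, y = toy_regression
        m = fit_final(X, y, ["d0", "d1"], 20, 2, "regression", seed=0)
        with pytest.raises(KeyError, match="d1"):
            predict_lc50(m, X[["d0", "d2"]])

    def test_single_label_training(self, toy_regression):
        X, _ = toy_regression
        m = fit_final(X, np.repeat("acute 2", len(X)), X.columns, 20, 1,
                      "classification", seed=0)
        assert set(predict_category_direct(m, X)) == {"acute 2"}

    def test_task_mismatch_rejected(self, toy_regression):
        X, y = toy_regression
        m = fit_final(X, y, X.columns, 20, 2, "regression", seed=0)
        with pytest.raises(ValueError):
            predict_category_direct(m, X)

    def test_persistence_roundtrip(self, toy_regression, tmp_path):
        X, y = toy_regression
        m = fit_final(X, y, X.columns, 30, 2, "regression", seed=3)
        path = save_model(m, tmp_path / "m.joblib")
        back = load_model(path)
        assert np.array_equal(predict_lc50(back, X), predict_lc50(m, X))
        assert path.with_suffix(".joblib.json").exists()


class TestTwoStep:
    def test_matches_elementwise_ghs_composition(self, toy_regression):
        X, y = toy_regression
        m = fit_final(X, y, X.columns, 50, 2, "regression", seed=1)
        labels = two_step_categorize(m, ghs_schema(), X)
        preds = predict_lc50(m, X)
        assert list(labels) == [assign_ghs(10.0 ** p) for p in preds]

    def test_kmeans_schema_requires_masses(self, toy_regression):
        X, y = toy_regression
        m = fit_final(X, y, X.columns, 20, 2, "regression", seed=1)
        cat = KMeansCategorizer(
            centroids=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            feature_means=np.zeros(2), feature_sds=np.ones(2),
            labels=("high toxicity", "low toxicity"))
        with pytest.raises(ValueError, match="mass"):
            two_step_categorize(m, kmeans_schema(cat), X)
        labels = two_step_categorize(m, kmeans_schema(cat), X, masses=np.zeros(len(X)))
        assert set(labels) <= {"high toxicity", "low toxicity"}
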