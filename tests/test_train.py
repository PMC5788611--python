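import numpy as np
import pandas as pd
import pytest

from dhskit.train import (
    FAMILIES,
    HYBRIDS,
    ContractError,
    ModelSpec,
    default_grid,
    enumerate_experiment,
    fit_final,
    grid_search_svm,
    predict,
    repeated_cv,
    _grid_points,
)


def blobs(n=60, d=5, gap=6.0, seed=0):
    """Two well-separated Gaussian clouds -> a linearly separable problem."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    X = rng.normal(size=(n, d)) + gap * y[:, None]
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(d)], index=[f"s{i}" for i in range(n)]), y


SINGLE_POINT_SVM = {"C": [8.0], "gamma": [0.1]}


class TestModelSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            ModelSpec("neural_net")

    def test_svm_grid_must_cover_c_and_gamma(self):
        with pytest.raises(ValueError, match="C and gamma"):
            ModelSpec("svm_rbf", {"C": [1.0]})

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ModelSpec("knn", {"n_neighbors": []})

    def test_default_svm_grid_has_546_points(self):
        assert len(_grid_points(default_grid("svm_rbf"))) == 26 * 21 == 546

    def test_grid_points_ascend_in_sorted_key_order(self):
        pts = _grid_points({"C": [1, 2], "gamma": [3, 4]})
        assert pts == [{"C": 1, "gamma": 3}, {"C": 1, "gamma": 4},
                       {"C": 2, "gamma": 3}, {"C": 2, "gamma": 4}]


class TestGridSearchSVM:
    def test_separable_data_reaches_perfect_training_fit(self):
        X, y = blobs()
        (C, gamma), model = grid_search_svm(
            X, y, c_exponents=range(0, 4), g_exponents=range(-4, 0), folds=3, seed=0
        )
        assert C in {2.0**e for e in range(0, 4)}
        assert gamma in {2.0**e for e in range(-4, 0)}
        labels, scores = predict(model, X)
        assert (labels == y).all()
        assert (scores[y == 1] > 0.5).all()

    def test_refinement_stays_in_neighbourhood(self):
        X, y = blobs(n=40, d=3)
        (c0, g0), _ = grid_search_svm(
            X, y, c_exponents=[3], g_exponents=[-2], folds=2, seed=0
        )
        (c1, g1), _ = grid_search_svm(
            X, y, c_exponents=[3], g_exponents=[-2], folds=2, seed=0, refine=True
        )
        assert 2.0**-0.5 <= c1 / c0 <= 2.0**0.5
        assert 2.0**-0.5 <= g1 / g0 <= 2.0**0.5

    def test_degenerate_grid_rejected(self):
        X, y = blobs(n=20)
        with pytest.raises(ValueError, match="degenerate"):
            grid_search_svm(X, y, c_exponents=[], g_exponents=[0])

    def test_single_class_rejected(self):
        X, _ = blobs(n=20)
        with pytest.raises(ValueError, match="two classes"):
            grid_search_svm(X, np.ones(20, dtype=int))


class TestRepeatedCV:
    def test_perfect_separation_gives_unit_metrics(self):
        X, y = blobs(n=60)
        cv = repeated_cv(X, y, ModelSpec("svm_rbf", SINGLE_POINT_SVM),
                         repeats=2, folds=3, seed=0)
        assert cv.report.mcc == pytest.approx(1.0)
        assert cv.report.acc == pytest.approx(1.0)
        assert cv.report.auc == pytest.approx(1.0)

    def test_every_sample_predicted_once_per_repeat(self):
        X, y = blobs(n=40)
        cv = repeated_cv(X, y, ModelSpec("knn", {"n_neighbors": [3]}),
                         repeats=3, folds=4, seed=1)
        for _, grp in cv.oof.groupby("repeat"):
            assert sorted(grp["id"]) == sorted(X.index)

    def test_folds_are_class_stratified(self):
        X, y = blobs(n=60)
        folds = 5
        cv = repeated_cv(X, y, ModelSpec("knn", {"n_neighbors": [3]}),
                         repeats=2, folds=folds, seed=2)
        expected = y.sum() / folds
        for _, grp in cv.oof.groupby(["repeat", "fold"]):
            assert abs(grp["label"].sum() - expected) <= 1

    def test_deterministic_given_seed(self):
        X, y = blobs(n=40)
        spec = ModelSpec("svm_rbf", SINGLE_POINT_SVM)
        a = repeated_cv(X, y, spec, repeats=2, folds=3, seed=7)
        b = repeated_cv(X, y, spec, repeats=2, folds=3, seed=7)
        pd.testing.assert_frame_equal(a.oof, b.oof)
        assert a.report.mcc == b.report.mcc

    def test_nested_tuning_tie_breaks_to_smallest_parameter(self):
        X, y = blobs(n=60, gap=10.0)
        cv = repeated_cv(X, y, ModelSpec("knn", {"n_neighbors": [1, 3, 5]}),
                         repeats=1, folds=3, seed=0)
        # every inner search ties at MCC=1; ascending order keeps k=1
        assert all(p == {"n_neighbors": 1} for p in cv.chosen_params)
        assert cv.median_params == {"n_neighbors": 1}

    def test_class_smaller_than_fold_count_rejected(self):
        X, y = blobs(n=12)
        with pytest.raises(ValueError, match="at least"):
            repeated_cv(X, y, ModelSpec("knn", {"n_neighbors": [1]}),
                        repeats=1, folds=10)

    def test_label_permutation_yields_null_mcc(self):
        """Aggregated MCC stays near zero on label-permuted data."""
        spec = ModelSpec("svm_rbf", SINGLE_POINT_SVM)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(300, 10)),
                             columns=[f"f{i}" for i in range(10)])
            y = rng.permutation(np.repeat([1, 0], 150))
            cv = repeated_cv(X, y, spec, repeats=2, folds=5, seed=seed)
            assert abs(cv.report.mcc) <= 0.15


@pytest.fixture(scope="module")
def fitted():
    X, y = blobs(n=40)
    model = fit_final(X, y, ModelSpec("svm_rbf", SINGLE_POINT_SVM),
                      params={"C": 8.0, "gamma": 0.1}, seed=0)
    return X, y, model


class TestPredictContract:

    def test_training_points_recovered_with_confident_scores(self, fitted):
        X, y, model = fitted
        labels, scores = predict(model, X)
        assert (labels == y).all()
        assert ((scores > 0.5) == (y == 1)).all()

    def test_shuffled_columns_rejected(self, fitted):
        X, _, model = fitted
        with pytest.raises(ContractError, match="out of order"):
            predict(model, X[list(X.columns[::-1])])

    def test_missing_column_named_in_error(self, fitted):
        X, _, model = fitted
        with pytest.raises(ContractError, match="f0"):
            predict(model, X.drop(columns=["f0"]))

    def test_empty_matrix_gives_empty_output(self, fitted):
        X, _, model = fitted
        labels, scores = predict(model, X.iloc[:0])
        assert labels.size == 0 and scores.size == 0


class TestEnumerateExperiment:
    def test_default_enumeration_is_132_configurations(self):
        configs = enumerate_experiment()
        assert len(configs) == 132
        assert len({c["family"] for c in configs}) == 4

    def test_33_configurations_per_family(self):
        configs = enumerate_experiment(families=["svm_rbf"])
        assert len(configs) == 33

    def test_blocks_and_hybrids_only(self):
        configs = enumerate_experiment(families=["svm_rbf"], fis_thresholds=[])
        assert len(configs) == 14

    def test_hybrid_definitions(self):
        assert HYBRIDS["H1"] == ("MNC", "DNC")
        assert set(HYBRIDS["H7"]) == {"MNC", "DNC", "TNC", "TeNC", "PNC", "DPCP", "TPCP"}
        assert all(set(v) <= set(HYBRIDS["H7"]) for v in HYBRIDS.values())
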