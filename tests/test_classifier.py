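"""The machine-learning protocol: exact accuracy, CV, grid search, RFE, final model."""

import numpy as np
import pandas as pd
import pytest

from bioxtal import (
    FEATURE_SETS,
    FeatureVector,
    InterfaceClassifier,
    SyntheticTableSpec,
    TrainingConfig,
    compute_accuracy,
    cross_validate,
    generate_feature_table,
    grid_search,
    load_model,
    predict,
    recursive_feature_elimination,
    save_model,
    train_final,
)

FINAL22 = list(FEATURE_SETS["FINAL22"])


def separable_frame(n=120, n_features=4, seed=0, gap=8.0):
    """Two disjoint Gaussian blobs -> any sane classifier is near-perfect."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n // 2, n_features))
    b = rng.standard_normal((n // 2, n_features)) + gap
    X = pd.DataFrame(np.vstack([a, b]), columns=[f"f{i}" for i in range(n_features)])
    y = np.array(["bio"] * (n // 2) + ["xtal"] * (n // 2))
    return X, y


class TestAccuracy:
    def test_published_confusion_matrix_gives_092_exactly(self):
        # sensitivity 91/100, specificity 93/100 on a balanced set
        assert compute_accuracy(91, 93, 100, 100) == 0.92

    def test_exact_rational_arithmetic_on_counts(self):
        from fractions import Fraction

        assert compute_accuracy(1, 0, 3, 0) == float(Fraction(1, 3))
        assert compute_accuracy(21, 12, 40, 26) == float(Fraction(33, 66)) == 0.5

    def test_degenerate_cases(self):
        assert compute_accuracy(10, 20, 10, 20) == 1.0
        assert compute_accuracy(0, 0, 5, 5) == 0.0
        with pytest.raises(ValueError):
            compute_accuracy(0, 0, 0, 0)
        with pytest.raises(ValueError):
            compute_accuracy(5, 0, 3, 0)


class TestCrossValidate:
    def test_separable_data_is_almost_perfect(self):
        X, y = separable_frame()
        for algorithm in ("random_forest", "bagging"):
            config = TrainingConfig(
                algorithm=algorithm,
                hyperparameters={"n_estimators": 25},
                n_repeats=1,
                seed=0,
            )
            report = cross_validate(X, y, config)
            assert report.mean_accuracy >= 0.99

    def test_same_seed_twice_is_identical(self):
        X, y = separable_frame(seed=3, gap=1.0)
        config = TrainingConfig(hyperparameters={"n_estimators": 20}, n_repeats=2, seed=42)
        r1 = cross_validate(X, y, config)
        r2 = cross_validate(X, y, config)
        assert r1.fold_accuracies == r2.fold_accuracies

    def test_permuted_labels_score_at_chance(self):
        frame = generate_feature_table(
            SyntheticTableSpec(n_bio=150, n_xtal=150, seed=5), feature_set="FINAL22"
        )
        rng = np.random.default_rng(5)
        y = rng.permutation(frame["class"].to_numpy())
        config = TrainingConfig(hyperparameters={"n_estimators": 50}, n_repeats=3, seed=5)
        report = cross_validate(frame[FINAL22], y, config)
        assert report.mean_accuracy == pytest.approx(0.5, abs=0.08)

    def test_single_class_is_rejected(self):
        X, _ = separable_frame()
        with pytest.raises(ValueError):
            cross_validate(X, np.array(["bio"] * len(X)))

    def test_report_aggregates_all_folds(self):
        X, y = separable_frame(seed=1)
        config = TrainingConfig(hyperparameters={"n_estimators": 10}, n_folds=5, n_repeats=3, seed=1)
        report = cross_validate(X, y, config)
        assert len(report.fold_accuracies) == 15
        assert report.mean_accuracy == pytest.approx(np.mean(report.fold_accuracies))
        totals = report.confusion_totals
        assert sum(totals.values()) == len(X) * 3


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self):
        X, y = separable_frame()
        config = TrainingConfig(n_repeats=1, seed=0)
        best, report, results = grid_search(X, y, "random_forest", {"n_estimators": [15]}, config)
        assert best == {"n_estimators": 15}
        assert len(results) == 1

    def test_tie_break_prefers_fewest_estimators(self):
        X, y = separable_frame(gap=25.0)  # wide margin: both grid points tie at 1.0
        config = TrainingConfig(n_repeats=1, seed=0)
        best, report, results = grid_search(
            X, y, "random_forest", {"n_estimators": [10, 250]}, config
        )
        assert all(r.mean_accuracy >= 0.99 for _, r in results)
        assert best == {"n_estimators": 10}

    def test_best_is_no_worse_than_any_grid_point(self):
        X, y = separable_frame(seed=7, gap=1.2)
        config = TrainingConfig(n_repeats=1, seed=7)
        best, best_report, results = grid_search(
            X, y, "random_forest", {"n_estimators": [10, 30], "max_depth": [2, None]}, config
        )
        # independent re-evaluation of every grid point
        for params, _ in results:
            redo = cross_validate(
                X, y, TrainingConfig("random_forest", params, n_repeats=1, seed=7)
            )
            assert best_report.mean_accuracy >= redo.mean_accuracy - 1e-12

    def test_default_grids_cover_the_tuned_axes_for_every_algorithm(self):
        from bioxtal.classifier import ALGORITHMS, DEFAULT_GRIDS, _VALID_PARAMS

        assert set(DEFAULT_GRIDS) == set(ALGORITHMS)
        for algorithm, grid in DEFAULT_GRIDS.items():
            assert set(grid) == _VALID_PARAMS[algorithm] - {"max_depth"} or (
                set(grid) == _VALID_PARAMS[algorithm]
            )
            # every candidate is accepted by the estimator config
            TrainingConfig(algorithm=algorithm, hyperparameters={k: v[0] for k, v in grid.items()})

    def test_invalid_grid_key_is_rejected(self):
        X, y = separable_frame()
        with pytest.raises(ValueError):
            grid_search(X, y, "random_forest", {"learning_rate": [0.1]})
        with pytest.raises(ValueError):
            grid_search(X, y, "random_forest", {})


class TestRFE:
    def test_fully_informative_feature_ranks_first_and_survives(self):
        rng = np.random.default_rng(0)
        n = 160
        X = pd.DataFrame(rng.standard_normal((n, 6)), columns=[f"noise{i}" for i in range(5)] + ["signal"])
        y = np.where(X["signal"] > 0, "bio", "xtal")
        X["signal"] = X["signal"] + 0.05 * rng.standard_normal(n)
        result = recursive_feature_elimination(
            X, y, TrainingConfig(seed=0, n_repeats=1, n_folds=4), n_trees=100
        )
        assert result.ranking[0] == "signal"
        assert "signal" in result.selected

    def test_aa_outranks_pp_under_the_class_conditional_model(self):
        """AA separates bio from xtal strongly; PP is near-identically distributed."""
        wins = 0
        for seed in range(5):
            frame = generate_feature_table(
                SyntheticTableSpec(n_bio=120, n_xtal=120, seed=seed), feature_set="S5"
            )
            X = frame[list(FEATURE_SETS["S5"])]
            y = frame["class"].to_numpy()
            forest = InterfaceClassifier(
                algorithm="random_forest", n_estimators=200, max_features="sqrt", random_state=seed
            ).fit(X, y)
            importances = dict(zip(X.columns, forest.feature_importances_))
            wins += importances["AA"] > importances["PP"]
        assert wins == 5

    def test_needs_at_least_two_features(self):
        X, y = separable_frame(n_features=1)
        with pytest.raises(ValueError):
            recursive_feature_elimination(X, y)


class TestFinalModel:
    @pytest.fixture(scope="class")
    def table(self):
        frame = generate_feature_table(
            SyntheticTableSpec(n_bio=150, n_xtal=150, seed=9), feature_set="FINAL22"
        )
        return frame[FINAL22], frame["class"].to_numpy()

    def test_training_on_separable_final22_table_is_accurate(self, table):
        X, y = table
        model = train_final(X, y, seed=1)
        accuracy = np.mean(model.estimator.predict(X) == y)
        assert accuracy >= 0.99  # training-set accuracy on well-separated classes

    def test_same_seed_gives_identical_predictions(self, table):
        X, y = table
        m1 = train_final(X, y, seed=7)
        m2 = train_final(X, y, seed=7)
        assert np.array_equal(m1.estimator.p_bio(X), m2.estimator.p_bio(X))

    def test_non_final22_manifest_is_rejected_at_training(self):
        X, y = separable_frame()
        with pytest.raises(ValueError, match="FINAL22"):
            train_final(X, y, seed=0)

    def test_prediction_refuses_a_mismatched_manifest(self, table):
        X, y = table
        model = train_final(X, y, seed=0)
        s3_vector = FeatureVector("S3", FEATURE_SETS["S3"], np.ones(6), entry_id="bad")
        (pred,) = predict(model, [s3_vector])
        assert pred.label == "error"
        with pytest.raises(ValueError):
            model.estimator.predict(pd.DataFrame(np.ones((1, 6)), columns=FEATURE_SETS["S3"]))

    def test_probabilities_are_normalized_and_nan_rows_fail_individually(self, table):
        X, y = table
        model = train_final(X, y, seed=0)
        good = FeatureVector("FINAL22", tuple(FINAL22), X.iloc[0].to_numpy(), entry_id="good")
        bad_values = X.iloc[1].to_numpy().copy()
        bad_values[3] = np.nan
        bad = FeatureVector("FINAL22", tuple(FINAL22), bad_values, entry_id="bad")
        preds = predict(model, [good, bad])
        assert preds[0].label in ("bio", "xtal")
        proba = model.estimator.predict_proba(X.iloc[[0]])
        assert proba.sum(axis=1) == pytest.approx(1.0)
        assert preds[1].label == "error" and "bad" == preds[1].entry_id
        assert predict(model, []) == []

    def test_bio_centroid_is_predicted_bio_with_high_confidence(self, table):
        X, y = table
        model = train_final(X, y, seed=0)
        centroid = X[np.asarray(y) == "bio"].mean().to_frame().T
        assert model.estimator.predict(centroid)[0] == "bio"
        assert model.estimator.p_bio(centroid)[0] > 0.9

    def test_model_round_trips_through_disk(self, table, tmp_path):
        X, y = table
        model = train_final(X, y, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.feature_manifest == model.feature_manifest
        assert loaded.metadata["training_hash"] == model.metadata["training_hash"]
        assert np.array_equal(loaded.estimator.p_bio(X), model.estimator.p_bio(X))

    def test_foreign_archives_fail_loudly(self, tmp_path):
        import joblib

        path = tmp_path / "other.joblib"
        joblib.dump({"something": "else"}, path)
        with pytest.raises(ValueError, match="refusing to load"):
            load_model(path)


class TestNeuralNetworkPath:
    def test_standardization_is_learned_on_training_data_only(self):
        X, y = separable_frame(n=80, seed=2, gap=3.0)
        clf = InterfaceClassifier(algorithm="neural_network", random_state=0).fit(X, y)
        scaler = clf.estimator_.named_steps["scale"]
        assert scaler.mean_ == pytest.approx(X.to_numpy().mean(axis=0))
        # altering unseen data never changes the fitted statistics
        _ = clf.predict(X + 100.0)
        assert scaler.mean_ == pytest.approx(X.to_numpy().mean(axis=0))

    def test_network_separates_disjoint_blobs(self):
        X, y = separable_frame(n=80, seed=4)
        config = TrainingConfig(algorithm="neural_network", n_repeats=1, n_folds=4, seed=4)
        report = cross_validate(X, y, config)
        assert report.mean_accuracy >= 0.99


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(algorithm="svm")
    with pytest.raises(ValueError):
        TrainingConfig(n_folds=1)
    with pytest.raises(ValueError):
        TrainingConfig(algorithm="adaboost", hyperparameters={"max_depth": 3})


@pytest.mark.parametrize("algorithm", ["adaboost", "gradient_boosting"])
def test_boosting_algorithms_train_and_predict(algorithm):
    X, y = separable_frame(n=60)
    clf = InterfaceClassifier(algorithm=algorithm, n_estimators=20, random_state=0).fit(X, y)
    assert set(clf.predict(X)) <= {"bio", "xtal"}
    assert np.mean(clf.predict(X) == y) >= 0.99
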