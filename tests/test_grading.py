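"""Repeated stratified hold-out evaluation of the four classifier families."""

import numpy as np
import pandas as pd
import pytest

from gliograde.grading import (
    ModelSpec,
    SplitScheme,
    default_model_specs,
    evaluate,
    external_validation,
    make_splits,
    per_grade_accuracy,
    tune_and_train,
)


def _blob_table(n_per_class=20, sep=8.0, seed=0, n_features=4):
    """Well-separated three-class Gaussian blobs."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, grade in enumerate(("II", "III", "IV")):
        X = rng.standard_normal((n_per_class, n_features)) + gi * sep
        for i in range(n_per_class):
            rows.append({"case_id": f"{grade}_{i}", "grade": grade,
                         **{f"f{j}": X[i, j] for j in range(n_features)}})
    return pd.DataFrame(rows)


class TestMakeSplits:
    def test_116_case_design_gives_87_train_29_test(self):
        labels = np.repeat(["II", "III", "IV"], [39, 36, 41])
        splits = make_splits(116, labels, SplitScheme(master_seed=1))
        assert len(splits) == 30  # default repeat count
        for tr, te in splits:
            assert len(tr) == 87 and len(te) == 29

    def test_each_repeat_is_a_partition(self):
        labels = np.repeat(["II", "III", "IV"], [10, 11, 12])
        for tr, te in make_splits(33, labels, SplitScheme(n_repeats=5, master_seed=0)):
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.union1d(tr, te)) == 33

    def test_stratification_keeps_every_class_in_both_halves(self):
        labels = np.repeat(["II", "III", "IV"], [8, 9, 10])
        for tr, te in make_splits(27, labels, SplitScheme(n_repeats=10, master_seed=3)):
            assert set(labels[tr]) == set(labels[te]) == {"II", "III", "IV"}

    def test_deterministic_given_master_seed(self):
        labels = np.repeat(["II", "IV"], [10, 10])
        a = make_splits(20, labels, SplitScheme(n_repeats=3, master_seed=7))
        b = make_splits(20, labels, SplitScheme(n_repeats=3, master_seed=7))
        for (t1, s1), (t2, s2) in zip(a, b):
            assert np.array_equal(t1, t2) and np.array_equal(s1, s2)

    def test_class_with_single_case_rejected(self):
        labels = np.array(["II"] * 10 + ["IV"])
        with pytest.raises(ValueError, match=">= 2"):
            make_splits(11, labels, SplitScheme())


class TestTuneAndTrain:
    def test_separable_blobs_svm_perfect(self):
        df = _blob_table()
        spec = [s for s in default_model_specs() if s.family == "SVM"][0]
        fitted = tune_and_train(spec, df[[f"f{j}" for j in range(4)]], df["grade"], seed=0)
        assert fitted.score(df[[f"f{j}" for j in range(4)]], df["grade"]) == 1.0

    def test_single_cell_grid_equals_plain_training(self):
        df = _blob_table(seed=1)
        X, y = df[[f"f{j}" for j in range(4)]], df["grade"]
        spec = ModelSpec("SVM", {"model__C": [1.0]})
        searched = tune_and_train(spec, X, y, seed=0)
        plain = ModelSpec("SVM", {}).build(seed=0).set_params(model__C=1.0).fit(X, y)
        assert np.array_equal(searched.predict(X), plain.predict(X))

    def test_best_grid_cell_is_argmax_of_inner_cv(self):
        df = _blob_table(seed=2, sep=2.0)
        X, y = df[[f"f{j}" for j in range(4)]], df["grade"]
        spec = ModelSpec("SVM", {"model__C": [0.01, 1.0, 100.0]})
        search = tune_and_train(spec, X, y, seed=0)
        assert search.best_score_ == pytest.approx(max(search.cv_results_["mean_test_score"]))

    def test_scaler_statistics_come_from_training_rows_only(self):
        """Leakage canary: shifting unseen rows must not move the fitted scaler."""
        df = _blob_table(seed=3)
        X = df[[f"f{j}" for j in range(4)]]
        spec = ModelSpec("SVM", {"model__C": [1.0]})
        fitted = tune_and_train(spec, X.iloc[:40], df["grade"].iloc[:40], seed=0)
        scaler = fitted.best_estimator_.named_steps["scale"]
        np.testing.assert_allclose(scaler.mean_, X.iloc[:40].mean().to_numpy())


class TestEvaluate:
    def test_oracle_feature_scores_perfectly_on_all_metrics(self):
        """A feature equal to the class index makes every family an oracle."""
        df = _blob_table(n_per_class=12, sep=50.0, seed=4, n_features=2)
        scheme = SplitScheme(n_repeats=4, master_seed=0)
        specs = [ModelSpec("SVM", {"model__C": [10.0]})]
        metrics = evaluate(specs, df, scheme, feature_columns=["f0", "f1"])["SVM"]
        for metric in ("accuracy", "precision_macro", "recall_macro", "f1_macro"):
            mean, _ = metrics.aggregate[metric]
            assert mean == 1.0
        assert np.all(metrics.confusion == np.diag(np.diag(metrics.confusion)))

    def test_confusion_rows_match_true_class_counts_every_repeat(self):
        df = _blob_table(n_per_class=12, sep=1.0, seed=5)
        scheme = SplitScheme(n_repeats=5, master_seed=2)
        specs = [ModelSpec("RF", {"model__n_estimators": [50]})]
        m = evaluate(specs, df, scheme, feature_columns=[f"f{j}" for j in range(4)])["RF"]
        log = m.prediction_log
        for rep, grp in log.groupby("repeat"):
            true_counts = grp["true"].value_counts()
            for grade in ("II", "III", "IV"):
                assert true_counts[grade] == 3  # 25% of 12 per class
        # pooled matrix total equals the pooled test size
        assert m.confusion.sum() == len(log)
        # row sums equal pooled true counts
        for i, grade in enumerate(m.classes):
            assert m.confusion[i].sum() == (log["true"] == grade).sum()

    def test_per_grade_accuracy_matches_prediction_log_recount(self):
        df = _blob_table(n_per_class=12, sep=1.5, seed=6)
        scheme = SplitScheme(n_repeats=4, master_seed=1)
        specs = [ModelSpec("SVM", {"model__C": [1.0]})]
        m = evaluate(specs, df, scheme, feature_columns=[f"f{j}" for j in range(4)])["SVM"]
        log = m.prediction_log
        for grade, acc in m.per_grade_accuracy.items():
            sub = log[log["true"] == grade]
            assert acc == pytest.approx((sub["predicted"] == grade).mean())

    def test_macro_f1_recomputable_from_per_class_f1(self):
        from sklearn.metrics import f1_score

        df = _blob_table(n_per_class=10, sep=1.0, seed=7)
        scheme = SplitScheme(n_repeats=2, master_seed=0)
        specs = [ModelSpec("SVM", {"model__C": [1.0]})]
        m = evaluate(specs, df, scheme, feature_columns=[f"f{j}" for j in range(4)])["SVM"]
        log = m.prediction_log
        for rep, grp in log.groupby("repeat"):
            per_class = f1_score(grp["true"], grp["predicted"], average=None,
                                 labels=list(m.classes), zero_division=0)
            row = m.per_repeat[m.per_repeat["repeat"] == rep].iloc[0]
            assert row["f1_macro"] == pytest.approx(per_class.mean())


class TestPerGradeAccuracy:
    def test_diagonal_matrix_is_perfect(self):
        acc = per_grade_accuracy(np.diag([5, 7, 9]))
        assert acc == {"II": 1.0, "III": 1.0, "IV": 1.0}

    def test_row_example(self):
        cm = np.array([[8, 2, 0], [1, 8, 1], [0, 0, 10]])
        assert per_grade_accuracy(cm)["II"] == pytest.approx(0.8)

    def test_empty_row_reported_missing_not_zero(self):
        cm = np.array([[0, 0, 0], [0, 5, 0], [0, 1, 4]])
        assert per_grade_accuracy(cm)["II"] is None


class TestExternalValidation:
    def test_holdout_scored_by_every_repeat_model(self):
        df = _blob_table(n_per_class=16, sep=10.0, seed=8)
        train, hold = df.iloc[: 3 * 12], df.iloc[3 * 12:]
        scheme = SplitScheme(n_repeats=3, master_seed=0)
        specs = [ModelSpec("SVM", {"model__C": [10.0]})]
        out = external_validation(specs, train.reset_index(drop=True),
                                  hold.reset_index(drop=True), scheme,
                                  feature_columns=[f"f{j}" for j in range(4)])
        assert len(out["SVM"]["per_repeat"]) == 3
        assert out["SVM"]["accuracy_mean"] == 1.0  # fully separable
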