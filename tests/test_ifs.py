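import numpy as np
import pytest

from m5cfeat.encode import FeatureMatrix, descriptor_for, make_descriptors, valid_kmer_starts
from m5cfeat.errors import ValidationError
from m5cfeat.ifs import ClassifierSpec, CVConfig, cross_validate, run_ifs, write_ifs
from m5cfeat.mrmr import RankedList


def _matrix(X, y_pm):
    """Wrap a raw array as a FeatureMatrix with toy provenance."""
    n, m = X.shape
    starts = list(range(1, m + 1))
    descriptors = make_descriptors(1, starts, 1)
    labels = ["positive" if v > 0 else "negative" for v in y_pm]
    return FeatureMatrix(values=X, descriptors=descriptors, labels=labels)


def _trivial_ranked(m):
    return RankedList(order=list(range(1, m + 1)), step_scores=[(0, 0, 0)] * m)


class TestClassifierSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("naive_bayes")

    def test_defaults_echoed(self):
        spec = ClassifierSpec("knn")
        assert spec.hyperparameters["n_neighbors"] == 5
        spec = ClassifierSpec("random_forest", {"n_estimators": 10})
        assert spec.hyperparameters["n_estimators"] == 10

    @pytest.mark.parametrize("family", ["decision_tree", "knn", "random_forest", "svm"])
    def test_build_returns_fit_predict(self, family):
        model = ClassifierSpec(family).build(seed=0)
        X = np.array([[0.0], [0.1], [5.0], [5.1], [0.2], [5.2]])
        y = np.array([-1, -1, 1, 1, -1, 1])
        model.fit(X, y)
        assert set(model.predict(X)) <= {-1, 1}


class TestCrossValidate:
    def test_perfectly_separable_single_feature(self):
        y = np.array([1, -1] * 10)
        X = y.reshape(-1, 1).astype(float)
        counts = cross_validate(
            _matrix(X, y), ClassifierSpec("knn", {"n_neighbors": 1}), CVConfig(seed=3)
        )
        assert counts.FP == counts.FN == 0
        assert counts.TP + counts.TN == 20

    def test_every_sample_tested_once(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 5 + [-1] * 5)
        X = rng.normal(size=(10, 3))
        counts = cross_validate(_matrix(X, y), ClassifierSpec("knn"), CVConfig(n_folds=10, seed=1))
        assert counts.total == 10  # leave-one-out-like folds of size 1

    def test_label_permutation_null_mcc_near_zero(self):
        from m5cfeat.metrics import compute_metrics

        rng = np.random.default_rng(7)
        for seed in (0, 1, 2):
            y = np.array([1] * 100 + [-1] * 100)
            X = rng.normal(size=(200, 5))  # features carry no label signal
            counts = cross_validate(_matrix(X, y), ClassifierSpec("knn"), CVConfig(seed=seed))
            assert abs(compute_metrics(counts).MCC) < 0.3

    def test_too_many_folds_rejected(self):
        y = np.array([1, 1, 1, -1, -1, -1])
        X = np.zeros((6, 1))
        with pytest.raises(ValueError):
            cross_validate(_matrix(X, y), ClassifierSpec("knn"), CVConfig(n_folds=7, seed=0))

    def test_training_fold_losing_a_class_rejected(self):
        # a lone negative must land in some test fold, emptying its
        # training fold of negatives
        y = np.array([1, 1, 1, 1, 1, -1])
        X = np.arange(6, dtype=float).reshape(-1, 1)
        with pytest.raises(ValidationError):
            cross_validate(_matrix(X, y), ClassifierSpec("knn", {"n_neighbors": 1}),
                           CVConfig(n_folds=2, seed=0))

    def test_single_class_rejected(self):
        X = np.zeros((6, 1))
        mat = _matrix(X, np.ones(6))
        with pytest.raises(ValidationError):
            cross_validate(mat, ClassifierSpec("knn"), CVConfig(n_folds=3, seed=0))


class TestRunIfs:
    def test_tie_breaks_to_smallest_prefix(self):
        # feature 1 alone separates perfectly; larger prefixes also reach
        # MCC=1 but the optimum must stay at size 1
        y = np.array([1, -1] * 10)
        X = np.column_stack([y.astype(float), np.zeros(20)])
        res = run_ifs(
            _matrix(X, y), _trivial_ranked(2),
            ClassifierSpec("knn", {"n_neighbors": 1}), CVConfig(seed=0),
        )
        assert res.rows[0][1].MCC == 1.0
        assert res.optimum_size == 1

    def test_rows_cover_all_sizes_with_valid_metrics(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 15 + [-1] * 15)
        X = rng.normal(size=(30, 6)) + y[:, None] * 0.5
        res = run_ifs(_matrix(X, y), _trivial_ranked(6), ClassifierSpec("decision_tree"),
                      CVConfig(n_folds=5, seed=2), max_size=4)
        assert [s for s, _ in res.rows] == [1, 2, 3, 4]
        for _, ms in res.rows:
            assert 0 <= ms.ACC <= 1 and -1 <= ms.MCC <= 1

    @pytest.mark.parametrize("family", ["decision_tree", "knn", "svm", "random_forest"])
    def test_deterministic_given_seed(self, family):
        rng = np.random.default_rng(9)
        y = np.array([1] * 20 + [-1] * 20)
        X = rng.normal(size=(40, 5)) + y[:, None] * 0.8
        mat = _matrix(X, y)
        spec = ClassifierSpec(family, {"n_estimators": 20} if family == "random_forest" else {})
        a = run_ifs(mat, _trivial_ranked(5), spec, CVConfig(n_folds=5, seed=6))
        b = run_ifs(mat, _trivial_ranked(5), spec, CVConfig(n_folds=5, seed=6))
        assert [(s, ms.as_tuple()) for s, ms in a.rows] == [
            (s, ms.as_tuple()) for s, ms in b.rows
        ]

    def test_constant_feature_ranked_last_changes_nothing_before_it(self):
        rng = np.random.default_rng(11)
        y = np.array([1] * 12 + [-1] * 12)
        X = rng.normal(size=(24, 3)) + y[:, None]
        X_plus = np.column_stack([X, np.full(24, 7.0)])
        base = run_ifs(_matrix(X, y), _trivial_ranked(3), ClassifierSpec("knn"),
                       CVConfig(n_folds=4, seed=1))
        plus = run_ifs(_matrix(X_plus, y), _trivial_ranked(4), ClassifierSpec("knn"),
                       CVConfig(n_folds=4, seed=1))
        assert [(s, m.as_tuple()) for s, m in base.rows] == [
            (s, m.as_tuple()) for s, m in plus.rows[:3]
        ]

    def test_mismatched_ranked_list_rejected(self):
        y = np.array([1, 1, -1, -1])
        mat = _matrix(np.zeros((4, 2)), y)
        with pytest.raises(ValidationError):
            run_ifs(mat, _trivial_ranked(5), ClassifierSpec("knn"), CVConfig(n_folds=2, seed=0))

    def test_metadata_echoes_configuration(self):
        y = np.array([1, -1] * 6)
        X = y.reshape(-1, 1).astype(float)
        res = run_ifs(_matrix(X, y), _trivial_ranked(1),
                      ClassifierSpec("svm", {"C": 2.0}), CVConfig(n_folds=3, seed=5))
        assert res.metadata["classifier"] == "svm"
        assert res.metadata["hyperparameters"]["C"] == 2.0
        assert res.metadata["seed"] == 5
        assert res.metadata["standardized"] is True


def test_ifs_tsv_layout(tmp_path):
    y = np.array([1, -1] * 8)
    X = np.column_stack([y.astype(float), np.zeros(16)])
    res = run_ifs(_matrix(X, y), _trivial_ranked(2),
                  ClassifierSpec("knn", {"n_neighbors": 1}), CVConfig(n_folds=4, seed=0))
    write_ifs(res, tmp_path / "ifs.tsv", header="stamp")
    lines = (tmp_path / "ifs.tsv").read_text().splitlines()
    assert lines[0] == "# stamp"
    assert lines[2].split("\t") == [
        "classifier", "n_features", "SN", "SP", "ACC", "MCC", "precision", "F1",
    ]
    assert len(lines) == 5  # stamp + optimum + header + 2 rows
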