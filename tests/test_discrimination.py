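"""Within-subject normalization, LOSO folds, classification and selection."""

import numpy as np
import pytest

from fcstates.discrimination import (
    ClassifierConfig,
    DEFAULT_C_GRID,
    FeatureTable,
    StateClassifier,
    WithinSubjectRatio,
    accuracy_score,
    concatenate_features,
    fit_predict_multiclass,
    loso_folds,
    normalize_within_subject,
    run_loso,
)


def _table(X, subjects, states):
    return FeatureTable(np.asarray(X, float), np.asarray(subjects), np.asarray(states))


@pytest.fixture
def separable_table(rng):
    """3 well-separated state clusters, 6 subjects, cluster means >> spread."""
    subjects = np.repeat(np.arange(6), 3)
    states = np.tile(np.arange(3), 6)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    X = centers[states] + 0.1 * rng.normal(size=(18, 2))
    return _table(X, subjects, states)


class TestClassifierConfig:
    def test_default_c_grid_spans_stated_range(self):
        grid = ClassifierConfig().c_grid
        assert len(grid) == 8
        assert grid[0] == pytest.approx(0.001)
        assert grid[-1] == pytest.approx(1000.0)
        ratios = np.diff(np.log10(grid))
        assert np.allclose(ratios, ratios[0])  # log-spaced

    def test_rejects_unsorted_grid(self):
        with pytest.raises(ValueError):
            ClassifierConfig(c_grid=(1.0, 0.1))


class TestNormalizeWithinSubject:
    def test_identical_states_normalize_to_one(self):
        X = np.tile([2.0, -3.0], (10, 1))
        t = _table(X, np.repeat(np.arange(2), 5), np.tile(np.arange(5), 2))
        norm, flags = normalize_within_subject(t)
        assert np.allclose(norm.X, 1.0)
        assert not flags.any()

    def test_hand_computed_ratio(self):
        # one subject's feature across 5 states (1,1,1,1,6): mean 2
        X = np.array([[1.0], [1.0], [1.0], [1.0], [6.0]])
        t = _table(X, np.zeros(5, int), np.arange(5))
        norm, _ = normalize_within_subject(t)
        assert np.allclose(norm.X.ravel(), [0.5, 0.5, 0.5, 0.5, 3.0])

    def test_all_zero_feature_flagged_not_nan(self):
        X = np.zeros((5, 2))
        X[:, 1] = np.arange(1, 6)
        t = _table(X, np.zeros(5, int), np.arange(5))
        norm, flags = normalize_within_subject(t)
        assert np.all(norm.X[:, 0] == 0)
        assert flags[0, 0] and not flags[0, 1]
        assert np.isfinite(norm.X).all()

    def test_missing_state_cell_rejected(self):
        t = _table(np.zeros((3, 1)), [0, 0, 1], [0, 1, 0])
        with pytest.raises(ValueError, match="missing state"):
            normalize_within_subject(t)

    def test_transformer_form_matches(self, rng):
        X = rng.normal(size=(6, 4)) + 5.0
        subjects = np.repeat([0, 1], 3)
        states = np.tile(np.arange(3), 2)
        t = _table(X, subjects, states)
        norm, _ = normalize_within_subject(t)
        via_tf = WithinSubjectRatio(subjects=subjects, states=states).fit_transform(X)
        assert np.allclose(via_tf, norm.X)


class TestLosoFolds:
    def test_fifteen_subjects_fifteen_folds(self):
        folds = loso_folds(np.repeat(np.arange(15), 5))
        assert len(folds) == 15
        test_sets = [t for _, t in folds]
        assert sorted(test_sets) == list(range(15))
        for train, test in folds:
            assert test not in train
            assert len(train) == 14

    def test_two_subjects(self):
        assert len(loso_folds([0, 1])) == 2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_folds([7, 7, 7])


class TestFitPredict:
    def test_separable_clusters_perfect(self, separable_table):
        train = _table(separable_table.X[:15], separable_table.subjects[:15],
                       separable_table.states[:15])
        test = _table(separable_table.X[15:], separable_table.subjects[15:],
                      separable_table.states[15:])
        pred = fit_predict_multiclass(train, test, ClassifierConfig(), C=1.0)
        assert np.array_equal(pred, test.states)

    def test_knn_duplicate_training_point(self, rng):
        X = rng.normal(size=(9, 3))
        train = _table(X, np.repeat(np.arange(3), 3), np.tile(np.arange(3), 3))
        test = _table(X[[4]], [99], [train.states[4]])
        pred = fit_predict_multiclass(train, test, ClassifierConfig(kind="knn", k=1), C=1.0)
        assert pred[0] == train.states[4]

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="single class"):
            StateClassifier().fit(X, np.zeros(4))

    def test_deterministic(self, separable_table):
        a = fit_predict_multiclass(separable_table, separable_table, ClassifierConfig(), 1.0)
        b = fit_predict_multiclass(separable_table, separable_table, ClassifierConfig(), 1.0)
        assert np.array_equal(a, b)


class TestRunLoso:
    def test_separable_data_high_accuracy(self, separable_table):
        res = run_loso(separable_table, ClassifierConfig(), fixed_c=1.0, normalize=False)
        assert res.accuracy == 100.0
        assert accuracy_score(res) == res.accuracy

    def test_folds_partition_samples(self, separable_table):
        res = run_loso(separable_table, ClassifierConfig(), fixed_c=1.0, normalize=False)
        assert np.array_equal(np.sort(np.unique(res.fold_subjects)),
                              np.unique(separable_table.subjects))
        assert len(res.y_true) == separable_table.n_samples

    def test_selected_lambda_recorded_per_fold(self, rng):
        subjects = np.repeat(np.arange(4), 3)
        states = np.tile(np.arange(3), 4)
        tables = {
            lam: _table(rng.normal(size=(12, 5)) + 3, subjects, states)
            for lam in (0.1, 1.0)
        }
        res = run_loso(config=ClassifierConfig(), tables_by_lambda=tables, fixed_c=1.0)
        assert set(res.selected_lambda) == set(range(4))
        assert all(lam in (0.1, 1.0) for lam in res.selected_lambda.values())
        summary = res.lambda_summary()
        assert summary["min"] <= summary["mean"] <= summary["max"]

    def test_hyperparameters_never_touch_test_subject(self, rng):
        # corrupting one subject's features must not change the lambda/C
        # selected when that subject is held out
        subjects = np.repeat(np.arange(4), 3)
        states = np.tile(np.arange(3), 4)
        base = rng.normal(size=(12, 4)) + 3
        tables = {lam: _table(base * (1 + lam), subjects, states) for lam in (0.1, 1.0)}
        res1 = run_loso(config=ClassifierConfig(c_grid=(0.1, 10.0)), tables_by_lambda=tables)
        corrupted = {
            lam: _table(np.where((subjects == 0)[:, None],
                                 rng.normal(size=(12, 4)) * 50, t.X),
                        subjects, states)
            for lam, t in tables.items()
        }
        res2 = run_loso(config=ClassifierConfig(c_grid=(0.1, 10.0)), tables_by_lambda=corrupted)
        assert res1.selected_lambda[0] == res2.selected_lambda[0]
        assert res1.selected_c[0] == res2.selected_c[0]

    def test_determinism(self, separable_table):
        r1 = run_loso(separable_table, ClassifierConfig(), normalize=False)
        r2 = run_loso(separable_table, ClassifierConfig(), normalize=False)
        assert np.array_equal(r1.y_pred, r2.y_pred)
        assert r1.selected_c == r2.selected_c

    def test_max_mode_reports_best_c_over_grid(self, separable_table):
        res = run_loso(separable_table, ClassifierConfig(), select_c="max", normalize=False)
        assert res.mode == "max"
        assert res.accuracy == 100.0


class TestConcatenate:
    def test_self_concatenation_doubles_width(self, separable_table):
        out = concatenate_features([separable_table, separable_table])
        assert out.X.shape == (separable_table.n_samples, 4)
        assert np.array_equal(out.subjects, separable_table.subjects)

    def test_width_arithmetic_edges_plus_amplitude(self, rng):
        n = 4  # edges n(n-1)/2 = 6, amplitude n = 4
        subjects, states = np.repeat([0, 1], 2), np.tile([0, 1], 2)
        edges = _table(rng.normal(size=(4, 6)), subjects, states)
        amp = _table(rng.normal(size=(4, 4)), subjects, states)
        assert concatenate_features([edges, amp]).X.shape[1] == n * (n + 1) // 2

    def test_row_mismatch_rejected(self, rng):
        a = _table(rng.normal(size=(4, 2)), np.repeat([0, 1], 2), np.tile([0, 1], 2))
        b = _table(rng.normal(size=(4, 2)), np.repeat([2, 3], 2), np.tile([0, 1], 2))
        with pytest.raises(ValueError, match="mismatch"):
            concatenate_features([a, b])


class TestAccuracy:
    def test_values(self):
        from fcstates.discrimination import CVResult

        y = np.repeat(np.arange(5), 15)
        assert CVResult(y, y.copy(), np.zeros(75)).accuracy == 100.0
        wrong = y.copy()
        wrong[:30] = (wrong[:30] + 1) % 5  # 45 of 75 correct
        assert CVResult(y, wrong, np.zeros(75)).accuracy == 60.0
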