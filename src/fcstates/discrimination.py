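"""Brain-state discrimination with leave-one-subject-out cross-validation.

Features (vectorized netmats) are ratio-normalized within subject: each
feature is divided by that subject's mean of the same feature across its
states.  Because the normalization uses only a subject's own scans, and each
LOSO fold holds out whole subjects, it is leakage-free by construction.

The classifier is a multiclass linear soft-margin SVM (one-vs-one reduction,
the native multiclass scheme of libsvm) or, optionally, k-nearest neighbours.
The soft-margin parameter C is searched over eight log-spaced values in
[0.001, 1000]; when ridge partial-correlation features are used, the
regularization lambda is selected jointly with C by a nested LOSO loop inside
each training fold (tie-breaks: smallest lambda, largest C).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

#: iteration cap for the libsvm solver; converged fits use a few hundred
#: iterations, the cap only bounds run time on degenerate feature scalings
_SVM_MAX_ITER = 100_000

DEFAULT_C_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 8))


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier family and hyperparameter grids."""

    kind: str = "linear_svm"  # {"linear_svm", "knn"}
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    k: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("linear_svm", "knn"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        grid = tuple(float(c) for c in self.c_grid)
        if any(c <= 0 for c in grid) or list(grid) != sorted(grid):
            raise ValueError("C grid must be positive and sorted ascending")
        object.__setattr__(self, "c_grid", grid)
        if self.k < 1:
            raise ValueError("k must be a positive integer")


@dataclass
class FeatureTable:
    """Samples-by-features matrix with subject and state labels."""

    X: np.ndarray
    subjects: np.ndarray
    states: np.ndarray
    feature_names: tuple[str, ...] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.subjects = np.asarray(self.subjects)
        self.states = np.asarray(self.states)
        if not (len(self.X) == len(self.subjects) == len(self.states)):
            raise ValueError("X, subjects and states must have equal length")
        if np.isnan(self.X).any():
            raise ValueError("features contain missing values")
        seen = set()
        for key in zip(self.subjects.tolist(), self.states.tolist()):
            if key in seen:
                raise ValueError(f"duplicate (subject, state) row {key}")
            seen.add(key)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    def rows_for(self, subjects: Sequence) -> np.ndarray:
        mask = np.isin(self.subjects, np.asarray(list(subjects)))
        return np.flatnonzero(mask)

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or tuple(f"f{i}" for i in range(self.X.shape[1]))
        df = pd.DataFrame(self.X, columns=list(names))
        df.insert(0, "state", self.states)
        df.insert(0, "subject", self.subjects)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        feats = [c for c in df.columns if c not in ("subject", "state")]
        return cls(
            df[feats].to_numpy(float),
            df["subject"].to_numpy(),
            df["state"].to_numpy(),
            feature_names=tuple(feats),
        )


def normalize_within_subject(table: FeatureTable) -> tuple[FeatureTable, np.ndarray]:
    """Ratio normalization: divide by the subject's across-state feature mean.

    Every subject must have every state.  Features whose within-subject mean
    is (near-)zero (|mean| < 1e-12 x the feature's overall scale) are set to 0
    for that subject and flagged; the returned flag matrix is
    (n_subjects, n_features) over sorted subject order.
    """
    subjects = np.unique(table.subjects)
    states = np.unique(table.states)
    for s in subjects:
        have = set(table.states[table.subjects == s].tolist())
        missing = set(states.tolist()) - have
        if missing:
            raise ValueError(f"subject {s} is missing state(s) {sorted(missing)}")
    scale = np.mean(np.abs(table.X), axis=0)
    scale[scale == 0] = 1.0
    eps = 1e-12 * scale
    out = np.empty_like(table.X)
    flags = np.zeros((subjects.size, table.X.shape[1]), dtype=bool)
    for si, s in enumerate(subjects):
        rows = table.subjects == s
        mean = table.X[rows].mean(axis=0)
        bad = np.abs(mean) < eps
        flags[si] = bad
        safe = np.where(bad, 1.0, mean)
        vals = table.X[rows] / safe
        vals[:, bad] = 0.0
        out[rows] = vals
    norm = FeatureTable(out, table.subjects, table.states, table.feature_names,
                        dict(table.provenance, normalized="within_subject_ratio"))
    return norm, flags


class WithinSubjectRatio(BaseEstimator, TransformerMixin):
    """Transformer form of the within-subject ratio normalization.

    Needs the subject id of every row (constructor argument, aligned with X).
    Stateless across subjects, hence leakage-free under subject-wise CV.
    """

    def __init__(self, subjects: Sequence | None = None, states: Sequence | None = None):
        self.subjects = subjects
        self.states = states

    def fit(self, X, y=None):
        if self.subjects is None:
            raise ValueError("subjects must be provided")
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        states = self.states if self.states is not None else np.arange(len(X))
        table = FeatureTable(X, np.asarray(list(self.subjects)), np.asarray(list(states)))
        norm, _ = normalize_within_subject(table)
        return norm.X


def loso_folds(subject_ids: Sequence) -> list[tuple[np.ndarray, object]]:
    """One (train_subjects, test_subject) fold per unique subject."""
    subjects = np.unique(np.asarray(list(subject_ids)))
    if subjects.size < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [(subjects[subjects != s], s) for s in subjects]


class StateClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass linear SVM (one-vs-one) or k-NN over feature vectors.

    Thin sklearn-compatible wrapper fixing the conventions used throughout:
    linear kernel, one-vs-one voting with ties broken by aggregate decision
    values (libsvm's scheme), deterministic fits.
    """

    def __init__(self, kind: str = "linear_svm", C: float = 1.0, k: int = 3):
        self.kind = kind
        self.C = C
        self.k = k

    def fit(self, X, y):
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training data contains a single class")
        if self.kind == "linear_svm":
            self.model_ = SVC(kernel="linear", C=self.C, max_iter=_SVM_MAX_ITER)
        elif self.kind == "knn":
            self.model_ = KNeighborsClassifier(n_neighbors=self.k)
        else:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.model_.fit(np.asarray(X, float), y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, float))


def fit_predict_multiclass(
    train: FeatureTable,
    test: FeatureTable,
    config: ClassifierConfig,
    C: float = 1.0,
) -> np.ndarray:
    """Fit on the training table, predict state labels of the test table."""
    clf = StateClassifier(kind=config.kind, C=C, k=config.k)
    clf.fit(train.X, train.states)
    return clf.predict(test.X)


@dataclass
class CVResult:
    """Per-sample LOSO predictions plus selected hyperparameters."""

    y_true: np.ndarray
    y_pred: np.ndarray
    fold_subjects: np.ndarray  # held-out subject of each sample
    selected_lambda: dict = field(default_factory=dict)  # fold subject -> lambda
    selected_c: dict = field(default_factory=dict)  # fold subject -> C
    mode: str = "inner"

    @property
    def correct(self) -> np.ndarray:
        return np.asarray(self.y_true) == np.asarray(self.y_pred)

    @property
    def accuracy(self) -> float:
        return 100.0 * float(self.correct.mean())

    def lambda_summary(self) -> dict:
        """Mean and range of the per-fold selected lambda (Table-1 style)."""
        vals = np.array([v for v in self.selected_lambda.values() if v is not None])
        if vals.size == 0:
            return {"mean": None, "min": None, "max": None}
        return {"mean": float(vals.mean()), "min": float(vals.min()), "max": float(vals.max())}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.fold_subjects,
            "true_state": self.y_true,
            "predicted_state": self.y_pred,
            "correct": self.correct,
        })


def accuracy_score(result: CVResult) -> float:
    """Percent correct over all samples."""
    return result.accuracy


def _fit_predict_arrays(X_tr, y_tr, X_te, config: ClassifierConfig, C: float) -> np.ndarray:
    if config.kind == "linear_svm":
        model = SVC(kernel="linear", C=C, max_iter=_SVM_MAX_ITER)
    else:
        model = KNeighborsClassifier(n_neighbors=config.k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X_tr, y_tr)
    return model.predict(X_te)


def _inner_accuracy(
    X: np.ndarray,
    states: np.ndarray,
    rows_of: Mapping,
    train_subjects: np.ndarray,
    config: ClassifierConfig,
    C: float,
) -> float:
    """Pooled LOSO accuracy inside a training fold (never sees the test subject)."""
    correct = 0
    total = 0
    for held_out in train_subjects:
        tr = np.concatenate([rows_of[s] for s in train_subjects if s != held_out])
        te = rows_of[held_out]
        pred = _fit_predict_arrays(X[tr], states[tr], X[te], config, C)
        correct += int(np.sum(pred == states[te]))
        total += te.size
    return correct / total


def _subset(table: FeatureTable, rows: np.ndarray) -> FeatureTable:
    return FeatureTable(table.X[rows], table.subjects[rows], table.states[rows],
                        table.feature_names, table.provenance)


def run_loso(
    table: FeatureTable | None = None,
    config: ClassifierConfig = ClassifierConfig(),
    *,
    tables_by_lambda: Mapping[float, FeatureTable] | None = None,
    select_c: str = "inner",
    fixed_c: float | None = None,
    normalize: bool = True,
) -> CVResult:
    """Leave-one-subject-out classification with nested hyperparameter selection.

    Parameters
    ----------
    table : FeatureTable
        Features at a fixed configuration (ignored when ``tables_by_lambda``
        is given).
    tables_by_lambda : mapping lambda -> FeatureTable, optional
        Ridge partial-correlation features recomputed per lambda; activates
        nested lambda selection: within every training fold an inner LOSO
        evaluates each (lambda, C) pair and the maximizer is used on the
        held-out subject (ties: smallest lambda, then largest C).
    select_c : {"inner", "max"}
        "inner": C chosen by the inner loop (honest, default).  "max": report
        the accuracy maximized over the C grid on the held-out data — the more
        optimistic convention some studies report; exposed for replication.
    fixed_c : float, optional
        Skip C selection entirely and use this value.
    normalize : bool
        Apply within-subject ratio normalization first (default).
    """
    nested = tables_by_lambda is not None
    if nested:
        lambdas = sorted(tables_by_lambda)
        tables = {}
        for lam in lambdas:
            t = tables_by_lambda[lam]
            tables[lam] = normalize_within_subject(t)[0] if normalize else t
        base = tables[lambdas[0]]
    else:
        if table is None:
            raise ValueError("provide a FeatureTable or tables_by_lambda")
        base = normalize_within_subject(table)[0] if normalize else table
        tables = {None: base}
        lambdas = [None]

    c_values = [fixed_c] if fixed_c is not None else list(config.c_grid)
    folds = loso_folds(base.subjects)
    rows_of = {s: np.flatnonzero(base.subjects == s) for s in np.unique(base.subjects)}
    states = base.states
    X_of = {lam: tables[lam].X for lam in lambdas}

    y_true = np.empty(base.n_samples, dtype=base.states.dtype)
    y_pred = np.empty(base.n_samples, dtype=base.states.dtype)
    fold_of = np.empty(base.n_samples, dtype=base.subjects.dtype)
    sel_lambda: dict = {}
    sel_c: dict = {}

    if select_c == "max" and len(c_values) > 1:
        per_c_pred = {C: np.empty(base.n_samples, dtype=base.states.dtype) for C in c_values}
        for train_subjects, test_subject in folds:
            te = rows_of[test_subject]
            lam = lambdas[0]
            if nested:
                lam = _select_lambda_only(X_of, states, rows_of, lambdas, train_subjects,
                                          config, c_values)
            X = X_of[lam]
            tr = np.concatenate([rows_of[s] for s in train_subjects])
            for C in c_values:
                per_c_pred[C][te] = _fit_predict_arrays(X[tr], states[tr], X[te], config, C)
            y_true[te] = states[te]
            fold_of[te] = test_subject
            sel_lambda[test_subject] = lam
        accs = {C: np.mean(per_c_pred[C] == y_true) for C in c_values}
        best_c = max(c_values, key=lambda C: (accs[C], C))
        y_pred = per_c_pred[best_c]
        sel_c = {s: best_c for _, s in folds}
        return CVResult(y_true, y_pred, fold_of, sel_lambda, sel_c, mode="max")

    for train_subjects, test_subject in folds:
        best = None  # key = (inner acc, -lambda rank, C): smallest-lambda / largest-C ties
        if len(lambdas) > 1 or len(c_values) > 1:
            for li, lam in enumerate(lambdas):
                for C in c_values:
                    acc = _inner_accuracy(X_of[lam], states, rows_of, train_subjects, config, C)
                    key = (acc, -li, C)
                    if best is None or key > best[0]:
                        best = (key, lam, C)
            lam_star, c_star = best[1], best[2]
        else:
            lam_star, c_star = lambdas[0], c_values[0]
        X = X_of[lam_star]
        tr = np.concatenate([rows_of[s] for s in train_subjects])
        te = rows_of[test_subject]
        pred = _fit_predict_arrays(X[tr], states[tr], X[te], config, c_star)
        y_true[te] = states[te]
        y_pred[te] = pred
        fold_of[te] = test_subject
        sel_lambda[test_subject] = lam_star
        sel_c[test_subject] = c_star
    return CVResult(y_true, y_pred, fold_of, sel_lambda, sel_c, mode="inner")


def _select_lambda_only(X_of, states, rows_of, lambdas, train_subjects, config, c_values):
    best = None
    for li, lam in enumerate(lambdas):
        acc = max(
            _inner_accuracy(X_of[lam], states, rows_of, train_subjects, config, C)
            for C in c_values
        )
        key = (acc, -li)
        if best is None or key > best[0]:
            best = (key, lam)
    return best[1]


def concatenate_features(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Column-wise concatenation of feature tables over identical row sets."""
    if not tables:
        raise ValueError("no tables to concatenate")
    first = tables[0]
    key = list(zip(first.subjects.tolist(), first.states.tolist()))
    for t in tables[1:]:
        if list(zip(t.subjects.tolist(), t.states.tolist())) != key:
            raise ValueError("tables have mismatching (subject, state) rows")
    names: list[str] = []
    for ti, t in enumerate(tables):
        base = t.feature_names or tuple(f"f{i}" for i in range(t.X.shape[1]))
        names.extend(f"t{ti}_{n}" for n in base)
    return FeatureTable(
        np.hstack([t.X for t in tables]),
        first.subjects,
        first.states,
        feature_names=tuple(names),
        provenance={"concatenated": [t.provenance for t in tables]},
    )


def permuted_chance_accuracy(
    table: FeatureTable,
    config: ClassifierConfig = ClassifierConfig(),
    n_permutations: int = 200,
    seed: int = 0,
    C: float = 1.0,
) -> np.ndarray:
    """LOSO accuracies under within-subject permutation of the state labels.

    Breaks any feature-state association while preserving the balanced design,
    giving the empirical chance distribution (expected mean 1/n_states).
    C is held fixed: no hyperparameter search is meaningful under the null.
    """
    rng = np.random.default_rng(seed)
    norm, _ = normalize_within_subject(table)
    subjects = np.unique(norm.subjects)
    accs = np.empty(n_permutations)
    for p in range(n_permutations):
        states = norm.states.copy()
        for s in subjects:
            rows = np.flatnonzero(norm.subjects == s)
            states[rows] = states[rng.permutation(rows)]
        shuffled = FeatureTable(norm.X, norm.subjects, states, norm.feature_names)
        res = run_loso(shuffled, config, fixed_c=C, normalize=False)
        accs[p] = res.accuracy
    return accs
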