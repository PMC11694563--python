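"""Predict removal clusters from molecular descriptors under 5-fold CV.

Features are the six Abraham solvation descriptors (E, S, A, B, V, L)
plus log Kow; labels come from a removal-based clustering (C1 or C2).
Three classifiers are compared — support vector machine, random forest,
logistic regression — with their configurations pinned explicitly so
"default hyperparameters" is a frozen, reproducible statement. Accuracy
per held-out fold is the reported metric; a random forest trained on all
data supplies impurity-decrease feature importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ClusterAssignment, DescriptorTable, DESCRIPTOR_COLUMNS

#: pinned classifier configurations ("defaults", made explicit)
MODEL_CONFIGS: dict[str, dict] = {
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "RF": {"n_estimators": 100, "criterion": "gini", "bootstrap": True},
    # ridge (l2) penalty is the solver default; C pins its weight
    "LR": {"C": 1.0, "solver": "lbfgs", "max_iter": 1000},
}


def _make_model(model: str, seed: int | None):
    if model == "SVM":
        return SVC(random_state=seed, **MODEL_CONFIGS["SVM"])
    if model == "RF":
        return RandomForestClassifier(random_state=seed, **MODEL_CONFIGS["RF"])
    if model == "LR":
        return LogisticRegression(random_state=seed, **MODEL_CONFIGS["LR"])
    raise ValueError(f"unknown model {model!r}; expected SVM, RF or LR")


def build_feature_matrix(
    descriptors: DescriptorTable, assignment: ClusterAssignment
) -> tuple[np.ndarray, np.ndarray, list[str], tuple[str, ...]]:
    """Align descriptors with cluster labels into (X, y).

    Rows are ordered by sorted compound id; columns follow the canonical
    descriptor order (log Kow last). Labeled compounds without a complete
    descriptor row are dropped and reported.

    Returns ``(X, y, compound_ids, dropped)``.
    """
    labeled = set(assignment.labels)
    have = set(descriptors.compounds)
    kept = sorted(labeled & have)
    dropped = tuple(sorted(labeled - have))
    if not kept:
        raise ValueError("no labeled compound has a descriptor row")
    X = descriptors.data.loc[kept, list(DESCRIPTOR_COLUMNS)].to_numpy(dtype=float)
    y = np.array([assignment.labels[c] for c in kept])
    if len(np.unique(y)) < 2:
        raise ValueError("fewer than 2 distinct labels after dropping")
    return X, y, kept, dropped


def make_folds(n: int, k: int, seed: int | None) -> list[np.ndarray]:
    """Seeded shuffled split of ``range(n)`` into k folds of near-equal size."""
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if n < k:
        raise ValueError(f"cannot split n={n} samples into k={k} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def _stratified_folds(y: np.ndarray, k: int, seed: int | None) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset += len(idx)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class CVReport:
    """Cross-validation outcome for one classifier."""

    model: str
    per_fold_accuracy: list[float]
    fold_indices: list[np.ndarray]
    seed: int | None
    invalid_folds: list[int] = field(default_factory=list)
    per_class_recall: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "per_fold_accuracy": [round(a, 12) for a in self.per_fold_accuracy],
            "mean_accuracy": round(self.mean_accuracy, 12),
            "fold_sizes": [len(f) for f in self.fold_indices],
            "invalid_folds": self.invalid_folds,
            "hyperparameters": MODEL_CONFIGS[self.model],
            "seed": self.seed,
        }


def crossval_classify(
    X: np.ndarray,
    y: np.ndarray,
    model: str = "RF",
    k_folds: int = 5,
    seed: int | None = 0,
    standardize: bool = False,
    stratify: bool = False,
) -> CVReport:
    """k-fold cross-validated accuracy for one pinned classifier.

    Folds are seeded shuffled splits of near-equal size (stratified
    splits on request). A fold whose training half degenerates to a
    single class is marked invalid and excluded from the mean with a
    warning. ``standardize`` z-scores features using training-fold
    statistics only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            warnings.warn(
                f"class {cls!r} has a single member; it may be missing from "
                "some training splits", stacklevel=2,
            )
    folds = (_stratified_folds(y, k_folds, seed) if stratify
             else make_folds(len(y), k_folds, seed))

    accs: list[float] = []
    invalid: list[int] = []
    recall: dict = {c: [0, 0] for c in classes}
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {i}: training split has a single class; "
                          "fold excluded", stacklevel=2)
            invalid.append(i)
            continue
        X_tr, X_te = X[train_idx], X[test_idx]
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        clf = _make_model(model, seed)
        clf.fit(X_tr, y_tr)
        pred = clf.predict(X_te)
        accs.append(float(np.mean(pred == y[test_idx])))
        for t, p in zip(y[test_idx], pred):
            recall[t][1] += 1
            recall[t][0] += int(t == p)
    if not accs:
        raise ValueError("every fold was degenerate; cannot report accuracy")
    per_class = {
        str(c): (hits / total if total else None) for c, (hits, total) in recall.items()
    }
    return CVReport(
        model=model,
        per_fold_accuracy=accs,
        fold_indices=folds,
        seed=seed,
        invalid_folds=invalid,
        per_class_recall=per_class,
    )


@dataclass
class ImportanceReport:
    """Normalised impurity-decrease feature importances, ranked."""

    ranking: list[tuple[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"feature": f, "weight": w, "rank": i + 1}
                for i, (f, w) in enumerate(self.ranking)
            ]
        )

    @property
    def weights(self) -> dict[str, float]:
        return dict(self.ranking)

    @property
    def top_feature(self) -> str:
        return self.ranking[0][0]


def rf_feature_importance(
    X: np.ndarray, y: np.ndarray, seed: int | None = 0
) -> ImportanceReport:
    """Gini importance of each descriptor from a forest fit on all data."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(DESCRIPTOR_COLUMNS):
        raise ValueError(
            f"expected {len(DESCRIPTOR_COLUMNS)} feature columns, got {X.shape[1]}"
        )
    forest = RandomForestClassifier(random_state=seed, **MODEL_CONFIGS["RF"])
    forest.fit(X, np.asarray(y))
    imp = forest.feature_importances_.astype(float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    order = np.argsort(-imp, kind="stable")
    return ImportanceReport(
        ranking=[(DESCRIPTOR_COLUMNS[i], float(imp[i])) for i in order]
    )
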