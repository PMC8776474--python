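"""Incremental feature selection (IFS) under cross-validation.

Growing prefixes of an mRMR-ranked feature list are evaluated with a
classifier under seeded stratified k-fold cross-validation; confusion
counts are pooled over all test folds (each sample predicted exactly
once) before metric computation, and the optimum prefix is the one
maximizing MCC, with ties broken to the smallest prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .encode import FeatureMatrix
from .errors import ValidationError
from .metrics import ConfusionCounts, MetricSet, compute_metrics
from .mrmr import RankedList

FAMILIES = ("decision_tree", "knn", "random_forest", "svm")

# declared defaults, overridable via ClassifierSpec.hyperparameters
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "decision_tree": {"criterion": "gini"},
    "knn": {"n_neighbors": 5},
    "random_forest": {"n_estimators": 100},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
}

# distance- and margin-based families get per-fold standardization
_SCALED_FAMILIES = {"knn", "svm"}


@dataclass
class ClassifierSpec:
    """One classifier family plus its (fully explicit) hyperparameters."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    def build(self, seed: int):
        """A fresh (unfitted) estimator; stochastic families derive their
        internal seed from ``seed`` so runs are reproducible."""
        hp = self.hyperparameters
        if self.family == "decision_tree":
            est = DecisionTreeClassifier(random_state=seed, **hp)
        elif self.family == "knn":
            est = KNeighborsClassifier(**hp)
        elif self.family == "random_forest":
            est = RandomForestClassifier(random_state=seed, **hp)
        else:
            est = SVC(random_state=seed, **hp)
        if self.family in _SCALED_FAMILIES:
            return Pipeline([("scale", StandardScaler()), ("clf", est)])
        return est


@dataclass
class CVConfig:
    """Cross-validation settings: seeded stratified folds, pooled confusion.

    Stratification needs at least one member of each class per test fold;
    when ``n_folds`` exceeds the minority class count (e.g., leave-one-out
    on a balanced set), seeded unstratified folds are used instead, which
    is valid as long as every training fold still contains both classes.
    """

    n_folds: int = 10
    stratified: bool = True
    seed: int = 1

    def splitter(self, min_class_count: int):
        if self.stratified and self.n_folds <= min_class_count:
            return StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.seed
            )
        return KFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)


def cross_validate(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    cv: CVConfig,
    feature_indices: list[int] | None = None,
) -> ConfusionCounts:
    """Pooled confusion counts over a seeded stratified k-fold run.

    ``feature_indices`` restricts the matrix to a subset of 1-based
    feature indices (in the given order).  A fresh model is fitted per
    fold; every sample is predicted exactly once, in its test fold.
    """
    y = matrix.y
    if np.unique(y).size < 2:
        raise ValidationError("both classes must be present")
    if not 2 <= cv.n_folds <= matrix.n_samples:
        raise ValueError(
            f"n_folds={cv.n_folds} outside [2, n_samples={matrix.n_samples}]"
        )
    counts = np.bincount((y > 0).astype(int), minlength=2)
    X = matrix.values
    if feature_indices is not None:
        X = X[:, [i - 1 for i in feature_indices]]

    tp = tn = fp = fn = 0
    for train_idx, test_idx in cv.splitter(int(counts.min())).split(X, y):
        if np.unique(y[train_idx]).size < 2:
            raise ValidationError("a training fold lost one class entirely")
        model = spec.build(seed=cv.seed)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        truth = y[test_idx]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        tn += int(np.sum((pred == -1) & (truth == -1)))
        fp += int(np.sum((pred == 1) & (truth == -1)))
        fn += int(np.sum((pred == -1) & (truth == 1)))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


@dataclass
class IFSResult:
    """Per-prefix-size metrics plus the MCC-optimal prefix.

    ``rows`` covers prefix sizes 1…N in ascending order; ``optimum_size``
    attains the maximum MCC, ties broken to the smallest size.
    ``metadata`` echoes the classifier family, hyperparameters, and CV
    settings that produced the table.
    """

    rows: list[tuple[int, MetricSet]]
    optimum_size: int
    optimum_metrics: MetricSet
    metadata: dict[str, Any] = field(default_factory=dict)


def run_ifs(
    matrix: FeatureMatrix,
    ranked: RankedList,
    spec: ClassifierSpec,
    cv: CVConfig,
    max_size: int | None = None,
) -> IFSResult:
    """Evaluate classifiers on growing prefixes of the ranked list.

    For each prefix size s = 1…``max_size`` (default: the whole list) the
    top-s features are cross-validated and the pooled-confusion metrics
    recorded.  The full per-size table is always emitted, not only the
    optimum row.
    """
    valid = set(range(1, matrix.n_features + 1))
    if not set(ranked.order) <= valid:
        raise ValidationError("ranked list refers to features absent from the matrix")
    if max_size is None:
        max_size = len(ranked.order)
    if not 1 <= max_size <= len(ranked.order):
        raise ValueError(f"max_size={max_size} outside [1, {len(ranked.order)}]")

    rows: list[tuple[int, MetricSet]] = []
    best_size, best_metrics = None, None
    for s in range(1, max_size + 1):
        counts = cross_validate(matrix, spec, cv, feature_indices=ranked.top(s))
        ms = compute_metrics(counts)
        rows.append((s, ms))
        if best_metrics is None or ms.MCC > best_metrics.MCC:  # strict: ties -> smallest s
            best_size, best_metrics = s, ms
    assert best_size is not None and best_metrics is not None
    return IFSResult(
        rows=rows,
        optimum_size=best_size,
        optimum_metrics=best_metrics,
        metadata={
            "classifier": spec.family,
            "hyperparameters": dict(spec.hyperparameters),
            "n_folds": cv.n_folds,
            "stratified": cv.stratified,
            "seed": cv.seed,
            "standardized": spec.family in _SCALED_FAMILIES,
        },
    )


def write_ifs(result: IFSResult, path: str | Path, header: str | None = None) -> None:
    """TSV mirroring the report layout: classifier, n_features, SN, SP,
    ACC, MCC, precision, F1 — one row per prefix size (3-dp rounding)."""
    name = result.metadata.get("classifier", "?")
    rows = []
    for s, ms in result.rows:
        r = ms.rounded()
        rows.append(
            {
                "classifier": name,
                "n_features": s,
                "SN": f"{r.SN:.3f}",
                "SP": f"{r.SP:.3f}",
                "ACC": f"{r.ACC:.3f}",
                "MCC": f"{r.MCC:.3f}",
                "precision": f"{r.precision:.3f}",
                "F1": f"{r.F1:.3f}",
            }
        )
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f"# optimum n_features={result.optimum_size} "
                 f"MCC={result.optimum_metrics.MCC:.3f}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
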