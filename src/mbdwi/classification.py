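"""Four-classifier benign/malignant benchmark on radiomics features.

The benchmark compares, per parameter map, four scorers trained on the same
stratified half of the cohort:

* RF      — random forest (100 trees, depth 3), raw features (trees are
            scale-invariant),
* L1R-LR  — L1-regularized linear (logistic) model on standardized
            features: the penalty performs implicit feature selection,
* PCA-LR  — rank-test prefilter to the 100 lowest-P features, 10 principal
            components, linear model, all refit on training data only,
* SVM-RBF — RBF-kernel support vector machine, C/gamma grid-searched on the
            training set.

Every classifier yields a continuous malignancy score (probability or
decision margin) so downstream ROC analysis is paired by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_KINDS",
    "CohortSplit",
    "ClassifierSpec",
    "CVResult",
    "stratified_split",
    "build_estimator",
    "train_classifier",
    "predict_scores",
    "repeated_cv",
    "feature_importance",
]

CLASSIFIER_KINDS = ("rf", "l1r", "pca", "svm")

#: pinned SVM grid (searched on training folds only).
SVM_GRID = {"svc__C": [0.1, 1.0, 10.0, 100.0],
            "svc__gamma": ["scale", 0.01, 0.001]}


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint stratified train/test partition of subject ids."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclass(frozen=True)
class ClassifierSpec:
    """One benchmark entry: classifier kind, hyperparameters, seed.

    Hyperparameters are recorded verbatim in outputs; defaults are
    RF(trees=100, max_depth=3), L1R(C=1.0), PCA(prefilter=100 features,
    components=10), SVM(RBF, grid-searched C/gamma).
    """

    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")


def stratified_split(labels: pd.Series, fraction: float = 0.5,
                     seed: int = 0) -> CohortSplit:
    """Stratified train/test split of labeled subject ids.

    The class ratio in each half matches the whole cohort to integer
    rounding; a 542-subject cohort at fraction 0.5 yields a 271-subject
    training set.  Deterministic for a fixed seed.
    """
    labels = pd.Series(labels)
    counts = labels.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least two subjects of each class")
    train_ids, test_ids = train_test_split(
        labels.index.to_numpy(), train_size=fraction,
        stratify=labels.to_numpy(), random_state=seed,
    )
    return CohortSplit(tuple(train_ids), tuple(test_ids), seed)


class RankSumPrefilter(BaseEstimator, TransformerMixin):
    """Keep the k features with the lowest two-sample rank-test P values.

    The Mann-Whitney U test is computed per feature on the training data
    only (fit), so no information leaks from validation folds.
    """

    def __init__(self, k: int = 100):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        pos, neg = X[y == 1], X[y == 0]
        pvals = np.ones(X.shape[1])
        for j in range(X.shape[1]):
            if np.ptp(X[:, j]) > 0:
                pvals[j] = mannwhitneyu(
                    pos[:, j], neg[:, j], alternative="two-sided"
                ).pvalue
        k = min(self.k, X.shape[1])
        self.support_ = np.sort(np.argsort(pvals, kind="stable")[:k])
        self.pvalues_ = pvals
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]


def build_estimator(spec: ClassifierSpec):
    """Instantiate the (unfitted) scikit-learn pipeline for one spec."""
    p = spec.params
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth", 3),
            random_state=spec.seed,
        )
    if spec.kind == "l1r":
        return Pipeline([
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(
                l1_ratio=1.0, solver="liblinear",
                C=p.get("C", 1.0), max_iter=2000,
                random_state=spec.seed)),
        ])
    if spec.kind == "pca":
        return Pipeline([
            ("scale", StandardScaler()),
            ("prefilter", RankSumPrefilter(k=p.get("prefilter", 100))),
            ("pca", PCA(n_components=p.get("components", 10),
                        random_state=spec.seed)),
            ("lr", LogisticRegression(C=np.inf, max_iter=2000)),
        ])
    if spec.kind == "svm":
        base = Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", random_state=spec.seed)),
        ])
        return GridSearchCV(
            base, p.get("grid", SVM_GRID),
            cv=StratifiedKFold(3, shuffle=True, random_state=spec.seed),
            scoring="roc_auc", n_jobs=None,
        )
    raise ValueError(spec.kind)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return (y == "malignant").astype(int)
    return y.astype(int)


def train_classifier(spec: ClassifierSpec, features, labels):
    """Fit one classifier on training features/labels only."""
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if np.isnan(X).any():
        raise ValueError("features contain missing values")
    model = build_estimator(spec)
    model.fit(X, y)
    return model


def predict_scores(model, features) -> np.ndarray:
    """Continuous malignancy score per subject (probability or margin)."""
    X = np.asarray(features, dtype=float)
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)[:, 1]
        except AttributeError:  # e.g. SVC without probability
            pass
    return model.decision_function(X)


@dataclass
class CVResult:
    """Bookkeeping of a repeated stratified k-fold CV run."""

    spec: ClassifierSpec
    k: int
    repeats: int
    seed: int
    fold_scores: np.ndarray  # (repeats, k) validation AUCs
    selected_features: list[list[np.ndarray]]  # per repeat, per fold

    def selection_frequency(self, n_features: int) -> np.ndarray:
        """How often each feature was kept, over all repeats x folds."""
        freq = np.zeros(n_features)
        total = 0
        for rep in self.selected_features:
            for sel in rep:
                freq[sel] += 1
                total += 1
        return freq / max(total, 1)


def _selected_of(model) -> np.ndarray | None:
    """Indices of features the fitted model effectively uses, if sparse."""
    if isinstance(model, Pipeline):
        if "prefilter" in model.named_steps:
            return model.named_steps["prefilter"].support_
        if "lr" in model.named_steps:
            coef = model.named_steps["lr"].coef_.ravel()
            return np.flatnonzero(coef != 0)
    return None


def repeated_cv(spec: ClassifierSpec, features, labels, k: int = 10,
                repeats: int = 100, seed: int = 0) -> CVResult:
    """Repeated stratified k-fold cross-validation on the training half.

    Fold assignment is reshuffled every repeat; all preprocessing
    (standardization, prefilter, PCA, SVM grid search) is refit inside each
    training fold.  Returns per-fold validation AUCs and the per-fold
    selected-feature sets for stability reporting.
    """
    from .evaluation import roc_auc

    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    if k > len(y):
        raise ValueError("k must not exceed the number of subjects")
    scores = np.zeros((repeats, k))
    selected: list[list[np.ndarray]] = []
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        folds = StratifiedKFold(k, shuffle=True, random_state=rep_seed)
        rep_sel: list[np.ndarray] = []
        for fold, (tr, va) in enumerate(folds.split(X, y)):
            model = train_classifier(
                ClassifierSpec(spec.kind, seed=rep_seed, params=spec.params),
                X[tr], y[tr])
            s = predict_scores(model, X[va])
            if len(np.unique(y[va])) == 2:
                scores[rep, fold] = roc_auc(s, y[va])
            else:  # leave-one-out-like degenerate fold
                scores[rep, fold] = np.nan
            sel = _selected_of(model)
            rep_sel.append(sel if sel is not None
                           else np.arange(X.shape[1]))
        selected.append(rep_sel)
    return CVResult(spec, k, repeats, seed, scores, selected)


def feature_importance(model, feature_names: Sequence[str]) -> pd.Series:
    """Mean-decrease-in-impurity importances of a fitted random forest.

    Returned sorted descending; they are non-negative and sum to 1.
    """
    if not isinstance(model, RandomForestClassifier):
        raise TypeError("feature importance is defined for the RF model only")
    imp = pd.Series(model.feature_importances_, index=list(feature_names))
    return imp.sort_values(ascending=False)
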