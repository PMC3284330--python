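"""Random-forest contract shared by the per-term (GBP) and per-pair (GBA)
classifiers: 100 bootstrap-aggregated trees, out-of-bag vote fractions for
training objects, and per-feature variable importance."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance


@dataclass
class ForestModel:
    """Fitted ensemble with OOB scores for its training objects."""

    clf: RandomForestClassifier
    feature_names: list[str]
    oob_score: np.ndarray  # per training object, vote fraction in [0,1]
    n_trees: int
    seed: int
    _train_shape: tuple[int, int] = field(default=(0, 0))


def train_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    feature_names: list[str] | None = None,
    max_features: str | float = "sqrt",
) -> ForestModel:
    """Fit a Breiman random forest and return OOB vote fractions.

    Trees are grown to purity on bootstrap samples with sqrt(p) candidate
    features per split (Gini). A training object's OOB score is the fraction
    of positive votes among trees whose bootstrap sample excluded it — an
    internal cross-validation estimate. The rare object that is in-bag for
    every tree falls back to its in-bag vote fraction.

    Raises ``ValueError`` when *y* contains a single class.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"training labels contain a single class ({classes.tolist()}); "
            "both positive and negative examples are required"
        )
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # few trees can leave some objects never out-of-bag; handled below
        warnings.simplefilter("ignore", UserWarning)
        clf.fit(X, y)
    oob = clf.oob_decision_function_[:, list(clf.classes_).index(1)]
    missing = np.isnan(oob)
    if missing.any():
        oob = oob.copy()
        oob[missing] = clf.predict_proba(X[missing])[:, list(clf.classes_).index(1)]
    names = feature_names if feature_names is not None else [
        f"f{j}" for j in range(X.shape[1])
    ]
    return ForestModel(clf, list(names), oob, n_trees, seed, X.shape)


def predict(model: ForestModel, X_new: np.ndarray) -> np.ndarray:
    """Fraction of trees voting positive for each new object."""
    X_new = np.asarray(X_new)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    pos = list(model.clf.classes_).index(1)
    return model.clf.predict_proba(X_new)[:, pos]


def variable_importance(
    model: ForestModel,
    method: str = "impurity",
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Per-feature contribution, sorted descending.

    Default is mean impurity decrease; ``method='permutation'`` recomputes
    importance by shuffling each column (requires X, y).
    """
    if method == "impurity":
        imp = model.clf.feature_importances_
    elif method == "permutation":
        if X is None or y is None:
            raise ValueError("permutation importance requires X and y")
        res = permutation_importance(
            model.clf, np.asarray(X), np.asarray(y), n_repeats=n_repeats,
            random_state=seed,
        )
        imp = res.importances_mean
    else:
        raise ValueError(f"unknown importance method {method!r}")
    ranked = sorted(zip(model.feature_names, imp), key=lambda kv: -kv[1])
    return [(name, float(v)) for name, v in ranked]
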