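"""Grid-searched soft-margin kernel SVM for thrombosis prediction.

The classifier is an RBF-kernel SVM, ``K(x, x') = exp(-gamma ||x-x'||^2)``
(gamma plays the role of 1/sigma^2), with the penalty C and gamma chosen
by exhaustive grid search: every (C, gamma) pair is scored by stratified
inner cross-validation accuracy on the training subset and the
highest-accuracy pair wins, ties broken toward the smallest C then the
smallest gamma (prefer the least complex model; value-based, so the
result does not depend on grid enumeration order).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["default_grid", "GridSearchRBFSVM"]


def default_grid() -> list[float]:
    """Powers of two from 2^-7 to 2^7, the libsvm-style search range."""
    return [float(2.0**e) for e in range(-7, 8)]


class GridSearchRBFSVM(ClassifierMixin, BaseEstimator):
    """Soft-margin SVM with exhaustive (C, gamma) grid search.

    Parameters
    ----------
    kernel : {"rbf", "linear", "poly"}
    c_grid, gamma_grid : candidate values (default 2^-7 .. 2^7); the gamma
        grid is ignored for the linear kernel.
    degree : polynomial degree (poly kernel only).
    inner_folds : stratified CV fold count for tuning; every class must
        have at least this many training patients.
    random_state : seed for the inner fold shuffle.

    Attributes
    ----------
    C_, gamma_ : the selected pair.
    cv_results_ : DataFrame with one row per grid pair and its inner-CV
        accuracy.
    model_ : the final SVC refitted on the whole training subset.
    """

    def __init__(self, kernel: str = "rbf", c_grid=None, gamma_grid=None,
                 degree: int = 3, inner_folds: int = 5, random_state: int = 0):
        self.kernel = kernel
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.degree = degree
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _make_svc(self, C: float, gamma: float) -> SVC:
        return SVC(kernel=self.kernel, C=C, gamma=gamma, degree=self.degree)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("X must be 2-d with at least one feature")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        classes, counts = np.unique(y, return_counts=True)
        if set(classes) != {-1, 1}:
            raise ValueError("labels must contain both +1 and -1")
        c_grid = sorted(set(self.c_grid or default_grid()))
        gamma_grid = [1.0] if self.kernel == "linear" else sorted(
            set(self.gamma_grid or default_grid())
        )
        if counts.min() < self.inner_folds:
            raise ValueError(
                f"need at least inner_folds={self.inner_folds} patients per class"
            )
        skf = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True, random_state=self.random_state
        )
        splits = list(skf.split(X, y))
        rows = []
        for C in c_grid:
            for gamma in gamma_grid:
                correct = 0
                for tr, te in splits:
                    svc = self._make_svc(C, gamma).fit(X[tr], y[tr])
                    correct += (svc.predict(X[te]) == y[te]).sum()
                rows.append({"C": C, "gamma": gamma, "cv_accuracy": correct / len(y)})
        self.cv_results_ = pd.DataFrame(rows)
        # best accuracy; ties -> smallest C, then smallest gamma
        best = self.cv_results_.sort_values(
            ["cv_accuracy", "C", "gamma"], ascending=[False, True, True]
        ).iloc[0]
        self.C_, self.gamma_ = float(best["C"]), float(best["gamma"])
        self.model_ = self._make_svc(self.C_, self.gamma_).fit(X, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with the training subset")
        return self.model_.decision_function(X)

    def predict(self, X):
        """Label = sign of the decision score; an exact 0 maps to +1."""
        return np.where(self.decision_function(X) >= 0, 1, -1)
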