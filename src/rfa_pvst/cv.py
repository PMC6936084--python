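"""Outer stratified cross-validation driver.

Per fold: preprocessing statistics and the feature ranking are fitted on
the training part only (no test-fold information reaches normalization,
selection or grid search); SVM models are then tuned, trained and
evaluated on the held-out fold for a ladder of ranking-prefix sizes up to
the automatically detected risk-set size.  The aggregate report is the
unweighted arithmetic mean of every metric over all evaluated
(fold, subset-size) rows; NaN cells propagate to NaN means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .metrics import METRIC_COLUMNS, confusion, metric_report
from .preprocess import CohortPreprocessor
from .scoring import RFAPVSTSelector
from .svm import GridSearchRBFSVM

__all__ = ["FoldPlan", "FoldReport", "CVReport", "stratified_folds", "subset_ladder",
           "run_fold", "cross_validate", "aggregate", "DEFAULT_SEED"]

#: default outer seed (the study's publication date), configurable everywhere
DEFAULT_SEED = 20191230


@dataclass
class FoldPlan:
    k: int
    assignment: np.ndarray  # fold id per patient
    seed: int

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


def stratified_folds(labels, k: int = 5, seed: int = DEFAULT_SEED) -> FoldPlan:
    """Partition each class into k balanced parts: a seeded shuffle per
    class dealt round-robin, so per-fold class counts differ by at most 1."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    assignment = np.empty(labels.shape[0], dtype=int)
    rng = np.random.default_rng(seed)
    for cls in (1, -1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls:+d} has fewer than k={k} patients")
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def subset_ladder(cut: int, step: int = 2) -> list[int]:
    """Prefix sizes evaluated per fold: 1, 1+step, ... up to the detected
    risk-set size, plus the detected size itself."""
    sizes = sorted(set(range(1, cut + 1, step)) | {cut})
    return sizes


@dataclass
class FoldReport:
    fold: int
    ranking: np.ndarray          # feature ids best-first on the training part
    selected: np.ndarray         # detected risk set (ranking prefix)
    rows: list[dict] = field(default_factory=list)


@dataclass
class CVReport:
    folds: list[FoldReport]
    rows: pd.DataFrame           # one row per (fold, subset_size) model
    summary: pd.Series           # unweighted mean of every metric column

    def rankings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold": f.fold,
             "ranking": ",".join(str(i) for i in f.ranking),
             "selected": ",".join(str(i) for i in f.selected)}
            for f in self.folds
        )


def run_fold(
    X, y, train_idx, test_idx, *,
    fold: int = 0,
    selector=None,
    svm_params: dict | None = None,
    subset_sizes=None,
    prefix_step: int = 2,
    representation: str = "discretized",
    feature_ids=None,
    seed: int = DEFAULT_SEED,
) -> FoldReport:
    """Select, tune, train and evaluate on one train/test split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ids = np.arange(X.shape[1]) if feature_ids is None else np.asarray(feature_ids)
    pre = CohortPreprocessor(representation=representation)
    Xtr = pre.fit_transform(X[train_idx])
    Xte = pre.transform(X[test_idx])
    ytr, yte = y[train_idx], y[test_idx]
    sel = clone(selector) if selector is not None else RFAPVSTSelector()
    sel.fit(Xtr, ytr)
    ranking = sel.ranking_
    cut = getattr(sel, "cut_index_", len(ranking))
    if subset_sizes is None:
        subset_sizes = subset_ladder(cut, prefix_step)
    if max(subset_sizes) > X.shape[1]:
        raise ValueError("subset size exceeds the number of features")
    report = FoldReport(fold=fold, ranking=ids[ranking], selected=ids[ranking[:cut]])
    svm_params = dict(svm_params or {})
    svm_params.setdefault("random_state", seed)
    for size in subset_sizes:
        cols = ranking[:size]
        clf = GridSearchRBFSVM(**svm_params).fit(Xtr[:, cols], ytr)
        scores = clf.decision_function(Xte[:, cols])
        pred = np.where(scores >= 0, 1, -1)
        rep = metric_report(confusion(yte, pred), scores=scores, y_true=yte)
        row = {"fold": fold, "subset_size": size, "C": clf.C_, "gamma": clf.gamma_}
        row.update(rep.as_dict())
        report.rows.append(row)
    return report


def cross_validate(
    X, y, *,
    selector=None,
    k: int = 5,
    seed: int = DEFAULT_SEED,
    svm_params: dict | None = None,
    subset_sizes=None,
    prefix_step: int = 2,
    representation: str = "discretized",
    feature_ids=None,
) -> CVReport:
    """Full outer k-fold protocol with a fresh selector per fold."""
    plan = stratified_folds(y, k=k, seed=seed)
    folds = []
    for f in range(k):
        train_idx, test_idx = plan.split(f)
        folds.append(
            run_fold(
                X, y, train_idx, test_idx, fold=f, selector=selector,
                svm_params=svm_params, subset_sizes=subset_sizes,
                prefix_step=prefix_step, representation=representation,
                feature_ids=feature_ids, seed=seed,
            )
        )
    rows = pd.DataFrame([r for fr in folds for r in fr.rows])
    return CVReport(folds=folds, rows=rows, summary=aggregate(rows))


def aggregate(rows: pd.DataFrame) -> pd.Series:
    """Unweighted arithmetic mean of every metric over all evaluated rows
    (not per-fold best); NaN cells make the corresponding mean NaN."""
    if len(rows) == 0:
        raise ValueError("no rows to aggregate")
    cols = [c for c in METRIC_COLUMNS if c in rows.columns]
    return rows[cols].mean(skipna=False)
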