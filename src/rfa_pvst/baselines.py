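"""Comparison feature selectors behind one ranking interface.

Three classic filter/wrapper selectors compete with the risk-degree
ranking in the cross-validated comparison: Relief (nearest hit/miss
weighting), SVM-RFE (recursive elimination on linear-SVM weight
magnitudes) and mRMR (greedy max-relevance min-redundancy on mutual
information, difference scheme).  Additional selectors plug in through
:func:`register_selector`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import mutual_info_score
from sklearn.svm import SVC

__all__ = [
    "SelectorResult",
    "RankingSelector",
    "ReliefSelector",
    "SVMRFESelector",
    "MRMRSelector",
    "register_selector",
    "get_selector",
    "SELECTOR_REGISTRY",
]


@dataclass
class SelectorResult:
    """Ranking produced by one selector: ids best-first plus the
    per-feature score on the algorithm's own scale."""

    algorithm: str
    ranking: np.ndarray
    weights: np.ndarray


class RankingSelector(SelectorMixin, BaseEstimator):
    """Base class: subclasses implement ``_rank(X, y) -> (ranking, weights)``
    with ranking = column indices best-first.

    ``n_select`` bounds the support mask used by ``transform``; None keeps
    every feature (the ranking itself is the product of interest).
    """

    algorithm = "base"

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-d with one label per row")
        if set(np.unique(y)) != {-1, 1}:
            raise ValueError("labels must contain both +1 and -1")
        self.n_features_in_ = X.shape[1]
        self.ranking_, self.weights_ = self._rank(X, y)
        return self

    def _rank(self, X, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def _get_support_mask(self):
        k = getattr(self, "n_select", None) or self.n_features_in_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask

    def result(self, feature_ids=None) -> SelectorResult:
        ids = np.arange(self.n_features_in_) if feature_ids is None else np.asarray(feature_ids)
        return SelectorResult(self.algorithm, ids[self.ranking_], self.weights_)


class ReliefSelector(RankingSelector):
    """Classic binary Relief.

    Iterates over ``n_samples`` seeded-shuffled instances (default: every
    instance once); for each, finds the nearest hit and nearest miss by
    Manhattan distance on range-normalized features and updates
    ``W_j += (|x_j - miss_j| - |x_j - hit_j|) / n_samples``.  Ranking by
    descending weight, ties toward the lower column index.
    """

    algorithm = "relief"

    def __init__(self, n_samples: int | None = None, random_state: int = 0,
                 n_select: int | None = None):
        self.n_samples = n_samples
        self.random_state = random_state
        self.n_select = n_select

    def _rank(self, X, y):
        m, n = X.shape
        for cls in (1, -1):
            if (y == cls).sum() < 2:
                raise ValueError("each class needs at least 2 instances")
        span = X.max(axis=0) - X.min(axis=0)
        span[span == 0] = 1.0  # constant feature contributes 0 everywhere
        Xs = X / span
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(m)
        n_samples = m if self.n_samples is None else int(self.n_samples)
        picks = np.resize(order, n_samples)
        W = np.zeros(n)
        dists = np.abs(Xs[:, None, :] - Xs[None, :, :]).sum(axis=2) if m <= 512 else None
        for i in picks:
            d = dists[i] if dists is not None else np.abs(Xs - Xs[i]).sum(axis=1)
            d = d.copy()
            d[i] = np.inf  # exclude self from the hit search
            same_idx = np.flatnonzero(y == y[i])
            miss_idx = np.flatnonzero(y != y[i])
            hit = same_idx[np.argmin(d[same_idx])]
            miss = miss_idx[np.argmin(d[miss_idx])]
            W += (np.abs(Xs[i] - Xs[miss]) - np.abs(Xs[i] - Xs[hit])) / n_samples
        ranking = np.lexsort((np.arange(n), -W))
        return ranking, W


class SVMRFESelector(RankingSelector):
    """Recursive feature elimination on linear soft-margin SVM weights.

    Retrains at every round, dropping the single feature with the smallest
    ``|w|`` (ties toward the lower column index); the ranking is the
    reverse elimination order.  ``weights_`` holds the elimination round
    (higher = survived longer).
    """

    algorithm = "svmrfe"

    def __init__(self, C: float = 1.0, n_select: int | None = None):
        self.C = C
        self.n_select = n_select

    def _rank(self, X, y):
        n = X.shape[1]
        remaining = list(range(n))
        eliminated: list[int] = []
        while len(remaining) > 1:
            svm = SVC(kernel="linear", C=self.C).fit(X[:, remaining], y)
            w = np.abs(svm.coef_.ravel())
            drop = int(np.argmin(w))
            eliminated.append(remaining.pop(drop))
        eliminated.append(remaining[0])
        ranking = np.array(eliminated[::-1])
        weights = np.empty(n)
        weights[ranking] = np.arange(n, 0, -1)
        return ranking, weights


class MRMRSelector(RankingSelector):
    """Greedy max-relevance min-redundancy (difference scheme).

    Works on discretized features (small alphabets such as {-1, 0, 1}).
    Step 1 picks the feature with maximal mutual information with the
    label; each later step maximizes ``I(f; y) - mean_{g chosen} I(f; g)``
    with empirical-frequency mutual information in nats.  Ties go to the
    lower column index.  ``n_select`` limits the greedy path length
    (remaining features are appended by descending relevance).
    """

    algorithm = "mrmr"

    def __init__(self, n_select: int | None = None):
        self.n_select = n_select

    def _rank(self, X, y):
        n = X.shape[1]
        k = n if self.n_select is None else int(self.n_select)
        if k <= 0:
            raise ValueError("n_select must be positive")
        relevance = np.array([mutual_info_score(y, X[:, j]) for j in range(n)])
        redundancy = np.zeros(n)
        chosen: list[int] = []
        scores = np.empty(n)
        remaining = list(range(n))
        while remaining and len(chosen) < k:
            crit = np.array(
                [relevance[j] - (redundancy[j] / len(chosen) if chosen else 0.0)
                 for j in remaining]
            )
            best = remaining[int(np.argmax(crit))]
            scores[best] = crit[remaining.index(best)]
            chosen.append(best)
            remaining.remove(best)
            for j in remaining:
                redundancy[j] += mutual_info_score(X[:, best], X[:, j])
        # features beyond the greedy path rank by plain relevance
        tail = sorted(remaining, key=lambda j: (-relevance[j], j))
        for j in tail:
            scores[j] = -np.inf
        ranking = np.array(chosen + tail, dtype=int)
        return ranking, scores


SELECTOR_REGISTRY: dict[str, type] = {
    "relief": ReliefSelector,
    "svmrfe": SVMRFESelector,
    "mrmr": MRMRSelector,
}


def register_selector(name: str, cls: type) -> None:
    """Plug an external selector class (must follow the
    :class:`RankingSelector` contract) into the registry, e.g. to
    reconstitute comparisons with selectors not shipped here."""
    SELECTOR_REGISTRY[name] = cls


def get_selector(name: str, **params):
    try:
        return SELECTOR_REGISTRY[name](**params)
    except KeyError:
        raise KeyError(f"unknown selector {name!r}; known: {sorted(SELECTOR_REGISTRY)}")
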