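"""Discernibility-independence risk-factor scoring and detection.

Each clinical index j gets three scores:

* **discernibility** ``dis_j = max(N0*N1 - S(j), S(j))`` where
  ``S(j) = sum_{k in PVST} sum_{i in non-PVST} 1[(x_i - x_k) <= 0]``
  counts ordered cross-class pairs in which the non-PVST value does not
  exceed the PVST value (N0 = #PVST, N1 = #non-PVST).  Taking the larger
  tail makes dis direction-free: it is the extreme Mann-Whitney pair
  count, in [ceil(N0*N1/2), N0*N1] for tie-free data.

* **independence** ``ind_j = exp(-pr)`` with pr an absolute Pearson
  correlation: for the feature(s) attaining the global maximum of dis, pr
  is the correlation with the *least* correlated partner (so the top
  feature keeps the highest achievable independence); for every other
  feature, pr is the correlation with its *most* correlated partner among
  the features of strictly higher discernibility.  ind lives in
  [e^-1, 1].

* **risk degree** ``RD_j = dis_j * ind_j`` — the area of the rectangle
  the index spans in the discernibility-independence plane.  Indexes are
  ranked by descending RD, and the risk-factor set is the top-right
  corner: the ranking prefix before the largest RD drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

__all__ = [
    "discernibility",
    "discernibility_all",
    "abs_pearson",
    "correlation_matrix",
    "independence",
    "risk_degree",
    "rank_features",
    "detect_cut",
    "RiskFactorSet",
    "RFAPVSTSelector",
    "scatter_coordinates",
]


def discernibility(x, labels, tie_mode: str = "paper") -> tuple[float, float]:
    """Cross-class pair-count statistic S and discernibility dis for one
    feature column.

    ``tie_mode="paper"`` counts tied pairs fully (the literal "<=" of the
    definition; a constant column then scores S = dis = N0*N1, a documented
    pathology); ``tie_mode="midrank"`` counts ties 1/2, recovering the
    standard rank-sum statistic.
    """
    S, dis = discernibility_all(np.asarray(x, dtype=float)[:, None], labels, tie_mode)
    return float(S[0]), float(dis[0])


def discernibility_all(X, labels, tie_mode: str = "paper") -> tuple[np.ndarray, np.ndarray]:
    """Vectorized S and dis for every column of X."""
    if tie_mode not in ("paper", "midrank"):
        raise ValueError("tie_mode must be 'paper' or 'midrank'")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    pos = X[labels == 1]   # PVST, N0 rows
    neg = X[labels == -1]  # non-PVST, N1 rows
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    # pair (k in pos, i in neg) counts when neg_value - pos_value <= 0
    diff = neg[:, None, :] - pos[None, :, :]
    lt = (diff < 0).sum(axis=(0, 1)).astype(float)
    eq = (diff == 0).sum(axis=(0, 1)).astype(float)
    S = lt + (eq if tie_mode == "paper" else 0.5 * eq)
    n_pairs = pos.shape[0] * neg.shape[0]
    dis = np.maximum(n_pairs - S, S)
    return S, dis


def abs_pearson(x, y) -> float:
    """Absolute Pearson correlation; a constant vector yields 0 (maximally
    uninformative) with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        warnings.warn("constant vector in correlation; returning 0", stacklevel=2)
        return 0.0
    return float(abs(xc @ yc) / denom)


def correlation_matrix(X) -> np.ndarray:
    """Symmetric matrix of absolute Pearson coefficients, unit diagonal;
    constant columns correlate 0 with everything."""
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    const = norms == 0
    if const.any():
        warnings.warn("constant feature(s) in correlation matrix; rows set to 0", stacklevel=2)
    safe = np.where(const, 1.0, norms)
    C = np.abs((Xc / safe).T @ (Xc / safe))
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.clip(C, 0.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


def independence(dis, corr) -> tuple[np.ndarray, np.ndarray]:
    """Independence score and anchor partner for every feature.

    Features at the global discernibility maximum pair with their least
    correlated partner; all others pair with the most correlated feature
    of strictly higher discernibility ("higher" read strictly, so features
    tied at the maximum all take the max branch).  Returns (ind, anchor)
    where anchor[j] is the partner column index (-1 for a lone feature).
    """
    dis = np.asarray(dis, dtype=float)
    corr = np.asarray(corr, dtype=float)
    n = dis.size
    if n == 1:
        return np.ones(1), np.array([-1])
    ind = np.empty(n)
    anchor = np.empty(n, dtype=int)
    top = dis.max()
    for j in range(n):
        row = corr[j]
        if dis[j] == top:
            others = np.delete(np.arange(n), j)
            k = others[np.argmin(row[others])]
        else:
            stronger = np.flatnonzero(dis > dis[j])
            k = stronger[np.argmax(row[stronger])]
        ind[j] = np.exp(-row[k])
        anchor[j] = k
    return ind, anchor


def risk_degree(dis, ind) -> np.ndarray:
    """Elementwise product dis * ind."""
    return np.asarray(dis, dtype=float) * np.asarray(ind, dtype=float)


def rank_features(rd, dis=None, feature_ids=None) -> np.ndarray:
    """Positions sorted by descending RD; ties break by descending dis,
    then ascending feature id.  Deterministic."""
    rd = np.asarray(rd, dtype=float)
    n = rd.size
    dis = np.zeros(n) if dis is None else np.asarray(dis, dtype=float)
    ids = np.arange(n) if feature_ids is None else np.asarray(feature_ids)
    return np.lexsort((ids, -dis, -rd))


def detect_cut(rd_sorted, max_cut: int | None = None) -> tuple[int, float]:
    """Largest-gap cut on a descending RD sequence.

    Returns (cut_index, gap): the prefix length before the largest drop
    ``rd[r-1] - rd[r]`` over r in [1, min(n-1, max_cut)]; gap ties break
    toward the earliest cut.  All-equal RD falls back to top-1 with a
    warning.
    """
    rd = np.asarray(rd_sorted, dtype=float)
    n = rd.size
    if n < 2:
        return n, 0.0
    limit = n - 1 if max_cut is None else min(n - 1, int(max_cut))
    gaps = rd[:limit] - rd[1 : limit + 1]
    best = int(np.argmax(gaps))
    if gaps[best] <= 0:
        warnings.warn("all risk degrees equal; selecting top-1", stacklevel=2)
        return 1, 0.0
    return best + 1, float(gaps[best])


@dataclass
class RiskFactorSet:
    """Ranked feature ids with the detected risk prefix."""

    ranking: np.ndarray   # feature ids best-first
    selected: np.ndarray  # prefix of ranking
    cut_index: int
    gap_value: float


class RFAPVSTSelector(SelectorMixin, BaseEstimator):
    """Risk-factor selector ranking features by discernibility x independence.

    Scikit-learn selector: ``fit(X, y)`` with y in {+1, -1} scores every
    column, ranks by descending risk degree and detects the risk set as
    the pre-largest-gap prefix; ``transform(X)`` keeps the selected
    columns.

    Parameters
    ----------
    tie_mode : {"paper", "midrank"}
        Tied cross-class pairs count fully (literal definition) or 1/2.
    n_select : int or None
        Fixed risk-set size overriding the automatic largest-gap cut.
    max_cut : int or None
        Upper bound on the automatic cut position (default n-1).

    Attributes
    ----------
    S_, dis_, ind_, rd_ : ndarray per input column
    anchor_ : partner column realizing each feature's independence
    ranking_ : column indices sorted best-first
    cut_index_, gap_value_ : detected prefix size and the RD drop there
    """

    def __init__(self, tie_mode: str = "paper", n_select: int | None = None,
                 max_cut: int | None = None):
        self.tie_mode = tie_mode
        self.n_select = n_select
        self.max_cut = max_cut

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-d with one label per row")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        self.n_features_in_ = X.shape[1]
        self.S_, self.dis_ = discernibility_all(X, y, self.tie_mode)
        self.corr_ = correlation_matrix(X)
        self.ind_, self.anchor_ = independence(self.dis_, self.corr_)
        self.rd_ = risk_degree(self.dis_, self.ind_)
        self.ranking_ = rank_features(self.rd_, self.dis_)
        if self.n_select is not None:
            if not 1 <= self.n_select <= self.n_features_in_:
                raise ValueError("n_select out of range")
            self.cut_index_ = int(self.n_select)
            self.gap_value_ = 0.0
        else:
            self.cut_index_, self.gap_value_ = detect_cut(
                self.rd_[self.ranking_], self.max_cut
            )
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[: self.cut_index_]] = True
        return mask

    def risk_factor_set(self, feature_ids=None) -> RiskFactorSet:
        ids = np.arange(self.n_features_in_) if feature_ids is None else np.asarray(feature_ids)
        ranking = ids[self.ranking_]
        return RiskFactorSet(
            ranking=ranking,
            selected=ranking[: self.cut_index_],
            cut_index=self.cut_index_,
            gap_value=self.gap_value_,
        )

    def scores_frame(self, feature_ids=None, feature_names=None) -> pd.DataFrame:
        """Per-feature score table sorted by rank (the scores.tsv layout)."""
        return scatter_coordinates(self, feature_ids, feature_names)


def scatter_coordinates(selector: RFAPVSTSelector, feature_ids=None,
                        feature_names=None) -> pd.DataFrame:
    """Coordinates of every feature in the discernibility-independence
    plane (x = dis, y = ind) with the detected risk set flagged, sorted by
    rank."""
    n = selector.n_features_in_
    ids = np.arange(n) if feature_ids is None else np.asarray(feature_ids)
    names = [str(i) for i in ids] if feature_names is None else list(feature_names)
    order = selector.ranking_
    sel = np.zeros(n, dtype=bool)
    sel[order[: selector.cut_index_]] = True
    anchor_ids = np.where(selector.anchor_ >= 0, ids[selector.anchor_], -1)
    return pd.DataFrame(
        {
            "feature_id": ids[order],
            "name": [names[j] for j in order],
            "S": selector.S_[order],
            "dis": selector.dis_[order],
            "ind": selector.ind_[order],
            "RD": selector.rd_[order],
            "anchor_feature": anchor_ids[order],
            "is_selected": sel[order],
        }
    )
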