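"""Successive min-max normalization and three-level discretization.

Measurement metrics differ wildly across clinical indexes, so each index
is first mapped to [0, 1] by its training min/max,

    x'_{i,j} = (x_{i,j} - min(x_j)) / (max(x_j) - min(x_j)),

and then coded into {-1, 0, 1} against the mean mu_j and standard
deviation sigma_j of the *normalized* training column:

    d_{i,j} = -1 if x'_{i,j} < mu_j - sigma_j
               1 if x'_{i,j} > mu_j + sigma_j
               0 otherwise  (boundaries fall in the 0 band).

All statistics are fitted on training rows only; normalized test values
outside the training range clip to [0, 1].  Boolean indexes pass through
the same chain (0/1 survives normalization unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["PreprocessStats", "fit_stats", "normalize", "discretize", "CohortPreprocessor"]


@dataclass
class PreprocessStats:
    """Per-feature min/max/mean/std fitted on a training partition."""

    minimum: np.ndarray
    maximum: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    constant: np.ndarray  # boolean mask of max == min columns
    ddof: int = 1
    fitted_on: str | None = None


def fit_stats(X, rows=None, ddof: int = 1, fitted_on: str | None = None) -> PreprocessStats:
    """Fit per-feature min, max, mean and standard deviation.

    ``rows`` restricts fitting to a training-row subset.  The sample
    convention (ddof=1) is the default; constant columns are flagged and
    get sigma = 0.
    """
    X = np.asarray(X, dtype=float)
    if rows is not None:
        X = X[np.asarray(rows)]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit statistics")
    mn, mx = X.min(axis=0), X.max(axis=0)
    return PreprocessStats(
        minimum=mn,
        maximum=mx,
        mean=X.mean(axis=0),
        std=X.std(axis=0, ddof=ddof),
        constant=mx == mn,
        ddof=ddof,
        fitted_on=fitted_on,
    )


def normalize(X, stats: PreprocessStats, clip: bool = True) -> np.ndarray:
    """Min-max map each column to [0, 1] using training min/max.

    Constant features map to 0; out-of-range values clip to [0, 1]
    when ``clip`` is set (the default, for held-out rows).
    """
    X = np.asarray(X, dtype=float)
    span = np.where(stats.constant, 1.0, stats.maximum - stats.minimum)
    out = (X - stats.minimum) / span
    out[:, stats.constant] = 0.0
    if clip:
        np.clip(out, 0.0, 1.0, out=out)
    return out


def discretize(X_normalized, stats: PreprocessStats) -> np.ndarray:
    """Three-level code against mu_j +/- sigma_j of the normalized training
    column; strict inequalities put the boundaries in the 0 band."""
    X = np.asarray(X_normalized, dtype=float)
    lo = stats.mean - stats.std
    hi = stats.mean + stats.std
    out = np.zeros_like(X)
    out[X < lo] = -1.0
    out[X > hi] = 1.0
    return out


class CohortPreprocessor(TransformerMixin, BaseEstimator):
    """Fit-on-train / apply-on-test preprocessing transformer.

    Parameters
    ----------
    representation : {"discretized", "normalized"}
        Output representation: the full chain (default) or min-max
        normalization only.
    ddof : int
        Standard-deviation convention for the discretization band
        (1 = sample, 0 = population).
    clip : bool
        Clip normalized values to [0, 1] (affects held-out rows whose raw
        values fall outside the training range).
    """

    def __init__(self, representation: str = "discretized", ddof: int = 1, clip: bool = True):
        self.representation = representation
        self.ddof = ddof
        self.clip = clip

    def fit(self, X, y=None):
        if self.representation not in ("discretized", "normalized"):
            raise ValueError("representation must be 'discretized' or 'normalized'")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d")
        self.n_features_in_ = X.shape[1]
        self.range_stats_ = fit_stats(X, ddof=self.ddof, fitted_on="train/raw")
        Xn = normalize(X, self.range_stats_, clip=False)
        self.band_stats_ = fit_stats(Xn, ddof=self.ddof, fitted_on="train/normalized")
        return self

    def transform(self, X):
        if not hasattr(self, "range_stats_"):
            raise RuntimeError("preprocessor is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        Xn = normalize(X, self.range_stats_, clip=self.clip)
        if self.representation == "normalized":
            return Xn
        return discretize(Xn, self.band_stats_)
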