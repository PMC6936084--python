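"""Friedman test and post-hoc mean-rank comparison across selectors.

Selectors are compared over blocks — one block per evaluated
(fold, subset-size) model, one column per selector, holding one metric
(e.g. Acc).  The Friedman chi-square uses within-block mid-ranks with the
standard tie correction; once it rejects, pairwise mean-rank differences
are tested against the Nemenyi critical difference

    CD = q_{alpha, k} / sqrt(2) * sqrt(k (k + 1) / (6 N))

with q the studentized-range quantile at the stated confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, studentized_range

__all__ = ["ScoreMatrix", "FriedmanResult", "PosthocResult", "friedman",
           "posthoc_mean_ranks", "build_score_matrix"]


@dataclass
class ScoreMatrix:
    """Blocks x algorithms matrix of one evaluation metric."""

    values: np.ndarray
    block_labels: list
    algorithms: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("scores must be 2-d (blocks x algorithms)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 blocks and 2 algorithms")
        if not np.isfinite(self.values).all():
            raise ValueError("scores contain non-finite entries; drop those blocks first")


def _as_matrix(scores) -> ScoreMatrix:
    if isinstance(scores, ScoreMatrix):
        return scores
    if isinstance(scores, pd.DataFrame):
        return ScoreMatrix(scores.to_numpy(float), list(scores.index), list(scores.columns))
    arr = np.asarray(scores, dtype=float)
    return ScoreMatrix(arr, list(range(arr.shape[0])), list(range(arr.shape[1])))


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    ranks: np.ndarray       # within-block mid-ranks, blocks x algorithms
    mean_ranks: np.ndarray  # per-algorithm
    algorithms: list


def friedman(scores, alpha: float = 0.05) -> FriedmanResult:
    """Tie-corrected Friedman test over blocks.

    chi2 = (k-1) * sum_j (R_j - N(k+1)/2)^2 / (sum_ij r_ij^2 - N k (k+1)^2 / 4),
    which reduces to the classic 12/(Nk(k+1)) form for tie-free ranks and
    to 0 (p = 1) when every block is constant.
    """
    sm = _as_matrix(scores)
    N, k = sm.values.shape
    ranks = np.apply_along_axis(rankdata, 1, sm.values)
    R = ranks.sum(axis=0)
    num = (k - 1) * ((R - N * (k + 1) / 2.0) ** 2).sum()
    den = (ranks**2).sum() - N * k * (k + 1) ** 2 / 4.0
    stat = 0.0 if den == 0 else num / den
    df = k - 1
    p = float(chi2.sf(stat, df)) if den != 0 else 1.0
    return FriedmanResult(
        chi2=float(stat), df=df, p=p, ranks=ranks,
        mean_ranks=R / N, algorithms=sm.algorithms,
    )


@dataclass
class PosthocResult:
    mean_ranks: np.ndarray
    differences: np.ndarray  # antisymmetric mean-rank differences
    significant: np.ndarray  # symmetric boolean flags
    critical_difference: float
    confidence: float
    algorithms: list

    def frame(self) -> pd.DataFrame:
        """Rendered matrix: mean-rank differences in the upper triangle,
        significance stars in the lower."""
        k = len(self.algorithms)
        out = pd.DataFrame("", index=self.algorithms, columns=self.algorithms)
        for i in range(k):
            for j in range(k):
                if i < j:
                    out.iloc[i, j] = f"{self.differences[i, j]:.4f}"
                elif i > j:
                    out.iloc[i, j] = "*" if self.significant[i, j] else ""
        return out


def posthoc_mean_ranks(scores, confidence: float = 0.95) -> PosthocResult:
    """Nemenyi-type multiple comparison on Friedman mean ranks: a pair
    differs significantly when |mean-rank difference| exceeds the critical
    difference at the stated confidence."""
    fr = friedman(scores)
    N, k = fr.ranks.shape
    q = studentized_range.ppf(confidence, k, np.inf)
    cd = q / np.sqrt(2.0) * np.sqrt(k * (k + 1) / (6.0 * N))
    diff = fr.mean_ranks[:, None] - fr.mean_ranks[None, :]
    sig = np.abs(diff) > cd
    np.fill_diagonal(sig, False)
    return PosthocResult(
        mean_ranks=fr.mean_ranks, differences=diff, significant=sig,
        critical_difference=float(cd), confidence=confidence,
        algorithms=fr.algorithms,
    )


def build_score_matrix(reports: dict, metric: str = "Acc") -> ScoreMatrix:
    """Assemble the blocks x algorithms matrix from per-algorithm CV rows.

    ``reports`` maps algorithm name -> rows DataFrame (as produced by
    :func:`rfa_pvst.cv.cross_validate`, columns fold/subset_size/metrics).
    Every algorithm must cover the same (fold, subset_size) grid.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 algorithms to compare")
    keyed = {}
    grid = None
    for algo, rows in reports.items():
        df = rows.rows if hasattr(rows, "rows") else rows
        df = df.set_index(["fold", "subset_size"])[metric]
        blocks = list(df.index)
        if grid is None:
            grid = blocks
        elif set(blocks) != set(grid):
            missing = sorted(set(grid) ^ set(blocks))
            raise ValueError(f"algorithm {algo!r}: mismatched blocks {missing}")
        keyed[algo] = df.reindex(grid)
    values = np.column_stack([keyed[a].to_numpy(float) for a in keyed])
    return ScoreMatrix(values, [f"fold{f}/k{s}" for f, s in grid], list(keyed))
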