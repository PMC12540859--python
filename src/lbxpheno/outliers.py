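"""Rare-event outlier detection over single-cell feature spaces.

Rare phenotypes sit at ~1:10,000 among WBCs, so unsupervised outlier
ranking is the first-line screen: score every cell, inspect the top-K
(K ~ 0.1% of cells).  Three detectors are provided:

* COPOD / ECOD — parameter-free detectors built on empirical tail
  probabilities: per dimension the left/right ECDF tail of each point is
  converted to a negative log probability and aggregated across dimensions;
  the final score is the largest of the left-tail, right-tail and
  skewness-corrected aggregates.  The two methods share this skeleton and
  differ in their tail-probability convention.
* iForest — isolation forest (100 estimators), via scikit-learn.

Scores are comparable only within one ranking; higher = more outlying.
The contamination parameter only thresholds binary flags and never affects
the ranking itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats
from sklearn.ensemble import IsolationForest

from .types import FeatureMatrix, LbxError

METHODS = ("COPOD", "ECOD", "iForest")


def robust_scale(x: np.ndarray) -> np.ndarray:
    """Per-feature (x - median) / IQR scaling; constant features map to 0."""
    med = np.median(x, axis=0)
    q75, q25 = np.percentile(x, [75, 25], axis=0)
    iqr = np.maximum(q75 - q25, 1e-9)
    return (x - med) / iqr


@dataclass
class OutlierRanking:
    """Per-cell outlier scores and their descending rank order."""

    scores: np.ndarray
    method: str
    contamination: float = 0.001

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.method not in METHODS:
            raise LbxError(f"unknown outlier method {self.method!r}")
        if not (0 < self.contamination < 0.5):
            raise LbxError("contamination must lie in (0, 0.5)")

    @property
    def order(self) -> np.ndarray:
        """Indices sorted by descending score (stable for ties)."""
        return np.argsort(-self.scores, kind="stable")

    def flags(self) -> np.ndarray:
        """Binary outlier labels from the contamination fraction (thresholding
        only; the ranking is unaffected by the contamination setting)."""
        k = max(1, int(round(self.contamination * len(self.scores))))
        out = np.zeros(len(self.scores), dtype=bool)
        out[self.order[:k]] = True
        return out


def _tail_scores(x: np.ndarray, denom_offset: int) -> Tuple[np.ndarray, np.ndarray]:
    """-log left/right ECDF tail probabilities per point per dimension."""
    n = x.shape[0]
    # tie-aware ranks: "number of values <= x" / ">= x" via searchsorted per dim
    left = np.empty_like(x)
    right = np.empty_like(x)
    for d in range(x.shape[1]):
        xs = np.sort(x[:, d], kind="stable")
        left[:, d] = np.searchsorted(xs, x[:, d], side="right")
        right[:, d] = n - np.searchsorted(xs, x[:, d], side="left")
    denom = n + denom_offset
    return -np.log(left / denom), -np.log(right / denom)


def _ecdf_detector(x: np.ndarray, denom_offset: int) -> np.ndarray:
    o_left, o_right = _tail_scores(x, denom_offset)
    skew = stats.skew(x, axis=0)
    o_auto = np.where(skew[None, :] < 0, o_left, o_right)
    sums = np.stack(
        [o_left.sum(axis=1), o_right.sum(axis=1), o_auto.sum(axis=1)]
    )
    return sums.max(axis=0)


def detect_outliers(
    features: FeatureMatrix | np.ndarray,
    method: str,
    contamination: float = 0.001,
    seed: int = 0,
    scale: bool = True,
) -> OutlierRanking:
    """Score every cell with the chosen detector (higher = more outlying).

    ``scale`` applies per-feature robust scaling first (recommended for the
    engineered space, harmless for the learned space; both spaces are always
    treated identically in comparisons).  iForest is seeded; COPOD/ECOD are
    deterministic score functions, so duplicated points get equal scores.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if len(x) < 10:
        raise LbxError("outlier detection needs at least 10 cells")
    if method not in METHODS:
        raise LbxError(f"unknown outlier method {method!r}; choose from {METHODS}")
    if scale:
        x = robust_scale(x)
    if method == "COPOD":
        scores = _ecdf_detector(x, denom_offset=0)
    elif method == "ECOD":
        scores = _ecdf_detector(x, denom_offset=1)
    else:
        forest = IsolationForest(
            n_estimators=100, contamination="auto", random_state=seed
        )
        forest.fit(x)
        scores = -forest.score_samples(x)
    return OutlierRanking(scores=scores, method=method, contamination=contamination)


def topk_recovery(
    ranking: OutlierRanking,
    truth: np.ndarray,
    k: int,
) -> Tuple[np.ndarray, float]:
    """Recovery curve and normalized AUC over the top-K of a ranking.

    Walks the first K ranked cells accumulating recall of the true rare
    cells (the returned curve is absolute recall, cumulative hits / all
    rare cells).  The AUC describes how early the rare cells found within
    the top-K prefix appear: the cumulative hit count is integrated over the
    prefix and normalized by the ideal ordering of those same hits (all of
    them first).  A ranking placing every rare cell first scores 1.0, one
    with no rare cell inside the top-K scores 0.0, and a random ranking
    averages ~0.5.  Invariant to strictly monotone transforms of the scores
    (rank-based).
    """
    truth = np.asarray(truth).astype(bool)
    n = len(truth)
    if len(ranking.scores) != n:
        raise LbxError("ranking/truth length mismatch")
    if not (1 <= k <= n):
        raise LbxError("K must lie in [1, n]")
    m = int(truth.sum())
    if m == 0:
        raise LbxError("no positive cells in truth")
    hits = truth[ranking.order[:k]]
    cum = np.cumsum(hits)
    recall = cum / m
    m_k = int(cum[-1])
    if m_k == 0:
        return recall, 0.0
    ideal = np.minimum(np.arange(1, k + 1), m_k)
    auc = float(cum.sum() / ideal.sum())
    return recall, auc
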