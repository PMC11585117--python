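"""MOGONET-compatible feature preselection.

Two steps: (1) rank features by a one-way ANOVA F statistic across classes;
(2) keep the smallest F-ranked prefix whose first principal component (on
standardized data) explains at least half of the total variance.  This is
the reduction that produced the "features for training" counts the
benchmark datasets ship with.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif

logger = logging.getLogger("mokl")

__all__ = ["anova_f_rank", "pc1_variance_cutoff", "preselect_features"]


def anova_f_rank(X: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by one-way ANOVA F value, descending.

    Returns ``(order, F)`` where ``order`` are feature indices sorted by
    descending F (ties keep original index order) and ``F`` is in original
    feature order.  Constant features get ``F = 0`` and sort last.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    order = np.argsort(-F, kind="stable")
    return order, F


def pc1_variance_cutoff(X_ranked: np.ndarray, threshold: float = 0.5,
                        grid: Sequence[int] | None = None) -> int:
    """Smallest F-ranked prefix whose PC1 explains >= ``threshold`` variance.

    ``X_ranked`` must have columns already in F-rank order.  The prefix
    length is scanned over ``grid`` (default ``50, 100, ... , p``); features
    are standardized before the PCA check.  If no prefix reaches the
    threshold, the grid's argmax is returned with a warning.
    """
    X_ranked = np.asarray(X_ranked, dtype=float)
    p = X_ranked.shape[1]
    if grid is None:
        grid = list(range(50, p + 1, 50)) or [p]
        if grid[-1] != p:
            grid.append(p)
    grid = sorted({int(k) for k in grid if 0 < k <= p})
    if not grid:
        raise ValueError("empty prefix grid")
    best_k, best_ratio = grid[0], -1.0
    for k in grid:
        sub = X_ranked[:, :k]
        sd = sub.std(axis=0)
        sub = (sub - sub.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        ratio = float(PCA(n_components=1).fit(sub).explained_variance_ratio_[0])
        if ratio >= threshold:
            return k
        if ratio > best_ratio:
            best_k, best_ratio = k, ratio
    logger.warning("pc1_variance_cutoff: threshold %.2f never reached "
                   "(best PC1 ratio %.3f at k=%d)", threshold, best_ratio, best_k)
    return best_k


def preselect_features(X: np.ndarray, labels, threshold: float = 0.5,
                       grid: Sequence[int] | None = None) -> np.ndarray:
    """Convenience: ANOVA-F rank then PC1-variance cutoff; returns kept indices."""
    order, _ = anova_f_rank(X, labels)
    k = pc1_variance_cutoff(np.asarray(X, float)[:, order], threshold, grid)
    return order[:k]
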