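"""Benchmark protocol: stratified 30/70 train/test splits over a fixed seed
set, per-split hyperparameter tuning confined to the training partition,
and mean +/- sd reporting of classification metrics.

Binary tasks report accuracy, F1 (positive class = second class in the
recorded class order) and AUC from decision scores; multiclass tasks report
accuracy, weighted F1 and macro F1.  Weighted F1 uses class supports as
weights summing to one (the standard support-weighted average).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import train_test_split

from .deep import DeepMKLClassifier, DeepMKLConfig, tune_deep_mkl
from .svm import MKLClassifier, STRATEGIES, grid_search

logger = logging.getLogger("mokl")

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "stratified_split",
    "accuracy",
    "f1_binary",
    "auc",
    "f1_macro",
    "f1_weighted",
    "compute_metrics",
    "fusion_weights_over_splits",
    "run_benchmark",
]


@dataclasses.dataclass
class SplitSpec:
    """Stratified train/test split specification (default: 30% train,
    seeds 0-4)."""

    train_fraction: float = 0.30
    seeds: list = dataclasses.field(default_factory=lambda: [0, 1, 2, 3, 4])
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must be in (0, 1)")
        if not self.seeds:
            raise ValueError("need at least one split seed")


def stratified_split(labels, spec: SplitSpec | float, seed: int):
    """Return (train_idx, test_idx) for one stratified split.

    Per-class training proportions land within one sample of the requested
    fraction; the two index sets are disjoint and exhaustive.
    """
    frac = spec.train_fraction if isinstance(spec, SplitSpec) else float(spec)
    stratify = spec.stratified if isinstance(spec, SplitSpec) else True
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("stratified split needs every class at least twice")
    idx = np.arange(len(y))
    train, test = train_test_split(idx, train_size=frac, random_state=seed,
                                   stratify=y if stratify else None)
    return np.sort(train), np.sort(test)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy(y_true, y_pred) -> float:
    """Fraction of correct predictions, (TP+TN)/(TP+TN+FP+FN)."""
    return float(skm.accuracy_score(y_true, y_pred))


def f1_binary(y_true, y_pred, pos_label=None) -> float:
    """Binary F1 = 2 P R / (P + R); zero denominators give 0."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if pos_label is None:
        pos_label = np.unique(y_true)[-1]
    return float(skm.f1_score(y_true, y_pred, pos_label=pos_label,
                              zero_division=0))

def auc(y_true, scores, pos_label=None) -> float:
    """ROC AUC, equal to the Mann-Whitney pair-ordering statistic
    (correctly ordered (positive, negative) pairs; ties count one half)."""
    y_true = np.asarray(y_true)
    if pos_label is None:
        pos_label = np.unique(y_true)[-1]
    return float(skm.roc_auc_score(y_true == pos_label, np.asarray(scores)))


def f1_macro(y_true, y_pred) -> float:
    """Unweighted mean of per-class one-vs-rest F1 scores."""
    return float(skm.f1_score(y_true, y_pred, average="macro", zero_division=0))


def f1_weighted(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1 (weights sum to one)."""
    return float(skm.f1_score(y_true, y_pred, average="weighted",
                              zero_division=0))


def compute_metrics(y_true, y_pred, scores=None) -> dict:
    """The protocol's metric set: binary -> ACC/F1/AUC, multiclass ->
    ACC/F1_weighted/F1_macro."""
    y_true = np.asarray(y_true)
    out = {"ACC": accuracy(y_true, y_pred)}
    if np.unique(y_true).size == 2:
        out["F1"] = f1_binary(y_true, y_pred)
        if scores is not None:
            out["AUC"] = auc(y_true, scores)
    else:
        out["F1_weighted"] = f1_weighted(y_true, y_pred)
        out["F1_macro"] = f1_macro(y_true, y_pred)
    return out


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def fusion_weights_over_splits(blocks, labels, strategy: str = "statis",
                               sigma: float = 5e-4,
                               spec: SplitSpec | None = None) -> np.ndarray:
    """Mean kernel-fusion weights over the protocol's training partitions.

    For each seed: take the stratified training split, standardize each
    block on it, compute per-block Gaussian kernels and the requested
    fusion weights.  Returns the seed-averaged weight vector -- the quantity
    reported when summarizing how much each omic contributes to the fused
    kernel.
    """
    from . import fusion as _fusion
    from .kernels import compute_kernel, KernelParams, standardize as _std

    spec = spec or SplitSpec()
    Xs = [np.asarray(getattr(b, "values", b), dtype=float) for b in blocks]
    y = np.asarray(labels)
    all_w = []
    for seed in spec.seeds:
        tr, _ = stratified_split(y, spec, seed)
        kernels = [compute_kernel(_std(X[tr]),
                                  KernelParams("gaussian_rbf", sigma))
                   for X in Xs]
        w = _fusion.compute_weights(strategy, kernels, labels=y[tr])
        all_w.append(w.values)
    return np.mean(all_w, axis=0)


@dataclasses.dataclass
class MetricsReport:
    """Per-seed metric values and their mean +/- sd aggregation."""

    per_seed: pd.DataFrame    # columns: method, seed, metric, value
    summary: pd.DataFrame     # columns: method, metric, mean, sd
    errors: list = dataclasses.field(default_factory=list)


def _aggregate(per_seed: pd.DataFrame) -> pd.DataFrame:
    g = (per_seed.groupby(["method", "metric"])["value"]
         .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=0)))
         .reset_index())
    return g[["method", "metric", "mean", "sd"]]


def run_benchmark(blocks, labels, methods: Sequence[str],
                  spec: SplitSpec | None = None,
                  c_grid: Sequence[float] = (1, 5, 10, 15, 20, 25),
                  sigma_grid: Sequence[float] = (5e-5, 1e-4, 5e-4, 1e-3, 5e-3),
                  folds: int = 5,
                  deep_config: DeepMKLConfig | None = None,
                  deep_search: dict | None = None,
                  deep_budget: int = 4) -> MetricsReport:
    """Run the full evaluation protocol for the requested methods.

    For every seed in ``spec.seeds``: split stratified 30/70, tune on the
    training partition with ``folds``-fold CV (grid search over (C, sigma)
    for the SVM family; random search over ``deep_search`` for the deep
    family), refit on the whole training partition, predict the test
    partition and score it.  A failing method is recorded in ``errors`` and
    the run continues.
    """
    spec = spec or SplitSpec()
    Xs = [np.asarray(getattr(b, "values", b), dtype=float) for b in blocks]
    y = np.asarray(labels)
    rows, errors = [], []
    for seed in spec.seeds:
        tr, te = stratified_split(y, spec, seed)
        tr_blocks = [X[tr] for X in Xs]
        te_blocks = [X[te] for X in Xs]
        for method in methods:
            try:
                if method in STRATEGIES:
                    gs = grid_search(tr_blocks, y[tr], method, c_grid,
                                     sigma_grid, folds=folds, seed=seed)
                    clf = MKLClassifier(method, sigma=gs.best_sigma,
                                        cost=gs.best_c).fit(tr_blocks, y[tr])
                    y_pred = clf.predict(te_blocks)
                    scores = (clf.decision_function(te_blocks)
                              if np.unique(y).size == 2 else None)
                elif method in ("deepmkl", "crossmodal"):
                    cfg = deep_config or DeepMKLConfig()
                    if method == "crossmodal" and not cfg.cross_modal:
                        cfg = dataclasses.replace(
                            cfg, cross_modal=True,
                            hidden=list(cfg.hidden) + [cfg.hidden[-1]])
                    cfg = dataclasses.replace(cfg, seed=seed)
                    if deep_search:
                        cfg = tune_deep_mkl(tr_blocks, y[tr], deep_search,
                                            budget=deep_budget, folds=folds,
                                            seed=seed, base=cfg)
                    clf = DeepMKLClassifier(cfg).fit(tr_blocks, y[tr])
                    y_pred = clf.predict(te_blocks)
                    scores = (clf.decision_function(te_blocks)
                              if np.unique(y).size == 2 else None)
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception as exc:   # record and continue with other cells
                logger.warning("benchmark: %s failed on seed %d: %s",
                               method, seed, exc)
                errors.append({"method": method, "seed": seed,
                               "error": str(exc)})
                continue
            for metric, value in compute_metrics(y[te], y_pred, scores).items():
                rows.append({"method": method, "seed": seed,
                             "metric": metric, "value": value})
    per_seed = pd.DataFrame(rows)
    if per_seed.empty:
        raise RuntimeError(f"benchmark produced no results; errors: {errors}")
    return MetricsReport(per_seed, _aggregate(per_seed), errors)
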