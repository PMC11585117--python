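"""SVM classification on fused (meta-)kernels.

:class:`MKLClassifier` is the end-to-end estimator: it standardizes each
omics block with training statistics, computes one Gaussian (or linear)
kernel per block, fuses them with the configured strategy's simplex weights,
and trains a C-SVM on the precomputed meta-kernel.  At test time the
per-block cross-kernels are recomputed with the *training* kernel parameters
and fused with the *training* weights before the dual expansion is applied.

``strategy="concat"`` is the early-integration baseline: one kernel on the
feature-wise concatenation of the standardized blocks.

Multiclass problems are handled by one-vs-one voting (the standard reduction
for precomputed-kernel SVMs); SimpleMKL/SEMKL weight optimization itself is
restricted to binary tasks and raises otherwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import fusion
from .kernels import (KernelMatrix, KernelParams, check_psd, compute_kernel,
                      cross_kernel, standardize)

__all__ = [
    "SVMModel",
    "MKLClassifier",
    "GridSearchResult",
    "train_svm",
    "predict",
    "grid_search",
    "svm_concat",
]

STRATEGIES = ("concat", "naive", "statis", "simplemkl", "semkl")


@dataclasses.dataclass
class SVMModel:
    """Dual solution of a C-SVM trained on a precomputed kernel."""

    svc: SVC
    cost: float
    classes: np.ndarray
    train_samples: list[str]

    @property
    def dual_coef(self) -> np.ndarray:
        return self.svc.dual_coef_

    @property
    def support(self) -> np.ndarray:
        return self.svc.support_

    @property
    def bias(self) -> np.ndarray:
        return self.svc.intercept_


def train_svm(K_train, labels, cost: float = 1.0) -> SVMModel:
    """Train a C-SVM on a precomputed (meta-)kernel.

    ``K_train`` may be a :class:`~mokl.fusion.MetaKernel`,
    :class:`~mokl.kernels.KernelMatrix` or a plain square array.
    """
    if isinstance(K_train, fusion.MetaKernel):
        V, samples = K_train.values, K_train.samples
    elif isinstance(K_train, KernelMatrix):
        V, samples = K_train.values, K_train.samples
    else:
        V = np.asarray(K_train, dtype=float)
        samples = [str(i) for i in range(V.shape[0])]
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("train_svm: labels contain a single class")
    ok, min_eig = check_psd(V)
    if not ok:
        raise ValueError(f"train_svm: kernel not PSD (min eig {min_eig:.2e})")
    if cost <= 0:
        raise ValueError("cost must be positive")
    svc = SVC(C=cost, kernel="precomputed")
    svc.fit(V, y)
    return SVMModel(svc, float(cost), svc.classes_, list(samples))


def _values(block) -> np.ndarray:
    """Accept OmicsBlock or plain arrays."""
    return np.asarray(getattr(block, "values", block), dtype=float)


class MKLClassifier:
    """Multi-omics kernel-fusion SVM (scikit-learn-style estimator).

    Parameters
    ----------
    strategy : {"concat", "naive", "statis", "simplemkl", "semkl"}
        Kernel fusion strategy; ``concat`` concatenates features instead.
    sigma : float
        Inverse Gaussian kernel width, shared across blocks by default.
    cost : float
        SVM regularization constant C (also used inside the supervised
        weight optimizers).
    kernel : {"gaussian_rbf", "linear"}
    scale : bool
        Standardize each block with training statistics before the kernel.
    per_block_sigma : sequence of float, optional
        Overrides ``sigma`` per block.
    """

    def __init__(self, strategy: str = "naive", sigma: float = 1e-3,
                 cost: float = 1.0, kernel: str = "gaussian_rbf",
                 scale: bool = True,
                 per_block_sigma: Sequence[float] | None = None):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}")
        self.strategy = strategy
        self.sigma = float(sigma)
        self.cost = float(cost)
        self.kernel = kernel
        self.scale = scale
        self.per_block_sigma = per_block_sigma

    # -- fitting ------------------------------------------------------------

    def _params(self, m: int) -> KernelParams:
        if self.kernel == "linear":
            return KernelParams("linear")
        s = (self.per_block_sigma[m] if self.per_block_sigma is not None
             else self.sigma)
        return KernelParams("gaussian_rbf", s)

    def _standardized(self, blocks, fit: bool):
        Xs = []
        if fit:
            self.scalers_ = []
        for m, b in enumerate(blocks):
            X = _values(b)
            if fit:
                mean = X.mean(axis=0)
                sd = X.std(axis=0)
                sd = np.where(sd > 0, sd, 1.0)
                if not self.scale:
                    mean, sd = np.zeros_like(mean), np.ones_like(sd)
                self.scalers_.append((mean, sd))
            mean, sd = self.scalers_[m]
            Xs.append((X - mean) / sd)
        return Xs

    def fit(self, blocks, y) -> "MKLClassifier":
        y = np.asarray(y)
        Xs = self._standardized(blocks, fit=True)
        self.train_X_ = Xs
        if self.strategy == "concat":
            Xcat = np.hstack(Xs)
            K = compute_kernel(Xcat, self._params(0), source="concat")
            self.weights_ = fusion.KernelWeights(np.ones(1), "concat")
            self.kernels_ = None
            fused = K.values
        else:
            kernels = [compute_kernel(X, self._params(m), source=f"block{m}")
                       for m, X in enumerate(Xs)]
            self.weights_ = fusion.compute_weights(self.strategy, kernels,
                                                   labels=y, cost=self.cost)
            fused = fusion.combine(kernels, self.weights_).values
        self.model_ = train_svm(fused, y, self.cost)
        self.classes_ = self.model_.classes
        return self

    # -- prediction ---------------------------------------------------------

    def _cross(self, blocks_test) -> np.ndarray:
        Xs_test = self._standardized(blocks_test, fit=False)
        for Xtr, Xte in zip(self.train_X_, Xs_test):
            if Xtr.shape[1] != Xte.shape[1]:
                raise ValueError("test blocks do not match training features")
        if self.strategy == "concat":
            return cross_kernel(np.hstack(Xs_test), np.hstack(self.train_X_),
                                self._params(0)).values
        V = np.zeros((Xs_test[0].shape[0], self.train_X_[0].shape[0]))
        for m, (b, Xtr, Xte) in enumerate(zip(self.weights_.values,
                                              self.train_X_, Xs_test)):
            V += b * cross_kernel(Xte, Xtr, self._params(m)).values
        return V

    def decision_function(self, blocks_test) -> np.ndarray:
        return self.model_.svc.decision_function(self._cross(blocks_test))

    def predict(self, blocks_test) -> np.ndarray:
        return self.model_.svc.predict(self._cross(blocks_test))


def predict(model: MKLClassifier, blocks_test):
    """Labels and decision scores for new samples under a fitted model."""
    return model.predict(blocks_test), model.decision_function(blocks_test)


def svm_concat(blocks, labels, cost: float = 1.0, sigma: float = 1e-3,
               kernel: str = "gaussian_rbf") -> MKLClassifier:
    """Early-integration baseline: one kernel on concatenated features."""
    return MKLClassifier("concat", sigma=sigma, cost=cost,
                         kernel=kernel).fit(blocks, labels)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GridSearchResult:
    """Cross-validated accuracy per (C, sigma) cell and the selected cell.

    ``fold_kernel_hashes`` fingerprints every fold-training kernel actually
    used, keyed by ``(fold, sigma)``; they depend only on fold-training rows,
    which makes information leakage from validation folds detectable.
    """

    c_grid: list
    sigma_grid: list
    cv_accuracy: np.ndarray          # shape (len(c_grid), len(sigma_grid))
    best_c: float
    best_sigma: float
    seed: int
    fold_kernel_hashes: dict


def grid_search(blocks, labels, strategy: str = "naive",
                c_grid: Sequence[float] = (1, 5, 10, 15, 20, 25),
                sigma_grid: Sequence[float] = (5e-5, 1e-4, 5e-4, 1e-3, 5e-3),
                folds: int = 5, seed: int = 0,
                scale: bool = True) -> GridSearchResult:
    """Stratified k-fold grid search over (C, sigma) for one fusion strategy.

    All per-fold computation (standardization, kernels, weight optimization)
    uses fold-training rows only.  The selected cell attains the maximum mean
    CV accuracy; ties break to the smallest C, then the smallest sigma.
    """
    y = np.asarray(labels)
    c_grid = sorted(set(float(c) for c in c_grid))
    sigma_grid = sorted(set(float(s) for s in sigma_grid))
    if not c_grid or not sigma_grid:
        raise ValueError("empty hyperparameter grid")
    Xs = [_values(b) for b in blocks]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    for _, val_idx in splits:
        if np.unique(y[np.setdiff1d(np.arange(len(y)), val_idx)]).size < 2:
            raise ValueError("a CV fold lost a class; reduce folds")

    acc = np.zeros((len(c_grid), len(sigma_grid)))
    hashes: dict = {}
    for j, sig in enumerate(sigma_grid):
        fold_cache = []
        for f, (tr, va) in enumerate(splits):
            tr_blocks = [X[tr] for X in Xs]
            va_blocks = [X[va] for X in Xs]
            digest = hashlib.sha1()
            for Xtr in tr_blocks:
                Xst = standardize(Xtr, enabled=scale)
                digest.update(np.ascontiguousarray(
                    compute_kernel(Xst, KernelParams("gaussian_rbf", sig)).values
                ).tobytes())
            hashes[(f, sig)] = digest.hexdigest()
            fold_cache.append((tr_blocks, va_blocks, y[tr], y[va]))
        for i, C in enumerate(c_grid):
            scores = []
            for tr_blocks, va_blocks, y_tr, y_va in fold_cache:
                clf = MKLClassifier(strategy, sigma=sig, cost=C, scale=scale)
                clf.fit(tr_blocks, y_tr)
                scores.append(float(np.mean(clf.predict(va_blocks) == y_va)))
            acc[i, j] = float(np.mean(scores))

    best = np.argwhere(acc == acc.max())
    # lexicographically smallest (C index, sigma index) among the maxima
    bi, bj = min(map(tuple, best))
    return GridSearchResult(c_grid, sigma_grid, acc,
                            best_c=c_grid[bi], best_sigma=sigma_grid[bj],
                            seed=seed, fold_kernel_hashes=hashes)
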