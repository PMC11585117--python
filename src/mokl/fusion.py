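"""Kernel fusion: simplex weights beta and the meta-kernel K* = sum_m beta_m K^m.

Four strategies are provided:

``naive``
    Equal weights 1/M.  Every omic contributes equally.
``statis``
    STATIS-UMKL consensus: weights proportional to the leading eigenvector of
    the M x M matrix of pairwise Frobenius cosines between kernels, i.e. the
    convex combination maximizing average similarity to all input kernels.
    Unsupervised; works for any number of classes.
``simplemkl``
    SimpleMKL: minimize the SVM dual objective J(beta) over the simplex by
    projected/reduced gradient descent with an Armijo line search, re-solving
    the SVM dual at each step.  Binary labels only.
``semkl``
    SEMKL: alternate an SVM dual solve with the closed-form group-lasso
    update  beta_m <- ||w_m|| / sum_h ||w_h||,  where
    ||w_m||^2 = beta_m^2 alpha^T diag(y) K_m diag(y) alpha.  Binary only.

All strategies return weights on the probability simplex (nonnegative,
summing to one).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .kernels import KernelMatrix, center_kernel, cosine_normalize, check_psd

__all__ = [
    "KernelWeights",
    "MetaKernel",
    "combine",
    "naive_weights",
    "kernel_similarity",
    "statis_weights",
    "simplemkl_weights",
    "semkl_weights",
    "compute_weights",
]


@dataclasses.dataclass
class KernelWeights:
    """Simplex weights over M kernels plus convergence bookkeeping."""

    values: np.ndarray
    strategy: str
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("weights must be a non-empty vector")
        if np.any(v < -1e-12):
            raise ValueError("negative kernel weight")
        v = np.clip(v, 0.0, None)
        total = v.sum()
        if total <= 0:
            raise ValueError("weights sum to zero")
        self.values = v / total

    def to_dict(self) -> dict:
        return {"strategy": self.strategy, "beta": self.values.tolist(),
                "iterations": self.iterations, "converged": self.converged}


@dataclasses.dataclass
class MetaKernel:
    """Fused kernel K* together with the weights and input provenance."""

    kernel: KernelMatrix
    weights: KernelWeights
    sources: list[str]

    @property
    def values(self) -> np.ndarray:
        return self.kernel.values

    @property
    def samples(self) -> list[str]:
        return self.kernel.samples


def _check_aligned(kernels: Sequence[KernelMatrix]) -> None:
    if not kernels:
        raise ValueError("empty kernel list")
    ref = kernels[0].samples
    for K in kernels[1:]:
        if K.samples != ref:
            raise ValueError("kernels have mismatched sample order")


def combine(kernels: Sequence[KernelMatrix], weights: KernelWeights) -> MetaKernel:
    """Convex combination ``K* = sum_m beta_m K^m`` of sample-aligned kernels."""
    _check_aligned(kernels)
    if len(kernels) != weights.values.size:
        raise ValueError(f"{len(kernels)} kernels but {weights.values.size} weights")
    V = np.zeros_like(kernels[0].values)
    for b, K in zip(weights.values, kernels):
        V += b * K.values
    fused = KernelMatrix(V, list(kernels[0].samples), kernels[0].params,
                         source="+".join(K.source or "?" for K in kernels))
    ok, min_eig = check_psd(fused)
    if not ok:
        raise ValueError(f"fused kernel not PSD (min eig {min_eig:.2e})")
    return MetaKernel(fused, weights, [K.source for K in kernels])


def naive_weights(M: int) -> KernelWeights:
    """Equal weights 1/M over M kernels."""
    if M < 1:
        raise ValueError("need at least one kernel")
    return KernelWeights(np.full(M, 1.0 / M), "naive")


def _preprocess(kernels: Sequence[KernelMatrix],
                enabled: bool) -> list[KernelMatrix]:
    """Center then cosine-normalize, so similarity compares shape not scale."""
    if not enabled:
        return list(kernels)
    out = []
    for K in kernels:
        Kc = center_kernel(K) if not K.centered else K
        d = np.diag(Kc.values)
        if np.any(d <= 0):
            # centered kernels can have zero diagonal (constant block);
            # fall back to the raw kernel for that entry
            out.append(Kc)
        else:
            out.append(cosine_normalize(Kc))
    return out


def kernel_similarity(kernels: Sequence[KernelMatrix],
                      preprocess: bool = True) -> np.ndarray:
    """M x M matrix of Frobenius cosines ``<K_m, K_m'>_F / (|K_m| |K_m'|)``."""
    _check_aligned(kernels)
    ks = _preprocess(kernels, preprocess)
    mats = [K.values.ravel() for K in ks]
    norms = np.array([np.linalg.norm(v) for v in mats])
    if np.any(norms == 0):
        raise ValueError("zero-norm kernel in similarity computation")
    M = len(mats)
    C = np.empty((M, M))
    for i in range(M):
        for j in range(i, M):
            C[i, j] = C[j, i] = float(mats[i] @ mats[j]) / (norms[i] * norms[j])
    np.fill_diagonal(C, 1.0)
    return C


def statis_weights(kernels: Sequence[KernelMatrix],
                   preprocess: bool = True) -> KernelWeights:
    """STATIS-UMKL consensus weights.

    beta is the leading eigenvector of the Frobenius-cosine similarity matrix
    C, rescaled to sum to one.  For entrywise-nonnegative C the
    Perron-Frobenius theorem makes that eigenvector nonnegative up to sign.
    """
    if len(kernels) < 2:
        raise ValueError("statis_weights needs at least 2 kernels")
    C = kernel_similarity(kernels, preprocess=preprocess)
    eigval, eigvec = np.linalg.eigh(C)
    v = eigvec[:, -1]
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-8):
        raise ValueError("leading eigenvector of kernel similarity has mixed "
                         "signs; kernels are not jointly comparable")
    return KernelWeights(np.clip(v, 0.0, None), "statis")


# ---------------------------------------------------------------------------
# supervised wrappers (binary SVM dual inside the loop)
# ---------------------------------------------------------------------------

def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("supervised MKL weight optimization requires binary "
                         f"labels, got {classes.size} classes")
    return np.where(y == classes[1], 1.0, -1.0)


def _svm_dual(K: np.ndarray, y: np.ndarray, cost: float):
    """Solve the binary SVM dual on a precomputed kernel.

    Returns ``(ay, objective)`` where ``ay`` is the full-length vector of
    ``alpha_i y_i`` and ``objective = sum alpha - 0.5 ay^T K ay`` (the dual
    value J).
    """
    svc = SVC(C=cost, kernel="precomputed")
    svc.fit(K, y)
    ay = np.zeros(len(y))
    ay[svc.support_] = svc.dual_coef_[0]
    obj = float(np.abs(ay).sum() - 0.5 * ay @ K @ ay)
    return ay, obj


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sort algorithm)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(v.size) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.clip(v - theta, 0.0, None)


def simplemkl_weights(kernels: Sequence[KernelMatrix], labels, cost: float = 1.0,
                      tol: float = 1e-4, max_iter: int = 200,
                      preprocess: bool = True) -> KernelWeights:
    """SimpleMKL margin-based weight optimization (binary classification).

    Minimizes the SVM dual value J(beta) over the simplex.  By Danskin's
    theorem the gradient at the current dual optimum ``alpha*`` is

        dJ/dbeta_m = -0.5 * alpha*^T diag(y) K_m diag(y) alpha*,

    and each step projects ``beta - s * grad`` back onto the simplex, with an
    Armijo backtracking line search on J (each evaluation re-solves the SVM).
    Weights hitting zero are clamped by the projection.
    """
    _check_aligned(kernels)
    y = _check_binary(labels)
    M = len(kernels)
    if M == 1:
        return KernelWeights(np.ones(1), "simplemkl", iterations=0)
    ks = [K.values for K in _preprocess(kernels, preprocess)]
    beta = np.full(M, 1.0 / M)

    def dual_at(b):
        Kb = sum(bm * Km for bm, Km in zip(b, ks))
        return _svm_dual(Kb, y, cost)

    ay, J = dual_at(beta)
    iterations = 0
    converged = False
    step0 = 1.0
    for iterations in range(1, max_iter + 1):
        grad = np.array([-0.5 * ay @ Km @ ay for Km in ks])
        # scale-free step: normalize the gradient so step sizes transfer
        gnorm = np.linalg.norm(grad - grad.mean())
        if gnorm < 1e-12:
            converged = True   # flat objective (e.g. duplicate kernels)
            break
        step = step0
        accepted = False
        for _ in range(30):
            cand = _project_simplex(beta - step * grad / gnorm)
            if np.max(np.abs(cand - beta)) < 1e-15:
                break
            ay_c, J_c = dual_at(cand)
            # Armijo: require decrease proportional to the projected move
            if J_c <= J - 1e-4 * (grad @ (beta - cand)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        delta = np.max(np.abs(cand - beta))
        beta, ay, J = cand, ay_c, J_c
        step0 = min(max(step * 2.0, 1e-3), 10.0)
        if delta < tol:
            converged = True
            break
    return KernelWeights(beta, "simplemkl", iterations=iterations,
                         converged=converged)


def semkl_weights(kernels: Sequence[KernelMatrix], labels, cost: float = 1.0,
                  tol: float = 1e-4, max_iter: int = 200,
                  preprocess: bool = True) -> KernelWeights:
    """SEMKL weight optimization via the group-lasso/MKL equivalence (binary).

    Alternates (i) an SVM dual solve on the current fused kernel with (ii) the
    closed-form update ``beta_m <- ||w_m|| / sum_h ||w_h||`` with
    ``||w_m||^2 = beta_m^2 alpha^T diag(y) K_m diag(y) alpha``.  Blocks whose
    margin contribution vanishes receive weight zero (the limit of the
    update).
    """
    _check_aligned(kernels)
    y = _check_binary(labels)
    M = len(kernels)
    if M == 1:
        return KernelWeights(np.ones(1), "semkl", iterations=0)
    ks = [K.values for K in _preprocess(kernels, preprocess)]
    beta = np.full(M, 1.0 / M)
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        Kb = sum(bm * Km for bm, Km in zip(beta, ks))
        ay, _ = _svm_dual(Kb, y, cost)
        q = np.array([max(ay @ Km @ ay, 0.0) for Km in ks])
        wnorm = beta * np.sqrt(q)
        total = wnorm.sum()
        if total <= 0:
            raise ValueError("semkl_weights: all block margins vanished")
        new_beta = wnorm / total
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta < tol:
            converged = True
            break
    return KernelWeights(beta, "semkl", iterations=iterations,
                         converged=converged)


def compute_weights(strategy: str, kernels: Sequence[KernelMatrix],
                    labels=None, cost: float = 1.0, **kw) -> KernelWeights:
    """Dispatch by strategy name (``naive``, ``statis``, ``simplemkl``, ``semkl``)."""
    if strategy == "naive":
        return naive_weights(len(kernels))
    if strategy == "statis":
        return statis_weights(kernels, **kw)
    if strategy == "simplemkl":
        return simplemkl_weights(kernels, labels, cost, **kw)
    if strategy == "semkl":
        return semkl_weights(kernels, labels, cost, **kw)
    raise ValueError(f"unknown fusion strategy {strategy!r}")
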