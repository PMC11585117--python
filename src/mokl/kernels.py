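"""Kernel matrices: computation, centering, cosine normalization, validation.

The Gaussian radial-basis kernel follows the inverse-kernel-width convention

    k(x, y) = exp(-sigma * ||x - y||^2),

so larger ``sigma`` means a narrower kernel.  Features are expected to be
standardized (training-set statistics) before kernel computation so that one
sigma is meaningful across omics with heterogeneous scales; see
:func:`standardize`.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.preprocessing import KernelCenterer

logger = logging.getLogger("mokl")

__all__ = [
    "KernelParams",
    "KernelMatrix",
    "CrossKernel",
    "standardize",
    "gaussian_kernel",
    "linear_kernel",
    "compute_kernel",
    "center_kernel",
    "cosine_normalize",
    "cross_kernel",
    "check_psd",
    "write_kernel_csv",
    "read_kernel_csv",
]

#: relative PSD tolerance used throughout (eigenvalues >= -tol * max_eig pass)
PSD_RTOL = 1e-8


@dataclasses.dataclass(frozen=True)
class KernelParams:
    """Kernel function name plus its parameters.

    ``sigma`` is the inverse kernel width of the Gaussian RBF kernel and is
    ignored for the linear kernel.
    """

    function: Literal["gaussian_rbf", "linear"] = "gaussian_rbf"
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.function not in ("gaussian_rbf", "linear"):
            raise ValueError(f"unknown kernel function {self.function!r}")
        if self.function == "gaussian_rbf":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian_rbf requires sigma > 0")


@dataclasses.dataclass
class KernelMatrix:
    """An n x n similarity matrix tied to the kernel that produced it."""

    values: np.ndarray
    samples: list[str]
    params: KernelParams
    source: str = ""
    centered: bool = False
    cosine_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match sample IDs")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > 1e-10:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")
        # enforce exact symmetry against round-off drift
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.samples)

    def copy(self) -> "KernelMatrix":
        return KernelMatrix(self.values.copy(), list(self.samples), self.params,
                            self.source, self.centered, self.cosine_normalized)


@dataclasses.dataclass
class CrossKernel:
    """n_test x n_train kernel evaluations, columns in training sample order."""

    values: np.ndarray
    test_samples: list[str]
    train_samples: list[str]
    params: KernelParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.test_samples), len(self.train_samples)):
            raise ValueError("cross-kernel shape mismatch")


def standardize(X_train: np.ndarray,
                X_test: np.ndarray | None = None,
                enabled: bool = True):
    """Zero-mean, unit-variance scaling using *training* statistics only.

    Constant features get unit divisor (they stay constant, contributing
    nothing to distances).  Returns the scaled training matrix, or a
    ``(train, test)`` pair when ``X_test`` is given.
    """
    X_train = np.asarray(X_train, dtype=float)
    if not enabled:
        return X_train if X_test is None else (X_train, np.asarray(X_test, float))
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xt = (X_train - mean) / sd
    if X_test is None:
        return Xt
    return Xt, (np.asarray(X_test, dtype=float) - mean) / sd


def _check_finite(X: np.ndarray, what: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{what}: non-finite input")
    return X


def gaussian_kernel(X: np.ndarray, sigma: float,
                    samples: list[str] | None = None,
                    source: str = "") -> KernelMatrix:
    """Gaussian RBF kernel ``exp(-sigma * ||x_i - x_j||^2)`` on the rows of X."""
    X = _check_finite(X, "gaussian_kernel")
    params = KernelParams("gaussian_rbf", float(sigma))
    sq = euclidean_distances(X, squared=True)
    K = np.exp(-sigma * sq)
    np.fill_diagonal(K, 1.0)
    if samples is None:
        samples = [str(i) for i in range(X.shape[0])]
    return KernelMatrix(K, list(samples), params, source)


def linear_kernel(X: np.ndarray, samples: list[str] | None = None,
                  source: str = "") -> KernelMatrix:
    """Linear kernel ``K = X X^T``."""
    X = _check_finite(X, "linear_kernel")
    K = X @ X.T
    if samples is None:
        samples = [str(i) for i in range(X.shape[0])]
    return KernelMatrix(K, list(samples), KernelParams("linear"), source)


def compute_kernel(X: np.ndarray, params: KernelParams,
                   samples: list[str] | None = None,
                   source: str = "") -> KernelMatrix:
    """Dispatch on ``params.function``."""
    if params.function == "gaussian_rbf":
        return gaussian_kernel(X, params.sigma, samples, source)
    return linear_kernel(X, samples, source)


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """Double-center a kernel: ``K~ = H K H`` with ``H = I - 11^T/n``.

    Centering corresponds to translating the implicit feature map to zero
    mean.  Idempotent; re-centering an already centered kernel only logs a
    warning.
    """
    if K.centered:
        logger.warning("center_kernel: kernel already centered; no-op")
        return K.copy()
    Kc = KernelCenterer().fit_transform(K.values)
    out = K.copy()
    out.values = 0.5 * (Kc + Kc.T)
    out.centered = True
    return out


def cosine_normalize(K: KernelMatrix) -> KernelMatrix:
    """Scale to unit diagonal: ``K'_ij = K_ij / sqrt(K_ii K_jj)``.

    Makes kernels from blocks with different overall scales comparable before
    fusion.  Requires a strictly positive diagonal; idempotent.
    """
    d = np.diag(K.values).copy()
    if np.any(d <= 0):
        raise ValueError("cosine_normalize: non-positive diagonal entry")
    s = 1.0 / np.sqrt(d)
    out = K.copy()
    out.values = K.values * np.outer(s, s)
    np.fill_diagonal(out.values, 1.0)
    out.cosine_normalized = True
    return out


def cross_kernel(X_test: np.ndarray, X_train: np.ndarray, params: KernelParams,
                 test_samples: list[str] | None = None,
                 train_samples: list[str] | None = None) -> CrossKernel:
    """Kernel evaluations between test rows and training rows.

    Uses the identical convention as the corresponding training kernel, so
    ``cross_kernel(X, X, p).values == compute_kernel(X, p).values``.
    """
    X_test = _check_finite(X_test, "cross_kernel")
    X_train = _check_finite(X_train, "cross_kernel")
    if X_test.shape[1] != X_train.shape[1]:
        raise ValueError("cross_kernel: feature dimension mismatch")
    if params.function == "gaussian_rbf":
        V = np.exp(-params.sigma * euclidean_distances(X_test, X_train,
                                                       squared=True))
    else:
        V = X_test @ X_train.T
    if test_samples is None:
        test_samples = [str(i) for i in range(X_test.shape[0])]
    if train_samples is None:
        train_samples = [str(i) for i in range(X_train.shape[0])]
    return CrossKernel(V, list(test_samples), list(train_samples), params)


def check_psd(K: KernelMatrix | np.ndarray,
              tol: float = PSD_RTOL) -> tuple[bool, float]:
    """Positive semi-definiteness check with a relative tolerance.

    Returns ``(is_psd, min_eigenvalue)``; PSD means
    ``min_eig >= -tol * max(max_eig, 1)``.
    """
    V = K.values if isinstance(K, KernelMatrix) else np.asarray(K, float)
    eig = np.linalg.eigvalsh(0.5 * (V + V.T))
    min_eig, max_eig = float(eig[0]), float(eig[-1])
    return min_eig >= -tol * max(max_eig, 1.0), min_eig


def write_kernel_csv(K: KernelMatrix, path: str | Path) -> None:
    """Export as a square CSV with sample IDs as header and index."""
    pd.DataFrame(K.values, index=K.samples, columns=K.samples).to_csv(path)


def read_kernel_csv(path: str | Path, params: KernelParams | None = None,
                    source: str = "") -> KernelMatrix:
    """Import a square kernel CSV written by :func:`write_kernel_csv`."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row and column sample IDs differ")
    return KernelMatrix(df.to_numpy(dtype=float),
                        [str(s) for s in df.index],
                        params or KernelParams("linear"), source)
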