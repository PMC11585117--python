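"""Deep multiple kernel learning: kernel-PCA dense embeddings per omic fused
by a multi-modal feedforward network.

Each omic is first embedded by kernel PCA on its (uncentered) Gaussian
kernel: the kernel is double-centered, eigendecomposed, and the top-d
positive components kept, giving training scores ``z_il = sqrt(lambda_l) *
v_il``.  A per-omic subnetwork of fully connected blocks (Linear ->
LeakyReLU -> Dropout -> BatchNorm) then learns a representation from each
embedding; the M representations are fused by concatenation, sum, or a
weighted sum with M learnable scalars; two further fully connected layers
perform the classification.  The cross-modal variant adds, before fusion,
one dedicated cross-connection layer per ordered omic pair so that each
omic's final subnetwork layer sees the other omics' intermediate
representations.

Training minimizes cross-entropy with Adam; all randomness (initialization,
shuffling, dropout) flows from the config seed.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from sklearn.preprocessing import KernelCenterer

from ._nn import Adam, Block, Dense, cross_entropy, softmax
from .kernels import (KernelMatrix, KernelParams, compute_kernel, cross_kernel,
                      standardize)

__all__ = [
    "KPCAEmbedder",
    "DeepMKLConfig",
    "DeepMKLNet",
    "DeepMKLModel",
    "fit_kpca",
    "transform_kpca",
    "build_network",
    "train_deep_mkl",
    "tune_deep_mkl",
    "DeepMKLClassifier",
]


# ---------------------------------------------------------------------------
# kernel PCA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KPCAEmbedder:
    """Kernel-PCA projection fitted on a training kernel.

    ``eigvals``/``eigvecs`` are the top-d components of the double-centered
    kernel (descending); ``centerer`` stores the training row/grand means
    needed to center test cross-kernels consistently.
    """

    params: KernelParams
    eigvals: np.ndarray            # (d,) descending, all > 0
    eigvecs: np.ndarray            # (n, d) orthonormal columns
    centerer: KernelCenterer
    train_samples: list[str]
    train_X: np.ndarray | None = None   # standardized training matrix, if known

    @property
    def d(self) -> int:
        return self.eigvals.size

    @property
    def scores(self) -> np.ndarray:
        """Training embedding: ``z_il = sqrt(lambda_l) v_il``."""
        return self.eigvecs * np.sqrt(self.eigvals)


def fit_kpca(K: KernelMatrix, d: int,
             train_X: np.ndarray | None = None) -> KPCAEmbedder:
    """Fit kernel PCA on an uncentered kernel, keeping the top-d components.

    Raises if fewer than ``d`` strictly positive eigenvalues exist.
    """
    n = K.n
    if not 0 < d < n:
        raise ValueError(f"need 0 < d < n, got d={d}, n={n}")
    if K.centered:
        raise ValueError("fit_kpca expects the uncentered kernel")
    centerer = KernelCenterer().fit(K.values)
    Kc = centerer.transform(K.values)
    Kc = 0.5 * (Kc + Kc.T)
    eigvals, eigvecs = np.linalg.eigh(Kc)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    tol = max(eigvals[0], 0.0) * 1e-12
    n_pos = int(np.sum(eigvals > tol))
    if n_pos < d:
        raise ValueError(f"only {n_pos} positive eigenvalues, cannot keep d={d}")
    return KPCAEmbedder(K.params, eigvals[:d].copy(),
                        np.ascontiguousarray(eigvecs[:, :d]),
                        centerer, list(K.samples),
                        None if train_X is None else np.asarray(train_X, float))


def transform_kpca(emb: KPCAEmbedder, X_test=None,
                   K_cross: np.ndarray | None = None) -> np.ndarray:
    """Project test points: ``z = K~_test v_l / sqrt(lambda_l)``.

    Either pass ``X_test`` (requires the embedder to have been fitted with
    ``train_X``) or a precomputed ``K_cross`` of test x train kernel values.
    The cross-kernel is centered with the stored training means.
    """
    if K_cross is None:
        if emb.train_X is None:
            raise ValueError("embedder has no training matrix; pass K_cross")
        X_test = np.asarray(X_test, dtype=float)
        if X_test.shape[1] != emb.train_X.shape[1]:
            raise ValueError("test features do not match training features")
        K_cross = cross_kernel(X_test, emb.train_X, emb.params).values
    Kc = emb.centerer.transform(np.asarray(K_cross, dtype=float))
    return Kc @ (emb.eigvecs / np.sqrt(emb.eigvals))


# ---------------------------------------------------------------------------
# network configuration and architecture
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DeepMKLConfig:
    """Hyperparameters of the (cross-modal) Deep MKL architecture.

    ``hidden`` are the per-omic subnetwork layer widths (three entries, or
    four when ``cross_modal`` since each cross-connection is an additional
    layer); ``head_hidden`` is the width of the penultimate classification
    layer.  ``sigma`` and ``n_components`` configure the kernel-PCA embedding
    step when the config is used end to end.
    """

    hidden: list = dataclasses.field(default_factory=lambda: [200, 200, 100])
    head_hidden: int = 64
    fusion: str = "concat"          # concat | sum | weighted_sum
    cross_modal: bool = False
    dropout: float = 0.3
    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    sigma: float = 1e-3
    n_components: int = 8

    def __post_init__(self) -> None:
        if self.fusion not in ("concat", "sum", "weighted_sum"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        want = 4 if self.cross_modal else 3
        if len(self.hidden) != want:
            raise ValueError(f"{'cross-modal ' if self.cross_modal else ''}"
                             f"subnetworks use {want} layers, got "
                             f"{len(self.hidden)} widths")


class DeepMKLNet:
    """Multi-modal feedforward network over per-omic embeddings.

    Structure (per omic): three fully connected blocks; cross-modal adds a
    fourth whose input is the concatenation of the omic's own third-layer
    output with one dedicated cross-layer per other omic.  Fusion then
    combines the M subnetwork outputs and a two-layer head produces class
    logits (block + plain linear output layer).
    """

    def __init__(self, M: int, d_per_omic: Sequence[int], n_classes: int,
                 config: DeepMKLConfig):
        if M < 1:
            raise ValueError("need at least one omic")
        if len(d_per_omic) != M:
            raise ValueError("d_per_omic must have one entry per omic")
        self.M, self.n_classes, self.config = M, int(n_classes), config
        rng = np.random.default_rng(config.seed)
        h = list(config.hidden)
        depth = 3                     # blocks before any cross-connection
        self.subnets: list[list[Block]] = []
        for m in range(M):
            widths = [int(d_per_omic[m])] + h[:depth]
            self.subnets.append([Block(widths[i], widths[i + 1], config.dropout, rng)
                                 for i in range(depth)])
        self.cross: list[list[Block | None]] = []
        self.final_blocks: list[Block] = []
        if config.cross_modal:
            # cross[m][s]: layer carrying omic s's depth-3 output into omic m
            for m in range(M):
                row = [Block(h[2], h[2], config.dropout, rng) if s != m else None
                       for s in range(M)]
                self.cross.append(row)
            for m in range(M):
                self.final_blocks.append(Block(h[2] * M, h[3], config.dropout, rng))
            out_width = h[3]
        else:
            out_width = h[2]
        if config.fusion == "concat":
            fused_width = out_width * M
        else:
            fused_width = out_width   # equal widths guaranteed by shared hidden
        self.fusion_scalars = (np.ones(M) if config.fusion == "weighted_sum"
                               else None)
        self.fusion_scalar_grads = (np.zeros(M) if self.fusion_scalars is not None
                                    else None)
        self.head_block = Block(fused_width, config.head_hidden, config.dropout, rng)
        self.head_out = Dense(config.head_hidden, self.n_classes, rng)
        self.params, self.grads = [], []
        for blocks in self.subnets:
            for b in blocks:
                self.params += b.params
                self.grads += b.grads
        for row in self.cross:
            for b in row:
                if b is not None:
                    self.params += b.params
                    self.grads += b.grads
        for b in self.final_blocks:
            self.params += b.params
            self.grads += b.grads
        if self.fusion_scalars is not None:
            self.params.append(self.fusion_scalars)
            self.grads.append(self.fusion_scalar_grads)
        self.params += self.head_block.params + self.head_out.params
        self.grads += self.head_block.grads + self.head_out.grads

    # -- forward / backward -------------------------------------------------

    def forward(self, xs: Sequence[np.ndarray], train: bool = False) -> np.ndarray:
        if len(xs) != self.M:
            raise ValueError(f"expected {self.M} embeddings, got {len(xs)}")
        outs = []
        for m, x in enumerate(xs):
            hcur = np.asarray(x, dtype=float)
            for b in self.subnets[m]:
                hcur = b.forward(hcur, train)
            outs.append(hcur)
        if self.config.cross_modal:
            self._cross_cache = outs
            merged = []
            for m in range(self.M):
                parts = [outs[m]]
                for s in range(self.M):
                    if s != m:
                        parts.append(self.cross[m][s].forward(outs[s], train))
                merged.append(self.final_blocks[m].forward(
                    np.hstack(parts), train))
            outs = merged
        self._fused_inputs = outs
        if self.config.fusion == "concat":
            fused = np.hstack(outs)
        elif self.config.fusion == "sum":
            fused = np.sum(outs, axis=0)
        else:
            fused = np.sum([w * o for w, o in zip(self.fusion_scalars, outs)],
                           axis=0)
        hidden = self.head_block.forward(fused, train)
        return self.head_out.forward(hidden, train)

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        """Backpropagate; returns gradients w.r.t. the M input embeddings."""
        d = self.head_block.backward(self.head_out.backward(dlogits))
        outs = self._fused_inputs
        if self.config.fusion == "concat":
            widths = [o.shape[1] for o in outs]
            cuts = np.cumsum(widths)[:-1]
            douts = list(np.split(d, cuts, axis=1))
        elif self.config.fusion == "sum":
            douts = [d.copy() for _ in range(self.M)]
        else:
            for m, o in enumerate(outs):
                self.fusion_scalar_grads[m] += float((d * o).sum())
            douts = [self.fusion_scalars[m] * d for m in range(self.M)]
        if self.config.cross_modal:
            pre = self._cross_cache          # depth-3 outputs per omic
            dpre = [np.zeros_like(p) for p in pre]
            w3 = pre[0].shape[1]
            for m in range(self.M):
                dmerged = self.final_blocks[m].backward(douts[m])
                parts = np.split(dmerged, np.arange(w3, dmerged.shape[1], w3),
                                 axis=1)
                dpre[m] += parts[0]
                k = 1
                for s in range(self.M):
                    if s != m:
                        dpre[s] += self.cross[m][s].backward(parts[k])
                        k += 1
            douts = dpre
        dxs = []
        for m in range(self.M):
            dcur = douts[m]
            for b in reversed(self.subnets[m]):
                dcur = b.backward(dcur)
            dxs.append(dcur)
        return dxs

    # -- utilities ----------------------------------------------------------

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def predict_proba(self, xs: Sequence[np.ndarray]) -> np.ndarray:
        return softmax(self.forward(xs, train=False))

    def input_gradients(self, xs: Sequence[np.ndarray],
                        class_idx: np.ndarray) -> list[np.ndarray]:
        """d(logit of ``class_idx``)/d(input) per omic, eval mode."""
        logits = self.forward(xs, train=False)
        seed = np.zeros_like(logits)
        seed[np.arange(len(class_idx)), np.asarray(class_idx, int)] = 1.0
        self.zero_grad()
        dxs = self.backward(seed)
        self.zero_grad()
        return dxs


@dataclasses.dataclass
class DeepMKLModel:
    """A (possibly trained) network plus its config and loss trace."""

    net: DeepMKLNet
    config: DeepMKLConfig
    classes: np.ndarray | None = None
    loss_trace: list = dataclasses.field(default_factory=list)
    embedders: list | None = None     # per-omic KPCAEmbedder when fitted end-to-end

    @property
    def trained(self) -> bool:
        return len(self.loss_trace) > 0


def build_network(config: DeepMKLConfig, M: int, d_per_omic: Sequence[int],
                  n_classes: int) -> DeepMKLModel:
    """Construct an untrained Deep MKL model for M omics."""
    return DeepMKLModel(DeepMKLNet(M, d_per_omic, n_classes, config), config)


def train_deep_mkl(embeddings: Sequence[np.ndarray], labels,
                   config: DeepMKLConfig,
                   model: DeepMKLModel | None = None) -> DeepMKLModel:
    """Train (cross-modal) Deep MKL on per-omic embedding matrices.

    ``labels`` may be arbitrary hashables; the recorded class order is
    first-appearance.  Minimizes cross-entropy with Adam; aborts on a
    non-finite loss.
    """
    embeddings = [np.asarray(e, dtype=float) for e in embeddings]
    n = embeddings[0].shape[0]
    if any(e.shape[0] != n for e in embeddings):
        raise ValueError("embeddings are not sample-aligned")
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    y = np.searchsorted(classes, y_raw)
    if model is None:
        model = build_network(config, len(embeddings),
                              [e.shape[1] for e in embeddings], classes.size)
    model.classes = classes
    net = model.net
    opt = Adam(net.params, net.grads, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)  # shuffling stream
    batch = max(2, min(config.batch_size, n))
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            if idx.size < 2:
                continue              # batch norm needs >= 2 rows
            net.zero_grad()
            logits = net.forward([e[idx] for e in embeddings], train=True)
            loss, dlogits = cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss})")
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.loss_trace.append(epoch_loss / max(n_batches, 1))
    return model


def tune_deep_mkl(blocks_train, labels, search_space: dict,
                  budget: int = 8, folds: int = 5, seed: int = 0,
                  base: DeepMKLConfig | None = None) -> DeepMKLConfig:
    """Random-search 5-fold CV over Deep MKL hyperparameters.

    ``search_space`` maps :class:`DeepMKLConfig` field names to candidate
    lists.  When ``budget`` covers the whole grid the search is exhaustive;
    otherwise ``budget`` distinct configurations are sampled with the given
    seed.  Kernel-PCA embedders are refit on fold-training rows only.
    Returns the config with the best mean CV accuracy, with ``n_evaluated``
    recorded on the returned object.
    """
    from sklearn.model_selection import StratifiedKFold

    if budget < 1:
        raise ValueError("search budget must be >= 1")
    if not search_space:
        raise ValueError("empty search space")
    keys = sorted(search_space)
    grid = list(itertools.product(*(search_space[k] for k in keys)))
    rng = np.random.default_rng(seed)
    if budget < len(grid):
        picks = rng.choice(len(grid), size=budget, replace=False)
        grid = [grid[i] for i in sorted(picks)]
    base = base or DeepMKLConfig()
    y = np.asarray(labels)
    Xs = [np.asarray(getattr(b, "values", b), dtype=float) for b in blocks_train]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    best_cfg, best_acc = None, -np.inf
    for combo in grid:
        cfg = dataclasses.replace(base, **dict(zip(keys, combo)))
        scores = []
        try:
            for tr, va in splits:
                clf = DeepMKLClassifier(cfg)
                clf.fit([X[tr] for X in Xs], y[tr])
                scores.append(float(np.mean(clf.predict([X[va] for X in Xs])
                                            == y[va])))
        except ValueError:
            continue                   # e.g. n_components too large for fold
        acc = float(np.mean(scores))
        if acc > best_acc:
            best_cfg, best_acc = cfg, acc
    if best_cfg is None:
        raise ValueError("no feasible configuration in the search space")
    best_cfg.n_evaluated = len(grid)
    best_cfg.cv_accuracy = best_acc
    return best_cfg


class DeepMKLClassifier:
    """End-to-end Deep MKL: standardize -> Gaussian kernel -> KPCA -> network.

    A thin pipeline mirroring :class:`~mokl.svm.MKLClassifier`'s interface so
    the benchmark harness can treat both families uniformly.
    """

    def __init__(self, config: DeepMKLConfig, scale: bool = True):
        self.config = config
        self.scale = scale

    def fit(self, blocks, y) -> "DeepMKLClassifier":
        Xs = [np.asarray(getattr(b, "values", b), dtype=float) for b in blocks]
        self.scalers_ = []
        embeddings = []
        self.embedders_ = []
        params = KernelParams("gaussian_rbf", self.config.sigma)
        for X in Xs:
            mean = X.mean(axis=0)
            sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
            if not self.scale:
                mean, sd = np.zeros_like(mean), np.ones_like(sd)
            self.scalers_.append((mean, sd))
            Xst = (X - mean) / sd
            K = compute_kernel(Xst, params)
            emb = fit_kpca(K, self.config.n_components, train_X=Xst)
            self.embedders_.append(emb)
            embeddings.append(emb.scores)
        self.embeddings_ = embeddings
        self.model_ = train_deep_mkl(embeddings, y, self.config)
        self.classes_ = self.model_.classes
        self.model_.embedders = self.embedders_
        return self

    def _embed(self, blocks_test) -> list[np.ndarray]:
        out = []
        for (mean, sd), emb, b in zip(self.scalers_, self.embedders_, blocks_test):
            X = (np.asarray(getattr(b, "values", b), dtype=float) - mean) / sd
            out.append(transform_kpca(emb, X))
        return out

    def predict_proba(self, blocks_test) -> np.ndarray:
        return self.model_.net.predict_proba(self._embed(blocks_test))

    def predict(self, blocks_test) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(blocks_test), axis=1)]

    def decision_function(self, blocks_test) -> np.ndarray:
        proba = self.predict_proba(blocks_test)
        if self.classes_.size == 2:
            return proba[:, 1]
        return proba
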