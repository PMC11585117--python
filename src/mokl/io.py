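"""Reading and writing omics tables, labels, run configs and benchmark reports.

An omics *block* is one assay's samples x features numeric matrix (e.g. mRNA
expression, DNA methylation or miRNA counts restricted to a common patient
set).  All blocks in a run share one sample axis; classification labels are
carried separately.  Loaders refuse missing values by default -- the expected
inputs are fully preprocessed matrices -- with optional per-feature mean
imputation behind an explicit flag.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mokl")

__all__ = [
    "OmicsBlock",
    "LabelVector",
    "RunConfig",
    "load_omics",
    "load_labels",
    "align_blocks",
    "write_report",
    "read_config",
]


@dataclasses.dataclass
class OmicsBlock:
    """One omic's numeric data matrix with sample and feature identifiers.

    Attributes
    ----------
    name : str
        Short block identifier (e.g. ``"mrna"``).
    samples : list of str
        Ordered sample IDs, one per matrix row.
    features : list of str
        Ordered feature IDs, one per matrix column; unique within the block.
    values : ndarray of shape (n_samples, n_features)
        Real-valued measurements; no missing values.
    """

    name: str
    samples: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"block {self.name!r} needs at least 2 samples, got {n}")
        if len(self.samples) != n or len(self.features) != p:
            raise ValueError("ID lists do not match matrix shape")
        if len(set(self.samples)) != n:
            raise ValueError(f"duplicate sample IDs in block {self.name!r}")
        if len(set(self.features)) != p:
            raise ValueError(f"duplicate feature IDs in block {self.name!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"block {self.name!r} contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        """Return a copy restricted to ``sample_ids`` in the given order."""
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return OmicsBlock(self.name, list(sample_ids), list(self.features),
                          self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.features)


@dataclasses.dataclass
class LabelVector:
    """Per-sample categorical class labels with a fixed, recorded class order."""

    samples: list[str]
    labels: list
    classes: list = None

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.labels):
            raise ValueError("samples and labels differ in length")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs in labels")
        if self.classes is None:
            # first-appearance order keeps the class encoding deterministic
            seen = {}
            for y in self.labels:
                seen.setdefault(y, None)
            self.classes = list(seen)
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside declared classes: {unknown}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def encoded(self) -> np.ndarray:
        """Integer codes following the recorded class order."""
        code = {c: i for i, c in enumerate(self.classes)}
        return np.array([code[y] for y in self.labels], dtype=int)

    def subset(self, sample_ids: Sequence[str]) -> "LabelVector":
        pos = {s: i for i, s in enumerate(self.samples)}
        return LabelVector(list(sample_ids),
                           [self.labels[pos[s]] for s in sample_ids],
                           list(self.classes))


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible run needs: kernels, strategy, grids, splits."""

    blocks: dict            # name -> {"path": ..., "orientation": ...}
    labels_path: str | None = None
    kernel: dict = dataclasses.field(
        default_factory=lambda: {"function": "gaussian_rbf"})
    strategy: str = "naive"
    c_grid: list = dataclasses.field(default_factory=lambda: [1, 5, 10, 15, 20, 25])
    sigma_grid: list = dataclasses.field(
        default_factory=lambda: [5e-5, 1e-4, 5e-4, 1e-3, 5e-3])
    deep: dict = dataclasses.field(default_factory=dict)
    train_fraction: float = 0.30
    seeds: list = dataclasses.field(default_factory=lambda: [0, 1, 2, 3, 4])
    metrics: list = dataclasses.field(default_factory=list)
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("config declares no omics blocks")
        if not self.c_grid or not self.sigma_grid:
            raise ValueError("hyperparameter grids must be non-empty")

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in reports."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_omics(path: str | Path,
               orientation: Literal["samples_rows", "features_rows"] = "samples_rows",
               name: str | None = None,
               impute_mean: bool = False) -> OmicsBlock:
    """Read a delimited samples x features table into an :class:`OmicsBlock`.

    The file must have one header row and one leading ID column; the delimiter
    is inferred from the extension (``.tsv``/``.txt`` -> tab, else comma).
    ``orientation="features_rows"`` transposes on load so that in-memory
    samples are always rows.  Missing values raise unless ``impute_mean`` is
    set, in which case each feature's mean fills its gaps.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    if orientation == "features_rows":
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample IDs {dup}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if np.isnan(values).any():
        if not impute_mean:
            raise ValueError(f"{path}: missing values (pass impute_mean=True "
                             "to fill with per-feature means)")
        col_mean = np.nanmean(values, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(values))
        values[nan_r, nan_c] = col_mean[nan_c]
        logger.info("%s: imputed %d missing values", path, len(nan_r))
    return OmicsBlock(name or path.stem, [str(s) for s in df.index],
                      [str(f) for f in df.columns], values)


def load_labels(path: str | Path) -> LabelVector:
    """Read a two-column (sample_id, label) CSV into a :class:`LabelVector`."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id,label")
    return LabelVector([str(s) for s in df.iloc[:, 0]], list(df.iloc[:, 1]))


def align_blocks(blocks: Sequence[OmicsBlock],
                 labels: LabelVector) -> tuple[list[OmicsBlock], LabelVector]:
    """Restrict all blocks and the labels to their common samples.

    The canonical order is the label vector's order filtered to the
    intersection; dropped samples are logged.  Idempotent.
    """
    common = set(labels.samples)
    for b in blocks:
        common &= set(b.samples)
    if len(common) < 2:
        raise ValueError("fewer than 2 samples shared across blocks and labels")
    order = [s for s in labels.samples if s in common]
    dropped = sorted(set(labels.samples) - common)
    for b in blocks:
        dropped += sorted(set(b.samples) - common)
    if dropped:
        logger.info("align_blocks: dropped %d sample entries: %s",
                    len(dropped), sorted(set(dropped)))
    return [b.subset(order) for b in blocks], labels.subset(order)


def write_report(report: pd.DataFrame, path: str | Path,
                 config_digest: str = "", seeds: Sequence[int] = ()) -> None:
    """Persist a benchmark report as CSV plus a JSON sidecar with provenance.

    ``report`` must carry columns ``method, metric, mean, sd``.
    """
    required = {"method", "metric", "mean", "sd"}
    if report.empty or not required.issubset(report.columns):
        raise ValueError("report must be non-empty with columns "
                         "method, metric, mean, sd")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(path, index=False)
    sidecar = {
        "config_digest": config_digest,
        "seeds": list(seeds),
        "results": report.to_dict(orient="records"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
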