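"""Loading, validation and harmonization of expression dataset collections.

A *collection* is a set of independently normalized, log-scale expression
matrices (genes x samples) that will be clustered separately and only then
compared. No between-dataset normalization is performed here by design; the
only transform offered is gene-wise batch mean centering, used for comparison
experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "Collection",
    "ParseError",
    "load_dataset",
    "load_collection",
    "harmonize",
    "harmonization_report",
    "batch_mean_center",
]


class ParseError(ValueError):
    """A cell in a delimited expression matrix could not be read as a number."""


@dataclass
class ExpressionDataset:
    """One dataset: log-scale expression values with gene/sample labels.

    values has shape (n_genes, n_samples); rows follow gene_symbols, columns
    follow sample_ids.
    """

    dataset_id: str
    gene_symbols: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.gene_symbols = list(self.gene_symbols)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"{self.dataset_id}: values must be 2-D")
        if self.values.shape != (len(self.gene_symbols), len(self.sample_ids)):
            raise ValueError(
                f"{self.dataset_id}: shape {self.values.shape} does not match "
                f"{len(self.gene_symbols)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError(f"{self.dataset_id}: duplicate gene symbols")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"{self.dataset_id}: duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.dataset_id}: non-finite values after loading")

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_symbols)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"{self.dataset_id}: genes not present: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes) -> "ExpressionDataset":
        """Restrict to `genes` (order as given); genes must all be present."""
        idx = self.gene_index(genes)
        return replace(self, gene_symbols=list(genes), values=self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_symbols, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, dataset_id: str, frame: pd.DataFrame) -> "ExpressionDataset":
        return cls(dataset_id, list(frame.index), list(frame.columns), frame.to_numpy(float))


@dataclass
class Collection:
    """Datasets plus the ordered feature set used for downstream analysis."""

    datasets: list[ExpressionDataset]
    feature_set: list[str] = field(default_factory=list)
    min_coverage: float = 0.0

    def __post_init__(self):
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset_id values must be unique within a collection")
        if self.feature_set:
            n = len(self.feature_set)
            for d in self.datasets:
                cov = len(set(d.gene_symbols) & set(self.feature_set)) / n
                if cov < self.min_coverage:
                    raise ValueError(
                        f"{d.dataset_id}: coverage {cov:.3f} below min_coverage "
                        f"{self.min_coverage}"
                    )

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self):
        return len(self.datasets)

    def __getitem__(self, dataset_id: str) -> ExpressionDataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    @property
    def dataset_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]


def _collapse_duplicates(frame: pd.DataFrame, dataset_id: str) -> pd.DataFrame:
    dup = frame.index.duplicated(keep=False)
    if not dup.any():
        return frame
    # keep, per symbol, the row with the largest mean absolute deviation
    mad = (frame.sub(frame.mean(axis=1), axis=0)).abs().mean(axis=1).to_numpy()
    order = np.argsort(-mad, kind="stable")
    keep_first = frame.iloc[order]
    keep = keep_first[~keep_first.index.duplicated(keep="first")]
    n_dropped = len(frame) - len(keep)
    logger.warning(
        "%s: collapsed %d duplicate gene rows (kept most variable row per symbol)",
        dataset_id, n_dropped,
    )
    return keep.loc[[g for g in dict.fromkeys(frame.index) ]]


def load_dataset(path, delimiter: str = "\t", dataset_id: str | None = None,
                 log2: bool = False) -> ExpressionDataset:
    """Read one delimited matrix: first column gene symbols, header sample IDs.

    Raises ParseError with row/column coordinates for non-numeric cells; rows
    containing missing values are dropped (logged). With log2=True the values
    are log2(x + 1) transformed for raw-scale inputs.
    """
    import os

    if dataset_id is None:
        dataset_id = os.path.splitext(os.path.basename(str(path)))[0]
    try:
        raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read dataset file {path!r}: {exc}") from exc
    frame = raw.apply(pd.to_numeric, errors="coerce")
    bad = frame.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at gene "
            f"{frame.index[r]!r} (row {r + 2}), sample {frame.columns[c]!r}"
        )
    na_rows = frame.isna().any(axis=1)
    if na_rows.any():
        logger.warning("%s: dropped %d gene rows with missing values",
                       dataset_id, int(na_rows.sum()))
        frame = frame.loc[~na_rows]
    frame = _collapse_duplicates(frame, dataset_id)
    if log2:
        frame = np.log2(frame + 1.0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return ExpressionDataset.from_frame(dataset_id, frame)


def load_collection(paths, delimiter: str = "\t", log2: bool = False) -> Collection:
    """Load each file into a validated ExpressionDataset; no harmonization yet."""
    datasets = [load_dataset(p, delimiter=delimiter, log2=log2) for p in paths]
    return Collection(datasets=datasets)


def harmonize(collection: Collection, feature_set, min_coverage: float = 0.7) -> Collection:
    """Subset every dataset to `feature_set`, dropping low-coverage datasets.

    A dataset is retained only if it contains at least min_coverage of the
    feature set; retained datasets are restricted to their intersection with
    the feature set (feature-set order preserved). The union of genes across
    retained datasets becomes the collection's analysis feature set. Fewer
    than 3 surviving datasets is an error: meta-clusters downstream require
    three unique datasets.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    feature_set = list(dict.fromkeys(feature_set))
    n = len(feature_set)
    if n == 0:
        raise ValueError("empty feature set")
    retained = []
    for d in collection:
        present = set(d.gene_symbols)
        matched = [g for g in feature_set if g in present]
        cov = len(matched) / n
        if cov < min_coverage:
            logger.info("harmonize: excluding %s (coverage %.3f < %.3f)",
                        d.dataset_id, cov, min_coverage)
            continue
        retained.append(d.subset_genes(matched))
    if len(retained) < 3:
        raise ValueError(
            f"only {len(retained)} datasets meet coverage {min_coverage}; "
            "at least 3 are required for meta-cluster discovery"
        )
    union = [g for g in feature_set
             if any(g in set(d.gene_symbols) for d in retained)]
    return Collection(datasets=retained, feature_set=union, min_coverage=min_coverage)


def harmonization_report(collection: Collection, feature_set,
                         min_coverage: float = 0.7) -> pd.DataFrame:
    """Per-dataset coverage report (dataset_id, genes in/matched, retained)."""
    feature_set = list(dict.fromkeys(feature_set))
    n = len(feature_set)
    rows = []
    for d in collection:
        matched = len(set(d.gene_symbols) & set(feature_set))
        cov = matched / n
        rows.append({
            "dataset_id": d.dataset_id,
            "n_genes_in": d.n_genes,
            "n_genes_matched": matched,
            "coverage": cov,
            "retained": cov >= min_coverage,
        })
    return pd.DataFrame(rows)


def batch_mean_center(dataset: ExpressionDataset) -> ExpressionDataset:
    """Gene-wise batch mean centering: subtract each gene's within-dataset mean."""
    centered = dataset.values - dataset.values.mean(axis=1, keepdims=True)
    return replace(dataset, values=centered)
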