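"""Variability-based gene ranking and cross-dataset meta-rank gene selection.

Each dataset ranks its genes by mean absolute deviation (about the gene's
within-dataset mean). A collection-level "meta-rank" list is the top genes by
mean rank across datasets, optionally topped up with each dataset's own most
variable genes, giving a union feature set that does not require every gene
on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Collection, ExpressionDataset

__all__ = ["GeneRanking", "rank_genes", "meta_rank"]


@dataclass
class GeneRanking:
    """Per-dataset variability ranking; rank 1 = most variable gene."""

    dataset_id: str
    gene_symbols: list[str]
    scores: np.ndarray
    ranks: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.ranks, index=self.gene_symbols, name=self.dataset_id)


def rank_genes(dataset: ExpressionDataset) -> GeneRanking:
    """Rank genes by mean absolute deviation, descending; ties alphabetical.

    score(g) = mean_s |x_gs - mean_s(x_g)|. Requires >= 2 samples.
    """
    if dataset.n_samples < 2:
        raise ValueError(f"{dataset.dataset_id}: gene variability undefined "
                         "for a single-sample dataset")
    x = dataset.values
    scores = np.abs(x - x.mean(axis=1, keepdims=True)).mean(axis=1)
    symbols = np.array(dataset.gene_symbols)
    order = np.lexsort((symbols, -scores))
    ranks = np.empty(len(symbols), dtype=int)
    ranks[order] = np.arange(1, len(symbols) + 1)
    return GeneRanking(dataset.dataset_id, list(symbols), scores, ranks)


def meta_rank(collection: Collection, n_global: int, n_intra: int = 0,
              exclude=()) -> list[str]:
    """Cross-dataset meta-rank gene list.

    Per dataset, genes are ranked by mean absolute deviation; a gene absent
    from a dataset receives that dataset's worst rank + 1. The global score is
    the mean rank across datasets; the top n_global genes by ascending mean
    rank are kept, then unioned with every gene in any dataset's top n_intra
    that is not already included. The result is sorted by (global score,
    symbol). `exclude` removes genes (e.g. a known signature) before ranking.
    """
    if n_global < 1:
        raise ValueError("n_global must be >= 1")
    if n_intra < 0:
        raise ValueError("n_intra must be >= 0")
    exclude = set(exclude)
    rankings = []
    for d in collection:
        keep = [g for g in d.gene_symbols if g not in exclude]
        if len(keep) < d.n_genes:
            d = d.subset_genes(keep)
        rankings.append(rank_genes(d))

    union: dict[str, None] = {}
    for r in rankings:
        union.update(dict.fromkeys(r.gene_symbols))
    genes = list(union)
    if n_global > len(genes):
        raise ValueError(f"n_global={n_global} exceeds union gene count {len(genes)}")

    table = pd.DataFrame(index=genes, dtype=float)
    for r in rankings:
        col = pd.Series(r.ranks, index=r.gene_symbols, dtype=float)
        table[r.dataset_id] = col.reindex(genes).fillna(len(r.gene_symbols) + 1)
    mean_rank = table.mean(axis=1)

    # deterministic sort: ascending mean rank, alphabetical tie-break
    order = sorted(genes, key=lambda g: (mean_rank[g], g))
    selected = dict.fromkeys(order[:n_global])
    if n_intra > 0:
        for r in rankings:
            top = [g for g, rk in zip(r.gene_symbols, r.ranks) if rk <= n_intra]
            selected.update(dict.fromkeys(top))
    return sorted(selected, key=lambda g: (mean_rank[g], g))
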