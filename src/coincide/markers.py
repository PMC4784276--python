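"""Meta-analytic marker-gene scoring for meta-clusters.

For each gene and meta-cluster, a standardized mean difference (Hedges' g)
is computed within every contributing dataset between samples in that
dataset's meta-cluster member clusters and all of its other clustered
samples; per-dataset effects are pooled across datasets by inverse-variance
weighting (fixed effect by default, DerSimonian-Laird random effects as an
option). Genes with a large summary effect are robust subtype markers; the
conventional filters are >= 0.5 for enrichment-analysis input and
strictly > 0.75 for druggable-target nomination.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.meta_analysis import effectsize_smd

from .cluster import Clustering
from .datasets import Collection
from .network import MetaClusterResult

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerTable",
    "per_dataset_effect",
    "summary_effect",
    "marker_table",
    "filter_markers",
]


@dataclass
class MarkerTable:
    """Long-format marker results; one row per (meta_cluster, gene)."""

    frame: pd.DataFrame  # columns: meta_cluster, gene, summary_effect,
    #          n_datasets, per_dataset_effects (JSON string)

    def __len__(self):
        return len(self.frame)

    def genes(self, meta_cluster: int) -> list[str]:
        sub = self.frame[self.frame.meta_cluster == meta_cluster]
        return list(sub.gene)


def per_dataset_effect(dataset, clustering: Clustering, member_clusters,
                       gene: str) -> tuple[float, float]:
    """Hedges' g (and its sampling variance) for one gene in one dataset.

    Compares samples in the dataset's meta-cluster member clusters against
    all other clustered samples of the same dataset. Both groups need >= 2
    samples; otherwise a ValueError asks the caller to skip this dataset.
    """
    member_clusters = set(member_clusters)
    gi = dataset.gene_index([gene])[0]
    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    in_idx, out_idx = [], []
    for s, c in clustering.labels.items():
        (in_idx if c in member_clusters else out_idx).append(pos[s])
    if len(in_idx) < 2 or len(out_idx) < 2:
        raise ValueError(
            f"{dataset.dataset_id}: needs >= 2 samples in and outside the "
            f"meta-cluster (got {len(in_idx)}/{len(out_idx)})")
    x1 = dataset.values[gi, in_idx]
    x2 = dataset.values[gi, out_idx]
    sd1, sd2 = x1.std(ddof=1), x2.std(ddof=1)
    if sd1 == 0 and sd2 == 0:
        return 0.0, np.inf  # constant gene: no information
    g, var = effectsize_smd(x1.mean(), sd1, len(x1), x2.mean(), sd2, len(x2))
    return float(g), float(var)


def summary_effect(effects, variances, method: str = "fixed") -> float:
    """Inverse-variance pooled effect across datasets.

    method='fixed' (default) or 'dl' (DerSimonian-Laird random effects).
    Requires >= 2 contributing datasets.
    """
    effects = np.asarray(effects, float)
    variances = np.asarray(variances, float)
    if effects.size < 2:
        raise ValueError("summary effect needs >= 2 contributing datasets")
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / variances
    if method == "dl":
        fixed = float(np.sum(w * effects) / np.sum(w))
        q = float(np.sum(w * (effects - fixed) ** 2))
        k = effects.size
        tau2 = max(0.0, (q - (k - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        w = 1.0 / (variances + tau2)
    elif method != "fixed":
        raise ValueError(f"unknown pooling method {method!r}")
    return float(np.sum(w * effects) / np.sum(w))


def marker_table(collection: Collection, clusterings, meta: MetaClusterResult,
                 genes=None, method: str = "fixed") -> MarkerTable:
    """Summary effect size of every gene for every meta-cluster."""
    clusterings = {c.dataset_id: c for c in clusterings}
    metas = sorted(set(meta.community.values()))
    members_by_meta: dict[int, dict[str, set[int]]] = {m: {} for m in metas}
    for (ds, cl), m in meta.community.items():
        members_by_meta[m].setdefault(ds, set()).add(cl)
    rows = []
    for m in metas:
        gene_list = genes
        if gene_list is None:
            gene_list = collection.feature_set or sorted(
                {g for d in collection for g in d.gene_symbols})
        for gene in gene_list:
            effs, variances, per_ds = [], [], {}
            for ds_id, member_clusters in members_by_meta[m].items():
                d = collection[ds_id]
                if gene not in set(d.gene_symbols):
                    continue
                clu = clusterings[ds_id]
                # datasets fully inside the meta-cluster have no contrast group
                if member_clusters >= set(clu.labels.values()):
                    continue
                try:
                    g, v = per_dataset_effect(d, clu, member_clusters, gene)
                except ValueError:
                    logger.info("markers: skipping %s for gene %s (group too "
                                "small)", ds_id, gene)
                    continue
                if np.isfinite(v):
                    effs.append(g)
                    variances.append(v)
                    per_ds[ds_id] = (g, v)
            if len(effs) >= 2:
                pooled = summary_effect(effs, variances, method=method)
            else:
                pooled = np.nan
            rows.append({
                "meta_cluster": m, "gene": gene, "summary_effect": pooled,
                "n_datasets": len(effs),
                "per_dataset_effects": json.dumps(
                    {k: [round(a, 6), round(b, 6)] for k, (a, b) in per_ds.items()}),
            })
    return MarkerTable(pd.DataFrame(rows))


def filter_markers(table: MarkerTable, threshold: float = 0.5,
                   strict: bool = False) -> MarkerTable:
    """Rows with summary effect >= threshold (or strictly > with strict=True).

    threshold 0.5 is the enrichment-input convention; the druggable-target
    filter uses threshold 0.75 with strict=True.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    f = table.frame
    keep = f.summary_effect > threshold if strict else f.summary_effect >= threshold
    return MarkerTable(f[keep.fillna(False)].reset_index(drop=True))
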