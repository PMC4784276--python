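"""Step 2: bidirectional cluster-to-centroid similarity across datasets.

For an ordered dataset pair (reference, query), every query cluster's samples
are assigned by Pearson correlation to their nearest reference centroid. The
best-fit reference cluster is the one capturing the most samples; two
statistics summarise the match:

* nearest-neighbor fraction (NNF) — fraction of the query cluster's samples
  assigned to the best-fit centroid;
* mean similarity — mean Pearson correlation between the query cluster's
  samples and the best-fit centroid.

Significance comes from a permutation null: the reference centroid matrix is
rotated by Haar-uniform orthogonal matrices about the reference data's
overall mean point (preserving all pairwise centroid distances and norms
relative to that center), the assignment is re-run against each null set, and
the P value is the fraction of null sets whose best-fit mean similarity AND
NNF both strictly exceed the observed values. A cluster pair is retained as
*reciprocal* only if each cluster is the other's best fit when the roles of
reference and query are swapped; the two NNFs and similarities are then
averaged (the two P values are kept separate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_rng, standardize_columns
from .cluster import Clustering
from .datasets import Collection, ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CentroidSet",
    "DirectionalComparison",
    "PairComparison",
    "PairwiseResults",
    "compute_centroids",
    "assign_nearest",
    "random_rotations",
    "null_centroid_sets",
    "draw_null_sets",
    "directional_compare",
    "null_p",
    "all_pairs",
]

DEFAULT_N_NULL = 500  # suggested number of null centroid iterations
DEFAULT_MIN_SHARED_GENES = 10


@dataclass
class CentroidSet:
    """Per-cluster mean profiles of one dataset, restricted to `genes`.

    `center` is the overall per-gene mean across all of the dataset's
    samples; it is the fixed point of the null rotations.
    """

    dataset_id: str
    genes: list[str]
    centroids: np.ndarray  # genes x k
    cluster_ids: list[int]
    center: np.ndarray  # genes,
    sizes: dict[int, int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.cluster_ids)


@dataclass
class DirectionalComparison:
    """One query cluster compared against one reference centroid set."""

    query_cluster: tuple[str, int]
    reference_dataset: str
    best_reference_cluster: int
    nnf: float
    mean_sim: float
    p_value: float | None
    n_null: int
    mean_sim_all: dict[int, float] = field(default_factory=dict)


@dataclass
class PairComparison:
    """Bidirectional statistics for one cross-dataset cluster pair."""

    cluster_a: tuple[str, int]
    cluster_b: tuple[str, int]
    reciprocal: bool
    nnf_avg: float | None
    sim_avg: float | None
    p_a: float | None
    p_b: float | None
    size_a: int = 0
    size_b: int = 0
    n_shared_genes: int = 0


class PairwiseResults(list):
    """List of PairComparison plus the underlying directional comparisons."""

    def __init__(self, pairs, directional):
        super().__init__(pairs)
        self.directional: list[DirectionalComparison] = list(directional)

    def all_similarities(self) -> np.ndarray:
        """Every directional cluster-vs-centroid mean similarity, including
        non-best-fit values — the input to the density-based threshold."""
        vals = [v for d in self.directional for v in d.mean_sim_all.values()
                if np.isfinite(v)]
        return np.asarray(vals, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self:
            rows.append({
                "dataset_a": p.cluster_a[0], "cluster_a": p.cluster_a[1],
                "dataset_b": p.cluster_b[0], "cluster_b": p.cluster_b[1],
                "reciprocal": p.reciprocal, "nnf_avg": p.nnf_avg,
                "sim_avg": p.sim_avg, "p_a": p.p_a, "p_b": p.p_b,
                "size_a": p.size_a, "size_b": p.size_b,
                "n_shared_genes": p.n_shared_genes,
            })
        return pd.DataFrame(rows)


def compute_centroids(dataset: ExpressionDataset, clustering: Clustering,
                      genes=None) -> CentroidSet:
    """Per-cluster arithmetic mean profiles restricted to `genes`."""
    genes = list(genes) if genes is not None else list(dataset.gene_symbols)
    sub = dataset.subset_genes(genes)
    sample_pos = {s: i for i, s in enumerate(sub.sample_ids)}
    cluster_ids = sorted(set(clustering.labels.values()))
    cols = []
    sizes = {}
    for c in cluster_ids:
        members = clustering.members(c)
        if not members:
            raise ValueError(f"{dataset.dataset_id}: cluster {c} is empty")
        idx = [sample_pos[s] for s in members]
        cols.append(sub.values[:, idx].mean(axis=1))
        sizes[c] = len(members)
    centroids = np.column_stack(cols)
    center = sub.values.mean(axis=1)
    return CentroidSet(dataset.dataset_id, genes, centroids, cluster_ids,
                       center, sizes)


def _correlations(query: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Pearson of query columns (genes x n) vs centroid columns (genes x k).

    Constant columns on the shared genes correlate at -inf (never nearest).
    All-constant input is an error.
    """
    zq, cq = standardize_columns(query)
    zc, cc = standardize_columns(centroids)
    if cq.all() or cc.all():
        raise ValueError("all sample or centroid vectors are constant on the "
                         "shared genes; Pearson assignment undefined")
    if cq.any():
        logger.warning("%d constant sample vectors treated as never-nearest",
                       int(cq.sum()))
    if cc.any():
        logger.warning("%d constant centroid vectors treated as never-nearest",
                       int(cc.sum()))
    corr = zq.T @ zc
    if cq.any():
        corr[cq, :] = -np.inf
    if cc.any():
        corr[:, cc] = -np.inf
    return corr


def assign_nearest(query_values: np.ndarray, reference: CentroidSet) -> np.ndarray:
    """Nearest reference cluster id for each query sample (column).

    `query_values` rows must already be aligned to ``reference.genes``. Ties
    break toward the lowest centroid index.
    """
    if query_values.shape[0] != len(reference.genes):
        raise ValueError("query rows must align with reference genes")
    if len(reference.genes) < 2:
        raise ValueError("need at least 2 shared genes for correlation")
    corr = _correlations(query_values, reference.centroids)
    idx = np.argmax(corr, axis=1)  # argmax takes the first (lowest) on ties
    return np.asarray([reference.cluster_ids[i] for i in idx], dtype=int)


def random_rotations(dim: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """`n` Haar-uniform orthogonal matrices of size dim x dim (QR with sign
    correction of a standard Gaussian matrix)."""
    if dim < 2:
        raise ValueError("rotation undefined in fewer than 2 dimensions")
    a = rng.standard_normal((n, dim, dim))
    q, r = np.linalg.qr(a)
    diag = np.einsum("nii->ni", r)
    q *= np.where(diag >= 0, 1.0, -1.0)[:, None, :]
    return q


def null_centroid_sets(reference: CentroidSet, rotations: np.ndarray) -> np.ndarray:
    """Rotate the centroid matrix about the reference data's mean point.

    Returns an (n_null, genes, k) tensor; every null set preserves the
    pairwise centroid distances and the centroid norms about the center.
    """
    centered = reference.centroids - reference.center[:, None]
    return reference.center[None, :, None] + rotations @ centered


def draw_null_sets(reference: CentroidSet, n_null: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw `n_null` null centroid sets directly, without forming full
    rotation matrices.

    A Haar-uniform rotation applied to the centered centroid matrix C only
    acts on C's column space: writing the thin SVD C = U S V^T, Q C =
    (Q U) S V^T where Q U is a uniform random orthonormal r-frame. Drawing
    that frame by QR (with sign correction) of a genes x r Gaussian matrix
    gives the identical distribution at a fraction of the cost. Every null
    set preserves the pairwise centroid distances and centroid norms about
    the reference center exactly.
    """
    centered = reference.centroids - reference.center[:, None]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    r = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if r == 0:  # all centroids at the center: nulls equal the original
        return np.repeat(reference.centroids.T[None], n_null, axis=0).transpose(0, 2, 1)
    coords = s[:r, None] * vt[:r]  # r x k
    g = centered.shape[0]
    a = rng.standard_normal((n_null, g, r))
    q, rr = np.linalg.qr(a)
    diag = np.einsum("nii->ni", rr)
    q *= np.where(diag >= 0, 1.0, -1.0)[:, None, :]
    return reference.center[None, :, None] + q @ coords


def _cluster_stats(corr: np.ndarray) -> tuple[int, float, float]:
    """(best column index, nnf, mean similarity with best) from an
    (n_samples x k) correlation block for one query cluster."""
    n, k = corr.shape
    assigned = np.argmax(corr, axis=1)
    counts = np.bincount(assigned, minlength=k)
    best = int(np.argmax(counts))  # lowest index on ties
    nnf = counts[best] / n
    mean_sim = float(np.mean(corr[:, best]))
    return best, float(nnf), mean_sim


def _null_stats(null_corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-null (nnf, best-fit mean similarity) from an
    (n_samples, n_null, k) correlation tensor."""
    n, t, k = null_corr.shape
    assigned = np.argmax(null_corr, axis=2)  # n x t
    counts = (assigned[:, :, None] == np.arange(k)[None, None, :]).sum(axis=0)  # t x k
    nnf = counts.max(axis=1) / n
    best = counts.argmax(axis=1)  # t
    sims = np.take_along_axis(null_corr, best[None, :, None], axis=2)[:, :, 0]
    return nnf, sims.mean(axis=0)


def null_p(query_values: np.ndarray, reference: CentroidSet,
           observed_nnf: float, observed_sim: float, n_null: int = DEFAULT_N_NULL,
           seed=None, rotations: np.ndarray | None = None) -> float:
    """Permutation P value for one query cluster vs a reference centroid set.

    Counts null centroid sets whose recomputed best-fit mean similarity AND
    NNF both strictly exceed the observed values; returns count / n_null.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    dim = len(reference.genes)
    if dim < 2:
        raise ValueError("null rotation undefined on a single shared gene")
    if rotations is not None:
        nulls = null_centroid_sets(reference, rotations)  # t x g x k
    else:
        nulls = draw_null_sets(reference, n_null,
                               derive_rng(seed, "null", reference.dataset_id, dim))
    t = nulls.shape[0]
    zq, _ = standardize_columns(query_values)
    flat = np.transpose(nulls, (1, 0, 2)).reshape(dim, t * reference.k)
    zc, _ = standardize_columns(flat)
    corr = (zq.T @ zc).reshape(-1, t, reference.k)
    null_nnf, null_sim = _null_stats(corr)
    exceed = (null_sim > observed_sim) & (null_nnf > observed_nnf)
    return float(np.mean(exceed))


def directional_compare(query: ExpressionDataset, query_samples,
                        reference: CentroidSet, query_cluster: tuple[str, int],
                        n_null: int = DEFAULT_N_NULL, seed=None,
                        min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
                        rotations: np.ndarray | None = None,
                        compute_p: bool = True) -> DirectionalComparison:
    """Compare one query cluster against a reference dataset's centroids."""
    shared = [g for g in reference.genes if g in set(query.gene_symbols)]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes between {query.dataset_id} and "
            f"{reference.dataset_id}; minimum is {min_shared_genes}")
    ref = reference
    if shared != reference.genes:
        keep = [i for i, g in enumerate(reference.genes) if g in set(shared)]
        ref = CentroidSet(reference.dataset_id, [reference.genes[i] for i in keep],
                          reference.centroids[keep], reference.cluster_ids,
                          reference.center[keep], reference.sizes)
    sub = query.subset_genes(ref.genes)
    pos = {s: i for i, s in enumerate(sub.sample_ids)}
    qv = sub.values[:, [pos[s] for s in query_samples]]
    corr = _correlations(qv, ref.centroids)
    best_idx, nnf, mean_sim = _cluster_stats(corr)
    sim_all = {c: float(np.mean(corr[:, j]))
               for j, c in enumerate(ref.cluster_ids)}
    p = None
    if compute_p:
        p = null_p(qv, ref, nnf, mean_sim, n_null=n_null, seed=seed,
                   rotations=rotations)
    return DirectionalComparison(
        query_cluster=query_cluster, reference_dataset=ref.dataset_id,
        best_reference_cluster=ref.cluster_ids[best_idx], nnf=nnf,
        mean_sim=mean_sim, p_value=p, n_null=n_null if compute_p else 0,
        mean_sim_all=sim_all)


def all_pairs(collection: Collection, clusterings, n_null: int = DEFAULT_N_NULL,
              seed=None, min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
              genes=None) -> PairwiseResults:
    """Bidirectional comparison of every cross-dataset cluster pair.

    For every ordered dataset pair the query dataset's clusters are compared
    against the reference dataset's centroid set; unordered pairs that are
    mutual best fits become reciprocal PairComparisons with averaged NNF and
    similarity. Non-reciprocal best-fit pairs are retained (reciprocal=False)
    for the similarity density curve. Pairs whose parent datasets both have a
    single cluster are skipped.

    Null centroid sets are drawn once per reference dataset (per shared-gene
    dimension) and reused across its query clusters.
    """
    clusterings = {c.dataset_id: c for c in clusterings}
    datasets = [d for d in collection if d.dataset_id in clusterings]
    if len(datasets) < 2:
        raise ValueError("need clusterings for at least 2 datasets")
    feature = list(genes) if genes is not None else (
        list(collection.feature_set) or None)

    cent: dict[str, CentroidSet] = {}
    for d in datasets:
        gset = [g for g in (feature or d.gene_symbols)
                if g in set(d.gene_symbols)]
        cent[d.dataset_id] = compute_centroids(d, clusterings[d.dataset_id], gset)

    null_z_cache: dict[tuple[str, tuple], np.ndarray] = {}

    def null_columns(ref_cs: CentroidSet) -> np.ndarray:
        """Standardized flattened null centroid columns (g, n_null * k).

        Null sets are drawn once per reference dataset (per shared-gene
        subset) and reused across all of its query clusters.
        """
        key = (ref_cs.dataset_id, tuple(ref_cs.genes))
        if key not in null_z_cache:
            rng = derive_rng(seed, "null", ref_cs.dataset_id, len(ref_cs.genes))
            nulls = draw_null_sets(ref_cs, n_null, rng)  # t x g x k
            flat = np.transpose(nulls, (1, 0, 2)).reshape(len(ref_cs.genes), -1)
            null_z_cache[key] = standardize_columns(flat)[0]
        return null_z_cache[key]

    directional: list[DirectionalComparison] = []
    dir_index: dict[tuple[tuple[str, int], str], DirectionalComparison] = {}
    for ref in datasets:
        ref_id = ref.dataset_id
        for query in datasets:
            q_id = query.dataset_id
            if q_id == ref_id:
                continue
            if cent[ref_id].k == 1 and cent[q_id].k == 1:
                continue  # two single-cluster datasets are never compared
            shared = [g for g in cent[ref_id].genes
                      if g in set(query.gene_symbols)]
            if len(shared) < min_shared_genes:
                logger.warning("skipping %s vs %s: only %d shared genes",
                               q_id, ref_id, len(shared))
                continue
            ref_cs = cent[ref_id]
            if shared != ref_cs.genes:  # subset reference to shared genes
                idx = [i for i, g in enumerate(ref_cs.genes) if g in set(shared)]
                ref_cs = CentroidSet(ref_cs.dataset_id,
                                     [ref_cs.genes[i] for i in idx],
                                     ref_cs.centroids[idx], ref_cs.cluster_ids,
                                     ref_cs.center[idx], ref_cs.sizes)
            k = ref_cs.k
            sub = query.subset_genes(ref_cs.genes)
            zq, cq = standardize_columns(sub.values)
            if cq.all():
                raise ValueError(f"{q_id}: all samples constant on genes "
                                 f"shared with {ref_id}")
            zc, cc = standardize_columns(ref_cs.centroids)
            if cc.all():
                raise ValueError(f"{ref_id}: all centroids constant on genes "
                                 f"shared with {q_id}")
            obs_corr = zq.T @ zc
            if cq.any():
                obs_corr[cq, :] = -np.inf
            if cc.any():
                obs_corr[:, cc] = -np.inf
            null_corr = (zq.T @ null_columns(ref_cs)).reshape(-1, n_null, k)
            if cq.any():
                null_corr[cq, :, :] = -np.inf

            pos = {s: i for i, s in enumerate(sub.sample_ids)}
            qc = clusterings[q_id]
            for c in sorted(set(qc.labels.values())):
                rows = np.asarray([pos[s] for s in qc.members(c)], dtype=int)
                best_idx, nnf, mean_sim = _cluster_stats(obs_corr[rows])
                null_nnf, null_sim = _null_stats(null_corr[rows])
                p = float(np.mean((null_sim > mean_sim) & (null_nnf > nnf)))
                comp = DirectionalComparison(
                    query_cluster=(q_id, c), reference_dataset=ref_id,
                    best_reference_cluster=ref_cs.cluster_ids[best_idx],
                    nnf=nnf, mean_sim=mean_sim, p_value=p, n_null=n_null,
                    mean_sim_all={cid: float(np.mean(obs_corr[rows, j]))
                                  for j, cid in enumerate(ref_cs.cluster_ids)})
                directional.append(comp)
                dir_index[((q_id, c), ref_id)] = comp

    sizes = {d.dataset_id: clusterings[d.dataset_id].sizes() for d in datasets}
    pairs: list[PairComparison] = []
    seen: set[frozenset] = set()
    for comp in directional:
        a = comp.query_cluster  # (dataset, cluster) of the query
        b = (comp.reference_dataset, comp.best_reference_cluster)
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        back = dir_index.get((b, a[0]))
        reciprocal = back is not None and \
            (back.reference_dataset, back.best_reference_cluster) == a
        n_shared = len(set(cent[a[0]].genes) & set(cent[b[0]].genes))
        ca, cb = sorted([a, b])
        fwd, rev = (comp, back) if (a, b) == (ca, cb) else (back, comp)
        # fwd: query ca vs reference cb's dataset; p_a is ca's P value
        p_a = fwd.p_value if fwd is not None else None
        p_b = rev.p_value if rev is not None else None
        if reciprocal:
            nnf_avg = (comp.nnf + back.nnf) / 2.0
            sim_avg = (comp.mean_sim + back.mean_sim) / 2.0
        else:
            nnf_avg = sim_avg = None
        pairs.append(PairComparison(
            cluster_a=ca, cluster_b=cb, reciprocal=reciprocal,
            nnf_avg=nnf_avg, sim_avg=sim_avg, p_a=p_a, p_b=p_b,
            size_a=sizes[ca[0]][ca[1]], size_b=sizes[cb[0]][cb[1]],
            n_shared_genes=n_shared))
    return PairwiseResults(pairs, directional)
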