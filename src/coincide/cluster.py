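"""Step 1: per-dataset consensus k-means with PAC-based model selection.

Each dataset is clustered on its own. Consensus clustering repeatedly
subsamples the samples (default 90 %), runs k-means with a single random
start, and records how often each sample pair lands in the same cluster. The
Proportion of Ambiguous Clusters (PAC) — the fraction of pairwise consensus
values falling in an intermediate band, default (0.1, 0.9) — measures how
well k resolves the data; the k with the smallest PAC (rounded to two
decimals, ties toward smaller k) is selected. Final labels come from
average-linkage hierarchical clustering of 1 - consensus cut at k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from ._utils import derive_rng
from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "Clustering",
    "ConsensusKMeans",
    "pac_score",
    "consensus_kmeans",
    "select_k",
]


@dataclass
class ConsensusResult:
    """Co-clustering frequencies for one dataset at one k."""

    dataset_id: str
    k: int
    consensus: np.ndarray  # n_samples x n_samples, entries in [0, 1]
    pac: float


@dataclass
class Clustering:
    """Final per-dataset clustering: sample_id -> 1-based cluster label."""

    dataset_id: str
    labels: dict[str, int]
    k: int
    pac_by_k: dict[int, float]

    def __post_init__(self):
        present = sorted(set(self.labels.values()))
        if present != list(range(1, self.k + 1)):
            raise ValueError(
                f"{self.dataset_id}: cluster labels {present} are not 1..{self.k}"
            )

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out

    @classmethod
    def from_labels(cls, dataset_id: str, sample_ids, labels,
                    pac_by_k=None) -> "Clustering":
        """Build from parallel sample/label sequences (labels relabelled 1..k)."""
        uniq = sorted(set(labels))
        remap = {lab: i + 1 for i, lab in enumerate(uniq)}
        mapping = {s: remap[lab] for s, lab in zip(sample_ids, labels)}
        return cls(dataset_id, mapping, len(uniq), dict(pac_by_k or {}))


def pac_score(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Fraction of strictly-upper-triangle consensus entries in (lower, upper)."""
    if not 0 <= lower < upper <= 1:
        raise ValueError("require 0 <= lower < upper <= 1")
    consensus = np.asarray(consensus, dtype=float)
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    if vals.size == 0:
        return 0.0
    return float(((vals > lower) & (vals < upper)).mean())


class ConsensusKMeans(BaseEstimator, ClusterMixin):
    """Consensus k-means clusterer with PAC selection of the cluster number.

    scikit-learn style: ``fit(X)`` takes samples x features. Fitted
    attributes: ``labels_`` (0-based, sklearn convention), ``k_``,
    ``pac_by_k_`` (rounded to 2 decimals before argmin internally; raw values
    stored), ``consensus_`` (consensus matrix at the chosen k).

    Parameters
    ----------
    k_range : (int, int)
        Inclusive candidate range for the number of clusters, default (2, 6).
    n_resamples : int
        Subsampling iterations per k, default 100.
    subsample_fraction : float
        Fraction of samples drawn (without replacement) per iteration,
        default 0.9.
    pac_bounds : (float, float)
        Ambiguity band for the PAC score, default (0.1, 0.9).
    allow_k1 : bool
        If True and PAC at k=2 exceeds ``k1_pac_ceiling``, the dataset is
        treated as a single cluster (k=1). Off by default.
    random_state : int or None
        Seed for subsampling and k-means starts.
    """

    def __init__(self, k_range=(2, 6), n_resamples=100, subsample_fraction=0.9,
                 pac_bounds=(0.1, 0.9), allow_k1=False, k1_pac_ceiling=0.5,
                 random_state=None):
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.pac_bounds = pac_bounds
        self.allow_k1 = allow_k1
        self.k1_pac_ceiling = k1_pac_ceiling
        self.random_state = random_state

    def _consensus(self, X: np.ndarray, k: int, rng: np.random.Generator):
        n = X.shape[0]
        if not 2 <= k < n:
            raise ValueError(f"k={k} must satisfy 2 <= k < n_samples={n}")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        n_sub = math.ceil(self.subsample_fraction * n)
        n_sub = max(n_sub, k)
        together = np.zeros((n, n))
        co_drawn = np.zeros((n, n))
        for _ in range(self.n_resamples):
            idx = rng.choice(n, size=n_sub, replace=False)
            km = KMeans(n_clusters=k, n_init=1, algorithm="lloyd",
                        random_state=int(rng.integers(2**31 - 1)))
            labels = km.fit_predict(X[idx])
            onehot = np.zeros((n_sub, k))
            onehot[np.arange(n_sub), labels] = 1.0
            co = onehot @ onehot.T
            together[np.ix_(idx, idx)] += co
            co_drawn[np.ix_(idx, idx)] += 1.0
        never = co_drawn == 0
        if never[np.triu_indices_from(never, k=1)].any():
            logger.warning("consensus: %d sample pairs never co-sampled; "
                           "their consensus is reported as 0",
                           int(never[np.triu_indices_from(never, k=1)].sum()))
        consensus = np.divide(together, co_drawn, out=np.zeros_like(together),
                              where=~never)
        np.fill_diagonal(consensus, np.where(np.diag(co_drawn) > 0, 1.0,
                                             np.diag(consensus)))
        return consensus

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be samples x features")
        n = X.shape[0]
        if np.ptp(X) == 0:
            raise ValueError("all-constant matrix cannot be clustered")
        rng = derive_rng(self.random_state, "consensus")
        lo, hi = self.k_range
        ks = [k for k in range(max(lo, 2), min(hi, n - 1) + 1)]
        if not ks:
            raise ValueError(f"empty k_range {self.k_range} for n_samples={n}")
        pac_by_k: dict[int, float] = {}
        consensus_by_k: dict[int, np.ndarray] = {}
        for k in ks:
            cons = self._consensus(X, k, rng)
            consensus_by_k[k] = cons
            pac_by_k[k] = pac_score(cons, *self.pac_bounds)
        rounded = {k: round(pac_by_k[k], 2) for k in ks}
        best_k = min(ks, key=lambda k: (rounded[k], k))
        if self.allow_k1 and rounded.get(2, 0.0) > self.k1_pac_ceiling:
            self.k_ = 1
            self.labels_ = np.zeros(n, dtype=int)
            self.pac_by_k_ = pac_by_k
            self.consensus_ = consensus_by_k.get(2)
            return self
        cons = consensus_by_k[best_k]
        dist = 1.0 - cons
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0
        tree = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(tree, t=best_k, criterion="maxclust")
        self.k_ = int(len(np.unique(labels)))
        self.labels_ = np.asarray(labels, dtype=int) - 1
        self.pac_by_k_ = pac_by_k
        self.consensus_ = cons
        return self


def consensus_kmeans(dataset: ExpressionDataset, k: int, n_resamples: int = 100,
                     subsample_fraction: float = 0.9,
                     seed=None) -> ConsensusResult:
    """Consensus matrix and PAC for one dataset at a fixed k."""
    est = ConsensusKMeans(k_range=(k, k), n_resamples=n_resamples,
                          subsample_fraction=subsample_fraction,
                          random_state=seed)
    X = dataset.values.T
    if np.ptp(X) == 0:
        raise ValueError(f"{dataset.dataset_id}: all-constant matrix")
    rng = derive_rng(seed, "consensus")
    cons = est._consensus(np.asarray(X, float), k, rng)
    return ConsensusResult(dataset.dataset_id, k, cons, pac_score(cons))


def select_k(dataset: ExpressionDataset, k_range=(2, 6), n_resamples: int = 100,
             subsample_fraction: float = 0.9, pac_bounds=(0.1, 0.9),
             allow_k1: bool = False, k1_pac_ceiling: float = 0.5,
             seed=None) -> Clustering:
    """Cluster one dataset, choosing k by minimal rounded PAC."""
    est = ConsensusKMeans(k_range=k_range, n_resamples=n_resamples,
                          subsample_fraction=subsample_fraction,
                          pac_bounds=pac_bounds, allow_k1=allow_k1,
                          k1_pac_ceiling=k1_pac_ceiling,
                          random_state=derive_rng(seed, dataset.dataset_id)
                          .integers(2**31 - 1) if seed is not None else None)
    est.fit(dataset.values.T)
    return Clustering.from_labels(dataset.dataset_id, dataset.sample_ids,
                                  est.labels_ + 1, est.pac_by_k_)
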