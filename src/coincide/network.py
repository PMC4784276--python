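"""Steps 3-4: similarity threshold selection, the cluster network, and
meta-cluster (community) detection.

Edges join reciprocal cross-dataset cluster pairs that pass all of: averaged
NNF >= nnf_threshold, both directional P values <= p_threshold, and averaged
mean similarity >= sim_threshold; the edge weight is the averaged similarity.
The similarity threshold can be chosen from a Gaussian kernel density of all
cluster-vs-centroid mean similarities: the smallest-similarity local maximum
above a 0.1 baseline is suggested (larger maxima are reported as alternates,
since over-aggressive pruning removes genuinely replicable clusters).

Meta-clusters are Girvan-Newman communities of the weighted network (edge
betweenness on distance = 1/weight; the dendrogram cut maximizing weighted
modularity is kept), after removing communities spanning fewer than three
unique datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterNetwork",
    "MetaClusterResult",
    "ThresholdSuggestion",
    "similarity_density",
    "suggest_threshold",
    "build_network",
    "detect_meta_clusters",
]

Node = tuple[str, int]  # (dataset_id, cluster index)


@dataclass
class ClusterNetwork:
    """Nodes are (dataset_id, cluster) pairs; weighted edges passed thresholds."""

    nodes: list[Node]
    sizes: dict[Node, int]
    edges: list[tuple[Node, Node, float]]
    sim_threshold: float = 0.0
    nnf_threshold: float = 0.0
    p_threshold: float = 1.0

    def __post_init__(self):
        for a, b, w in self.edges:
            if a[0] == b[0]:
                raise ValueError(f"edge within dataset {a[0]}: {a} - {b}")

    @property
    def connected_nodes(self) -> list[Node]:
        seen: dict[Node, None] = {}
        for a, b, _ in self.edges:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, dataset_id=n[0], cluster=n[1],
                       size=self.sizes.get(n, 0))
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"dataset_a": a[0], "cluster_a": a[1], "dataset_b": b[0],
              "cluster_b": b[1], "weight": w} for a, b, w in self.edges])


@dataclass
class MetaClusterResult:
    """Communities of the cluster network, pruned to >= min_datasets datasets."""

    community: dict[Node, int]
    removed_nodes: list[Node]
    sample_assignments: dict[tuple[str, str], int] = field(default_factory=dict)
    datasets_per_meta: dict[int, int] = field(default_factory=dict)
    modularity: float = 0.0

    @property
    def n_meta_clusters(self) -> int:
        return len(set(self.community.values()))

    def members(self, meta: int) -> list[Node]:
        return [n for n, m in self.community.items() if m == meta]


@dataclass
class ThresholdSuggestion:
    primary: float
    alternates: list[float]
    grid: np.ndarray
    density: np.ndarray


def similarity_density(similarities, bw_method="silverman", grid_size=512):
    """Gaussian KDE of mean similarity values on [-1, 1], renormalized so the
    trapezoid integral over the grid is 1."""
    values = np.asarray(similarities, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise ValueError(
            f"only {values.size} similarity values; too few for a density "
            "estimate — set the similarity threshold manually")
    grid = np.linspace(-1.0, 1.0, grid_size)
    if np.ptp(values) == 0:
        # degenerate sample: all mass at one point; narrow Gaussian spike
        dens = np.exp(-0.5 * ((grid - values[0]) / 0.01) ** 2)
    else:
        dens = gaussian_kde(values, bw_method=bw_method)(grid)
    dens = dens / np.trapezoid(dens, grid)
    return grid, dens


def suggest_threshold(grid, density, baseline: float = 0.1) -> ThresholdSuggestion:
    """Similarity value at the smallest qualifying density peak.

    Qualifying local maxima lie at similarity > baseline and have density
    height > baseline. All qualifying peaks are reported as alternates so a
    user can re-run the network at a second maximum when one exists.
    """
    if not 0 <= baseline < 1:
        raise ValueError("baseline must be in [0, 1)")
    grid = np.asarray(grid, float)
    density = np.asarray(density, float)
    peaks = list(argrelextrema(density, np.greater)[0])
    # include plateau/boundary maxima
    if density.size >= 2 and density[-1] > density[-2]:
        peaks.append(density.size - 1)
    qualifying = sorted(grid[i] for i in peaks
                        if grid[i] > baseline and density[i] > baseline)
    if not qualifying:
        raise ValueError("no density peak qualifies above the baseline; "
                         "choose a similarity threshold manually")
    return ThresholdSuggestion(primary=float(qualifying[0]),
                               alternates=[float(q) for q in qualifying],
                               grid=grid, density=density)


def build_network(comparisons, sim_threshold: float, nnf_threshold: float = 0.7,
                  p_threshold: float = 0.01) -> ClusterNetwork:
    """Assign edges to reciprocal pairs passing all thresholds (inclusive)."""
    nodes: dict[Node, int] = {}
    for p in comparisons:
        nodes.setdefault(p.cluster_a, p.size_a)
        nodes.setdefault(p.cluster_b, p.size_b)
    edges = []
    for p in comparisons:
        if not p.reciprocal:
            continue
        if p.nnf_avg is None or p.sim_avg is None:
            continue
        if p.p_a is None or p.p_b is None:
            continue
        if (p.nnf_avg >= nnf_threshold and p.p_a <= p_threshold
                and p.p_b <= p_threshold and p.sim_avg >= sim_threshold):
            edges.append((p.cluster_a, p.cluster_b, float(p.sim_avg)))
    return ClusterNetwork(nodes=list(nodes), sizes=nodes, edges=edges,
                          sim_threshold=sim_threshold,
                          nnf_threshold=nnf_threshold, p_threshold=p_threshold)


def _girvan_newman_partition(nodes: list[Node], edges) -> tuple[list[set], float]:
    """Max-modularity partition along the Girvan-Newman dendrogram.

    Edge betweenness uses distance = 1/weight; modularity uses the
    similarity weights. Implemented over igraph for its C betweenness.
    """
    import igraph as ig

    index = {n: i for i, n in enumerate(nodes)}
    g = ig.Graph(n=len(nodes),
                 edges=[(index[a], index[b]) for a, b, _ in edges])
    weights = [float(w) for _, _, w in edges]
    base = g.copy()
    distances = [1.0 / max(w, 1e-12) for w in weights]
    g.es["distance"] = distances
    g.es["eid"] = list(range(len(edges)))

    def membership(graph) -> list[int]:
        return graph.connected_components().membership

    best_m = membership(g)
    best_q = base.modularity(best_m, weights=weights)
    n_comp = max(best_m) + 1
    while g.ecount() > 0:
        eb = g.edge_betweenness(weights="distance")
        g.delete_edges(int(np.argmax(eb)))
        m = membership(g)
        if max(m) + 1 == n_comp:
            continue
        n_comp = max(m) + 1
        q = base.modularity(m, weights=weights)
        if q > best_q:
            best_q, best_m = q, m
    groups: dict[int, set] = {}
    for node, com in zip(nodes, best_m):
        groups.setdefault(com, set()).add(node)
    return list(groups.values()), float(best_q)


def detect_meta_clusters(network: ClusterNetwork, min_datasets: int = 3,
                         clusterings=None) -> MetaClusterResult:
    """Girvan-Newman communities of the cluster network, pruned by dataset
    support; optionally expands cluster memberships to per-sample subtype
    assignments when the per-dataset clusterings are supplied."""
    if not network.nodes:
        raise ValueError("empty network")
    if not network.edges:
        communities, q = [{n} for n in network.nodes], 0.0
    else:
        communities, q = _girvan_newman_partition(network.nodes, network.edges)
    community: dict[Node, int] = {}
    removed: list[Node] = []
    datasets_per_meta: dict[int, int] = {}
    idx = 0
    for com in sorted(communities, key=lambda c: sorted(c)[0]):
        n_ds = len({n[0] for n in com})
        if n_ds < min_datasets:
            removed.extend(sorted(com))
            continue
        idx += 1
        datasets_per_meta[idx] = n_ds
        for n in sorted(com):
            community[n] = idx
    if removed:
        logger.info("pruned %d cluster nodes in meta-clusters spanning fewer "
                    "than %d datasets", len(removed), min_datasets)

    sample_assignments: dict[tuple[str, str], int] = {}
    if clusterings is not None:
        by_ds = {c.dataset_id: c for c in clusterings}
        for (ds, cl), meta in community.items():
            for s in by_ds[ds].members(cl):
                sample_assignments[(ds, s)] = meta
    return MetaClusterResult(community=community, removed_nodes=removed,
                             sample_assignments=sample_assignments,
                             datasets_per_meta=datasets_per_meta, modularity=q)
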