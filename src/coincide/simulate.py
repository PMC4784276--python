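"""Synthetic multi-dataset collections with known subtype structure, and the
edge-level TPR/FPR evaluation harness.

Ground truth comes from four *archetypes*: fixed mean expression profiles in
a 200-gene space (drawn once per seed from a standard Gaussian and rescaled
so the mean pairwise archetype separation is 4 expression units). A cluster
is a set of samples from one archetype plus i.i.d. Gaussian noise; a "mixed"
cluster draws each sample's archetype uniformly at random and acts as a
negative control. Seven scenario families vary cluster sizes (fixed 50 vs
random 1-100), clusters per dataset (fixed 4, random 2-4, random 1-4) and
the presence of mixed clusters (scenario 7: half the clusters mixed).

Evaluation treats every eligible cross-dataset cluster pair as a binary
prediction problem: an edge between two clusters of the same archetype is a
true positive; between different archetypes (or involving a mixed cluster) a
false positive. Pairs whose parent datasets both hold a single cluster are
not eligible (the method never compares them).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_rng, derive_seed
from .cluster import Clustering
from .datasets import Collection, ExpressionDataset
from .network import ClusterNetwork, build_network, detect_meta_clusters
from .similarity import all_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "SimCollection",
    "EvalEntry",
    "EvalResult",
    "generate",
    "score_edges",
    "sweep",
]

MIXED = "mixed"

_SIZE_RULES = {"fixed": ("fixed", 50), "random": ("random", (1, 100))}

# scenario id -> (cluster_size_rule, clusters_per_dataset_rule, mixed fraction)
_SCENARIOS = {
    1: ("fixed", "fixed4", 0.0),
    2: ("random", "fixed4", 0.0),
    3: ("fixed", "random24", 0.0),
    4: ("fixed", "random14", 0.0),
    5: ("random", "random24", 0.0),
    6: ("random", "random14", 0.0),
    7: ("fixed", "fixed4", 0.5),
}


@dataclass
class ScenarioConfig:
    """Parameters of one simulated collection."""

    scenario_id: int
    noise_sd: float = 0.0
    seed: int = 0
    n_datasets: int = 10
    n_genes: int = 200
    archetypes: int = 4
    separation: float = 4.0  # mean pairwise archetype distance, log-units
    cluster_size_rule: str = "fixed"
    clusters_per_dataset_rule: str = "fixed4"
    noisy_cluster_fraction: float = 0.0

    def __post_init__(self):
        if self.scenario_id not in _SCENARIOS:
            raise ValueError(f"scenario_id must be 1..7, got {self.scenario_id}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_scenario(cls, scenario_id: int, noise_sd: float = 0.0, seed: int = 0,
                      **kwargs) -> "ScenarioConfig":
        size_rule, k_rule, mixed = _SCENARIOS[scenario_id]
        return cls(scenario_id=scenario_id, noise_sd=noise_sd, seed=seed,
                   cluster_size_rule=size_rule, clusters_per_dataset_rule=k_rule,
                   noisy_cluster_fraction=mixed, **kwargs)


@dataclass
class SimCollection:
    """Generated collection plus ground truth and truth-label clusterings."""

    collection: Collection
    truth: dict[tuple[str, int], object]  # (dataset_id, cluster) -> archetype | "mixed"
    clusterings: list[Clustering]
    archetype_means: np.ndarray = field(repr=False, default=None)


@dataclass
class EvalEntry:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def n_eligible(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalResult:
    """Long-format replicate results and threshold/noise-averaged grids."""

    records: pd.DataFrame  # scenario, noise, threshold, rep, tpr, fpr
    n_reps: int

    def averaged(self) -> pd.DataFrame:
        return (self.records
                .groupby(["scenario", "noise", "threshold"], as_index=False)
                [["tpr", "fpr"]].mean())


def _archetype_means(n_genes: int, n_archetypes: int, separation: float,
                     rng: np.random.Generator) -> np.ndarray:
    means = rng.standard_normal((n_genes, n_archetypes))
    dists = [np.linalg.norm(means[:, i] - means[:, j])
             for i, j in itertools.combinations(range(n_archetypes), 2)]
    return means * (separation / float(np.mean(dists)))


def generate(config: ScenarioConfig) -> SimCollection:
    """Simulate one collection of clustered datasets with known archetypes."""
    rng = derive_rng(config.seed, "simulate", config.scenario_id)
    arch = _archetype_means(config.n_genes, config.archetypes,
                            config.separation, rng)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    datasets, truth, clusterings = [], {}, []

    for d in range(config.n_datasets):
        ds_id = f"sim{d + 1:02d}"
        if config.clusters_per_dataset_rule == "fixed4":
            chosen = list(range(config.archetypes))
        elif config.clusters_per_dataset_rule == "random24":
            k = int(rng.integers(2, config.archetypes + 1))
            chosen = sorted(rng.choice(config.archetypes, size=k, replace=False))
        elif config.clusters_per_dataset_rule == "random14":
            k = int(rng.integers(1, config.archetypes + 1))
            chosen = sorted(rng.choice(config.archetypes, size=k, replace=False))
        else:
            raise ValueError(
                f"unknown clusters_per_dataset_rule {config.clusters_per_dataset_rule!r}")

        n_mixed = int(round(config.noisy_cluster_fraction * len(chosen)))
        mixed_slots = set(rng.choice(len(chosen), size=n_mixed, replace=False)
                          ) if n_mixed else set()

        cols, labels, sample_ids = [], [], []
        for slot, a in enumerate(chosen):
            cluster = slot + 1
            if config.cluster_size_rule == "fixed":
                size = 50
            elif config.cluster_size_rule == "random":
                size = int(rng.integers(1, 101))
            else:
                raise ValueError(
                    f"unknown cluster_size_rule {config.cluster_size_rule!r}")
            if slot in mixed_slots:
                arch_idx = rng.integers(0, config.archetypes, size=size)
                base = arch[:, arch_idx]
                truth[(ds_id, cluster)] = MIXED
            else:
                base = np.repeat(arch[:, [a]], size, axis=1)
                truth[(ds_id, cluster)] = int(a)
            noise = config.noise_sd * rng.standard_normal((config.n_genes, size)) \
                if config.noise_sd > 0 else 0.0
            cols.append(base + noise)
            labels.extend([cluster] * size)
            sample_ids.extend(f"{ds_id}_c{cluster}_s{i}" for i in range(size))
        values = np.concatenate(cols, axis=1)
        datasets.append(ExpressionDataset(ds_id, genes, sample_ids, values))
        clusterings.append(Clustering(ds_id, dict(zip(sample_ids, labels)),
                                      len(chosen), {}))

    coll = Collection(datasets=datasets, feature_set=genes, min_coverage=1.0)
    return SimCollection(coll, truth, clusterings, arch)


def _eligible_pairs(truth: dict) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    k_per_ds: dict[str, int] = {}
    for ds, _ in truth:
        k_per_ds[ds] = k_per_ds.get(ds, 0) + 1
    nodes = sorted(truth)
    pairs = []
    for a, b in itertools.combinations(nodes, 2):
        if a[0] == b[0]:
            continue
        if k_per_ds[a[0]] == 1 and k_per_ds[b[0]] == 1:
            continue  # the method never compares two single-cluster datasets
        pairs.append((a, b))
    return pairs


def score_edges(network: ClusterNetwork, truth: dict,
                retained_nodes=None) -> EvalEntry:
    """Edge-level confusion counts against archetype ground truth.

    An edge is a true positive iff it joins two clusters of the same
    archetype; mixed clusters differ from everything. `retained_nodes`
    restricts the present edges to those among nodes surviving meta-cluster
    pruning.
    """
    for n in network.nodes:
        if n not in truth:
            raise KeyError(f"network node {n} missing from truth")
    retained = set(retained_nodes) if retained_nodes is not None else set(network.nodes)
    present = {frozenset((a, b)) for a, b, _ in network.edges
               if a in retained and b in retained}
    tp = fp = fn = tn = 0
    for a, b in _eligible_pairs(truth):
        same = truth[a] == truth[b] and truth[a] != MIXED and truth[b] != MIXED
        has_edge = frozenset((a, b)) in present
        if has_edge and same:
            tp += 1
        elif has_edge:
            fp += 1
        elif same:
            fn += 1
        else:
            tn += 1
    return EvalEntry(tp, fp, fn, tn)


def run_replicate(config: ScenarioConfig, sim_thresholds,
                  n_null: int = 500, nnf_threshold: float = 0.7,
                  p_threshold: float = 0.01, min_datasets: int = 3,
                  seed=None) -> list[dict]:
    """Full pipeline on one simulated collection, scored at each similarity
    threshold. Truth clusterings are taken as given (no re-clustering)."""
    sim = generate(config)
    pairs = all_pairs(sim.collection, sim.clusterings, n_null=n_null,
                      seed=seed if seed is not None else config.seed)
    out = []
    for thr in sim_thresholds:
        net = build_network(pairs, sim_threshold=thr,
                            nnf_threshold=nnf_threshold, p_threshold=p_threshold)
        if net.edges:
            meta = detect_meta_clusters(net, min_datasets=min_datasets)
            retained = list(meta.community)
        else:
            retained = []
        entry = score_edges(net, sim.truth, retained_nodes=retained)
        out.append({"threshold": float(thr), "tpr": entry.tpr, "fpr": entry.fpr,
                    "tp": entry.tp, "fp": entry.fp, "fn": entry.fn,
                    "tn": entry.tn})
    return out


def sweep(scenarios, noise_levels, sim_thresholds, n_reps: int = 50,
          seed: int = 0, n_null: int = 500, nnf_threshold: float = 0.7,
          p_threshold: float = 0.01, min_datasets: int = 3,
          progress: bool = False, **config_kwargs) -> EvalResult:
    """TPR/FPR grid over scenarios x noise levels x similarity thresholds,
    averaged over replicates.

    Replicate seeds derive deterministically from (seed, scenario,
    noise index, replicate)."""
    noise_levels = list(noise_levels)
    sim_thresholds = list(sim_thresholds)
    if not noise_levels or not sim_thresholds or n_reps < 1:
        raise ValueError("need non-empty grids and n_reps >= 1")
    rows = []
    cells = list(itertools.product(scenarios, range(len(noise_levels))))
    for s, ni in cells:
        noise = noise_levels[ni]
        for rep in range(n_reps):
            rep_seed = derive_seed(seed, "sweep", s, ni, rep)
            config = ScenarioConfig.from_scenario(s, noise_sd=noise,
                                                  seed=rep_seed, **config_kwargs)
            for rec in run_replicate(config, sim_thresholds, n_null=n_null,
                                     nnf_threshold=nnf_threshold,
                                     p_threshold=p_threshold,
                                     min_datasets=min_datasets, seed=rep_seed):
                rows.append({"scenario": s, "noise": float(noise),
                             "rep": rep, **rec})
        if progress:
            logger.info("sweep: scenario %s noise %.2f done", s, noise)
    return EvalResult(pd.DataFrame(rows), n_reps=n_reps)
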