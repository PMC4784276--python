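"""End-to-end orchestration: rank -> cluster -> pairs -> network -> markers.

`CoincideAnalysis` is the estimator-style entry point over an in-memory
collection; `run_all` drives a full configured run from files to a results
directory with a checksummed manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import derive_seed
from .cluster import Clustering, select_k
from .datasets import Collection, harmonization_report, harmonize, load_collection
from .features import meta_rank
from .markers import filter_markers, marker_table
from .network import (build_network, detect_meta_clusters, similarity_density,
                      suggest_threshold)
from .similarity import all_pairs

logger = logging.getLogger(__name__)

__all__ = ["CoincideAnalysis", "RunConfig", "run_all"]


class CoincideAnalysis(BaseEstimator):
    """Meta-cluster discovery across a collection of clustered datasets.

    ``fit(collection, clusterings=...)`` runs cluster-pair comparison,
    (optional) density-based similarity-threshold selection, edge assignment
    and community detection. When ``clusterings`` is omitted, every dataset
    is first clustered by consensus k-means with PAC selection of k.

    Parameters follow the method's recommended defaults: 500 null centroid
    iterations, NNF threshold 0.7, P value threshold 0.01 on both directional
    P values, minimum 3 unique datasets per meta-cluster, density baseline
    0.1. ``sim_threshold`` may be a number or "auto".

    Fitted attributes: ``pairs_``, ``sim_threshold_``, ``network_``,
    ``meta_clusters_``, ``sample_assignments_``, and (when clustering was run
    here) ``clusterings_``.
    """

    def __init__(self, sim_threshold="auto", nnf_threshold=0.7, p_threshold=0.01,
                 min_datasets=3, n_null=500, min_shared_genes=10,
                 density_baseline=0.1, k_range=(2, 6), n_resamples=100,
                 subsample_fraction=0.9, allow_k1=False, random_state=None):
        self.sim_threshold = sim_threshold
        self.nnf_threshold = nnf_threshold
        self.p_threshold = p_threshold
        self.min_datasets = min_datasets
        self.n_null = n_null
        self.min_shared_genes = min_shared_genes
        self.density_baseline = density_baseline
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.allow_k1 = allow_k1
        self.random_state = random_state

    def fit(self, collection: Collection, clusterings=None):
        if clusterings is None:
            logger.info("step 1: consensus clustering %d datasets", len(collection))
            clusterings = [
                select_k(d, k_range=self.k_range, n_resamples=self.n_resamples,
                         subsample_fraction=self.subsample_fraction,
                         allow_k1=self.allow_k1, seed=self.random_state)
                for d in collection
            ]
            self.clusterings_ = clusterings
        n_clusters = sum(len(set(c.labels.values())) for c in clusterings)
        logger.info("step 2: comparing %d input clusters across %d datasets",
                    n_clusters, len(collection))
        self.pairs_ = all_pairs(collection, clusterings, n_null=self.n_null,
                                seed=self.random_state,
                                min_shared_genes=self.min_shared_genes)
        n_recip = sum(1 for p in self.pairs_ if p.reciprocal)
        logger.info("step 2: %d reciprocal pairs of %d best-fit pairs",
                    n_recip, len(self.pairs_))
        if self.sim_threshold == "auto":
            grid, dens = similarity_density(self.pairs_.all_similarities())
            suggestion = suggest_threshold(grid, dens, self.density_baseline)
            self.sim_threshold_ = suggestion.primary
            self.threshold_alternates_ = suggestion.alternates
            logger.info("step 3: density-selected similarity threshold %.3f "
                        "(alternates: %s)", self.sim_threshold_,
                        suggestion.alternates)
        else:
            self.sim_threshold_ = float(self.sim_threshold)
        self.network_ = build_network(self.pairs_, self.sim_threshold_,
                                      self.nnf_threshold, self.p_threshold)
        logger.info("step 3: %d edges among %d clusters",
                    len(self.network_.edges), len(self.network_.nodes))
        self.meta_clusters_ = detect_meta_clusters(
            self.network_, min_datasets=self.min_datasets,
            clusterings=clusterings)
        self.sample_assignments_ = self.meta_clusters_.sample_assignments
        logger.info("step 4: %d meta-clusters (%d cluster nodes retained, "
                    "%d removed)", self.meta_clusters_.n_meta_clusters,
                    len(self.meta_clusters_.community),
                    len(self.meta_clusters_.removed_nodes))
        return self

    def fit_predict(self, collection: Collection, clusterings=None) -> dict:
        """Fit and return the per-sample meta-cluster assignment map."""
        return self.fit(collection, clusterings).sample_assignments_


@dataclass
class RunConfig:
    """Configuration of a full run; defaults are the recommended settings."""

    datasets: list[str] = field(default_factory=list)
    delimiter: str = "\t"
    log2: bool = False
    feature_set_file: str | None = None
    min_coverage: float = 0.7
    n_global: int = 200
    n_intra: int = 20
    exclude_file: str | None = None
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 100
    subsample_fraction: float = 0.9
    allow_k1: bool = False
    n_null: int = 500
    min_shared_genes: int = 10
    sim_threshold: object = "auto"
    nnf_threshold: float = 0.7
    p_threshold: float = 0.01
    min_datasets: int = 3
    density_baseline: float = 0.1
    marker_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write(path: Path, frame: pd.DataFrame):
    frame.to_csv(path, sep="\t", index=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir, collection: Collection | None = None,
            clusterings=None) -> Path:
    """Execute the full pipeline, writing every intermediate artifact plus a
    JSON manifest with seeds, thresholds and per-file checksums.

    `collection`/`clusterings` may be supplied directly (e.g. simulated or
    pre-clustered data); otherwise datasets are loaded from config paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if collection is None:
            raw = load_collection(config.datasets, delimiter=config.delimiter,
                                  log2=config.log2)
        else:
            raw = collection

        stage = "feature_select"
        if config.feature_set_file:
            feature_set = [ln.strip() for ln in
                           Path(config.feature_set_file).read_text().splitlines()
                           if ln.strip()]
        elif raw.feature_set:
            feature_set = list(raw.feature_set)
        else:
            exclude = []
            if config.exclude_file:
                exclude = [ln.strip() for ln in
                           Path(config.exclude_file).read_text().splitlines()
                           if ln.strip()]
            feature_set = meta_rank(raw, config.n_global, config.n_intra,
                                    exclude=exclude)
        (out / "genes.txt").write_text("\n".join(feature_set) + "\n")

        stage = "harmonize"
        report = harmonization_report(raw, feature_set, config.min_coverage)
        _write(out / "harmonization.tsv", report)
        coll = harmonize(raw, feature_set, config.min_coverage)

        stage = "cluster"
        analysis = CoincideAnalysis(
            sim_threshold=config.sim_threshold, nnf_threshold=config.nnf_threshold,
            p_threshold=config.p_threshold, min_datasets=config.min_datasets,
            n_null=config.n_null, min_shared_genes=config.min_shared_genes,
            density_baseline=config.density_baseline,
            k_range=(config.k_min, config.k_max), n_resamples=config.n_resamples,
            subsample_fraction=config.subsample_fraction,
            allow_k1=config.allow_k1, random_state=config.seed)
        analysis.fit(coll, clusterings=clusterings)
        used_clusterings = clusterings if clusterings is not None \
            else analysis.clusterings_
        for c in used_clusterings:
            frame = pd.DataFrame({"sample_id": list(c.labels),
                                  "cluster": list(c.labels.values())})
            _write(out / f"clusters_{c.dataset_id}.tsv", frame)
            if c.pac_by_k:
                (out / f"pac_{c.dataset_id}.json").write_text(
                    json.dumps({str(k): v for k, v in c.pac_by_k.items()},
                               indent=1))

        stage = "pairs"
        _write(out / "pairs.tsv", analysis.pairs_.to_frame())
        grid, dens = similarity_density(analysis.pairs_.all_similarities())
        _write(out / "similarity_density.tsv",
               pd.DataFrame({"similarity": grid, "density": dens}))

        stage = "network"
        _write(out / "edges.tsv", analysis.network_.edge_frame())
        import networkx as nx

        g = analysis.network_.to_networkx()
        for n, meta in analysis.meta_clusters_.community.items():
            g.nodes[n]["meta_cluster"] = meta
        nx.write_graphml(nx.relabel_nodes(g, {n: f"{n[0]}:{n[1]}" for n in g}),
                         out / "network.graphml")
        meta_frame = pd.DataFrame(
            [{"dataset_id": ds, "cluster": cl, "meta_cluster": m}
             for (ds, cl), m in sorted(analysis.meta_clusters_.community.items())])
        _write(out / "meta_clusters.tsv", meta_frame)
        sample_frame = pd.DataFrame(
            [{"dataset_id": ds, "sample_id": s, "meta_cluster": m}
             for (ds, s), m in sorted(analysis.sample_assignments_.items())])
        _write(out / "sample_assignments.tsv", sample_frame)

        stage = "markers"
        if analysis.meta_clusters_.community:
            table = marker_table(coll, used_clusterings, analysis.meta_clusters_)
            _write(out / "markers.tsv", table.frame)
            _write(out / "markers_filtered.tsv",
                   filter_markers(table, config.marker_threshold).frame)
    except Exception as exc:
        done = sorted(p.name for p in out.iterdir())
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}; artifacts completed "
            f"so far: {done}") from exc

    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "seed": config.seed,
        "sim_threshold_used": analysis.sim_threshold_,
        "n_meta_clusters": analysis.meta_clusters_.n_meta_clusters,
        "n_edges": len(analysis.network_.edges),
        "files": {p.name: _checksum(p) for p in sorted(out.iterdir())
                  if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return out
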