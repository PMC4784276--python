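import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coincide import Clustering, Collection, ExpressionDataset

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


def make_dataset(dataset_id, values, genes=None, samples=None) -> ExpressionDataset:
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    genes = genes or [f"g{i:03d}" for i in range(g)]
    samples = samples or [f"{dataset_id}_s{i}" for i in range(n)]
    return ExpressionDataset(dataset_id, genes, samples, values)


def make_clustered_collection(rng, n_datasets=3, n_genes=30, k=3,
                              cluster_size=8, noise=0.5, separation=3.0):
    """Archetype-structured collection with truth-label clusterings."""
    import itertools

    arch = rng.standard_normal((n_genes, k))
    mean_dist = np.mean([np.linalg.norm(arch[:, i] - arch[:, j])
                         for i, j in itertools.combinations(range(k), 2)])
    arch *= separation / mean_dist
    genes = [f"g{i:03d}" for i in range(n_genes)]
    datasets, clusterings = [], []
    for d in range(n_datasets):
        ds_id = f"d{d}"
        cols, labels, samples = [], [], []
        for c in range(k):
            block = arch[:, [c]] + noise * rng.standard_normal(
                (n_genes, cluster_size))
            cols.append(block)
            labels.extend([c + 1] * cluster_size)
            samples.extend(f"{ds_id}_c{c}_s{i}" for i in range(cluster_size))
        datasets.append(ExpressionDataset(ds_id, genes, samples,
                                          np.concatenate(cols, axis=1)))
        clusterings.append(Clustering(ds_id, dict(zip(samples, labels)), k, {}))
    coll = Collection(datasets=datasets, feature_set=genes, min_coverage=1.0)
    return coll, clusterings


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_collection(rng):
    return make_clustered_collection(rng)
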