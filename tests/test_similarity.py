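import numpy as np
import pytest
from scipy.stats import kstest

from coincide import (CentroidSet, Clustering, all_pairs, assign_nearest,
                      compute_centroids, directional_compare, draw_null_sets,
                      null_centroid_sets, null_p, random_rotations)
from coincide._utils import standardize_columns
from coincide.similarity import _cluster_stats, _correlations, _null_stats

from conftest import make_clustered_collection, make_dataset


def random_centroid_set(rng, dim=12, k=3, ds_id="ref"):
    data = rng.standard_normal((dim, 30))
    labels = rng.integers(0, k, 30)
    while len(set(labels)) < k:
        labels = rng.integers(0, k, 30)
    cent = np.column_stack([data[:, labels == c].mean(1) for c in range(k)])
    return CentroidSet(ds_id, [f"g{i:03d}" for i in range(dim)], cent,
                       list(range(1, k + 1)), data.mean(1))


class TestCentroids:
    def test_closed_form(self):
        ds = make_dataset("d", [[1, 3], [3, 5]])
        clu = Clustering("d", {ds.sample_ids[0]: 1, ds.sample_ids[1]: 1}, 1, {})
        cs = compute_centroids(ds, clu)
        np.testing.assert_allclose(cs.centroids[:, 0], [2, 4])

    def test_singleton_cluster_is_sample_profile(self, rng):
        vals = rng.standard_normal((5, 3))
        ds = make_dataset("d", vals)
        clu = Clustering("d", {ds.sample_ids[0]: 1, ds.sample_ids[1]: 2,
                               ds.sample_ids[2]: 2}, 2, {})
        cs = compute_centroids(ds, clu)
        np.testing.assert_allclose(cs.centroids[:, 0], vals[:, 0])

    def test_matches_brute_force(self, rng):
        vals = rng.standard_normal((8, 12))
        ds = make_dataset("d", vals)
        labels = rng.integers(1, 4, 12)
        while len(set(labels)) < 3:
            labels = rng.integers(1, 4, 12)
        clu = Clustering("d", dict(zip(ds.sample_ids, labels)), 3, {})
        cs = compute_centroids(ds, clu)
        for j, c in enumerate(cs.cluster_ids):
            np.testing.assert_allclose(cs.centroids[:, j],
                                       vals[:, labels == c].mean(axis=1))


class TestAssignNearest:
    def test_exact_match(self, rng):
        cs = random_centroid_set(rng)
        q = cs.centroids[:, [1]]
        assert assign_nearest(q, cs)[0] == 2

    def test_anticorrelated_single_centroid(self, rng):
        cs = random_centroid_set(rng, k=1)
        q = -cs.centroids  # Pearson -1 against the only centroid
        assert assign_nearest(q, cs)[0] == 1  # argmax over a singleton

    def test_matches_brute_force_many_cases(self, rng):
        for _ in range(100):
            cs = random_centroid_set(rng, dim=8, k=3)
            q = rng.standard_normal((8, 5))
            got = assign_nearest(q, cs)
            for s in range(5):
                corrs = [np.corrcoef(q[:, s], cs.centroids[:, j])[0, 1]
                         for j in range(3)]
                assert got[s] == int(np.argmax(corrs)) + 1

    def test_constant_sample_never_blocks(self, rng, caplog):
        cs = random_centroid_set(rng)
        q = np.column_stack([np.ones(12), cs.centroids[:, 2]])
        got = assign_nearest(q, cs)
        assert got[1] == 3  # real sample still assigned correctly

    def test_all_constant_errors(self, rng):
        cs = random_centroid_set(rng)
        with pytest.raises(ValueError, match="constant"):
            assign_nearest(np.ones((12, 3)), cs)


class TestNullGeometry:
    def test_rotations_are_orthogonal(self, rng):
        q = random_rotations(6, 20, rng)
        for m in q:
            np.testing.assert_allclose(m @ m.T, np.eye(6), atol=1e-10)

    @pytest.mark.parametrize("method", ["rotations", "frames"])
    def test_null_sets_preserve_centroid_geometry(self, rng, method):
        cs = random_centroid_set(rng, dim=10, k=4)
        if method == "rotations":
            nulls = null_centroid_sets(cs, random_rotations(10, 25, rng))
        else:
            nulls = draw_null_sets(cs, 25, rng)
        center = cs.center
        true_d = np.linalg.norm(cs.centroids[:, :, None]
                                - cs.centroids[:, None, :], axis=0)
        true_norms = np.linalg.norm(cs.centroids - center[:, None], axis=0)
        for t in range(nulls.shape[0]):
            d = np.linalg.norm(nulls[t][:, :, None] - nulls[t][:, None, :],
                               axis=0)
            np.testing.assert_allclose(d, true_d, atol=1e-8)
            np.testing.assert_allclose(
                np.linalg.norm(nulls[t] - center[:, None], axis=0),
                true_norms, atol=1e-8)

    def test_frame_draw_matches_rotation_distribution(self, rng):
        # mean null best-fit similarity should agree between the two
        # mathematically equivalent null constructions
        cs = random_centroid_set(rng, dim=15, k=3)
        q = cs.center[:, None] + rng.standard_normal((15, 20))
        stats = []
        for nulls in (null_centroid_sets(cs, random_rotations(15, 400, rng)),
                      draw_null_sets(cs, 400, rng)):
            flat = np.transpose(nulls, (1, 0, 2)).reshape(15, -1)
            zq, _ = standardize_columns(q)
            zc, _ = standardize_columns(flat)
            nnf, sim = _null_stats((zq.T @ zc).reshape(20, -1, 3))
            stats.append((nnf.mean(), sim.mean()))
        assert stats[0][0] == pytest.approx(stats[1][0], abs=0.05)
        assert stats[0][1] == pytest.approx(stats[1][1], abs=0.05)


class TestNullP:
    def test_perfect_match_p_zero(self, rng):
        cs = random_centroid_set(rng)
        q = np.repeat(cs.centroids[:, [0]], 4, axis=1)
        p = null_p(q, cs, observed_nnf=1.0, observed_sim=1.0, n_null=50, seed=1)
        assert p == 0.0  # nothing strictly exceeds sim = nnf = 1

    def test_matches_per_draw_brute_force(self, rng):
        cs = random_centroid_set(rng, dim=9, k=3)
        q = rng.standard_normal((9, 7))
        corr = _correlations(q, cs.centroids)
        _, nnf, msim = _cluster_stats(corr)
        rot = random_rotations(9, 40, np.random.default_rng(77))
        p = null_p(q, cs, nnf, msim, n_null=40, rotations=rot)
        # independent re-computation, one null draw at a time
        count = 0
        for t in range(40):
            null_cent = cs.center[:, None] + rot[t] @ (cs.centroids
                                                       - cs.center[:, None])
            corrs = np.array([[np.corrcoef(q[:, s], null_cent[:, j])[0, 1]
                               for j in range(3)] for s in range(7)])
            assigned = corrs.argmax(axis=1)
            counts = np.bincount(assigned, minlength=3)
            best = counts.argmax()
            if (corrs[:, best].mean() > msim) and (counts[best] / 7 > nnf):
                count += 1
        assert p == pytest.approx(count / 40)

    def test_single_shared_gene_errors(self, rng):
        cs = random_centroid_set(rng)
        cs1 = CentroidSet("r", ["g000"], cs.centroids[:1], cs.cluster_ids,
                          cs.center[:1])
        with pytest.raises(ValueError, match="single shared gene"):
            null_p(np.ones((1, 3)), cs1, 0.5, 0.5, n_null=5, seed=0)

    def test_similarity_exceedance_p_is_uniform(self, rng):
        # validates the rotation null itself: for the continuous similarity
        # statistic alone, exchangeability makes the exceedance p uniform
        ps = []
        for rep in range(150):
            cs = random_centroid_set(rng, dim=20, k=3, ds_id=f"r{rep}")
            q = cs.center[:, None] + rng.standard_normal((20, 25))
            corr = _correlations(q, cs.centroids)
            _, nnf, msim = _cluster_stats(corr)
            nulls = draw_null_sets(cs, 60, rng)
            flat = np.transpose(nulls, (1, 0, 2)).reshape(20, -1)
            zq, _ = standardize_columns(q)
            zc, _ = standardize_columns(flat)
            _, sim = _null_stats((zq.T @ zc).reshape(25, -1, 3))
            ps.append(np.mean(sim > msim))
        assert kstest(ps, "uniform").pvalue > 0.001


class TestDirectionalAndPairs:
    def test_identical_cluster_perfect_stats(self, rng):
        coll, clus = make_clustered_collection(rng, n_datasets=2, noise=0.0)
        cs = compute_centroids(coll.datasets[0], clus[0])
        comp = directional_compare(coll.datasets[1], clus[1].members(1), cs,
                                   ("d1", 1), n_null=20, seed=0)
        assert comp.best_reference_cluster == 1
        assert comp.nnf == 1.0
        assert comp.mean_sim == pytest.approx(1.0)
        assert comp.p_value == 0.0

    def test_all_pairs_reciprocal_twins(self, rng):
        coll, clus = make_clustered_collection(rng, n_datasets=3, noise=0.0)
        pairs = all_pairs(coll, clus, n_null=20, seed=4)
        recip = [p for p in pairs if p.reciprocal]
        # every same-archetype cluster pair across every dataset pair
        assert len(recip) == 3 * 3  # 3 dataset pairs x 3 archetypes
        for p in recip:
            assert p.cluster_a[1] == p.cluster_b[1]
            assert p.nnf_avg == 1.0
            assert p.sim_avg == pytest.approx(1.0)

    def test_reciprocity_is_mutual_argmax(self, rng):
        coll, clus = make_clustered_collection(rng, n_datasets=3, noise=0.8)
        pairs = all_pairs(coll, clus, n_null=10, seed=4)
        best = {(d.query_cluster, d.reference_dataset):
                (d.reference_dataset, d.best_reference_cluster)
                for d in pairs.directional}
        for p in pairs:
            a, b = p.cluster_a, p.cluster_b
            expected = (best.get((a, b[0])) == b) and (best.get((b, a[0])) == a)
            assert p.reciprocal == expected

    def test_matches_simple_path(self, rng):
        # the batched implementation must agree with the one-cluster path
        coll, clus = make_clustered_collection(rng, n_datasets=2, noise=1.0)
        pairs = all_pairs(coll, clus, n_null=5, seed=0)
        for d in pairs.directional:
            q_ds = coll[d.query_cluster[0]]
            ref = compute_centroids(coll[d.reference_dataset],
                                    clus[[c.dataset_id for c in clus].index(
                                        d.reference_dataset)],
                                    coll.feature_set)
            members = [c for c in clus
                       if c.dataset_id == d.query_cluster[0]][0].members(
                           d.query_cluster[1])
            simple = directional_compare(q_ds, members, ref, d.query_cluster,
                                         compute_p=False)
            assert simple.best_reference_cluster == d.best_reference_cluster
            assert simple.nnf == pytest.approx(d.nnf)
            assert simple.mean_sim == pytest.approx(d.mean_sim)
            for c, v in simple.mean_sim_all.items():
                assert v == pytest.approx(d.mean_sim_all[c])

    def test_dataset_order_invariance(self, rng):
        coll, clus = make_clustered_collection(rng, n_datasets=3, noise=0.6)
        a = all_pairs(coll, clus, n_null=15, seed=9)
        coll2 = type(coll)(datasets=coll.datasets[::-1],
                           feature_set=coll.feature_set, min_coverage=1.0)
        b = all_pairs(coll2, clus[::-1], n_null=15, seed=9)
        key = lambda p: (p.cluster_a, p.cluster_b)
        fa = {key(p): (p.reciprocal, p.nnf_avg, p.sim_avg, p.p_a, p.p_b)
              for p in a}
        fb = {key(p): (p.reciprocal, p.nnf_avg, p.sim_avg, p.p_a, p.p_b)
              for p in b}
        assert fa == fb

    def test_single_cluster_dataset_pairs_skipped(self, rng):
        coll, clus = make_clustered_collection(rng, n_datasets=3, noise=0.3)
        # collapse two datasets to a single cluster each
        mono = []
        for c in clus[:2]:
            mono.append(Clustering(c.dataset_id,
                                   {s: 1 for s in c.labels}, 1, {}))
        mono.append(clus[2])
        pairs = all_pairs(coll, mono, n_null=5, seed=0)
        involved = {frozenset((p.cluster_a[0], p.cluster_b[0])) for p in pairs}
        assert frozenset(("d0", "d1")) not in involved

    def test_statistic_ranges(self, rng):
        coll, clus = make_clustered_collection(rng, n_datasets=3, noise=1.5)
        pairs = all_pairs(coll, clus, n_null=8, seed=2)
        for d in pairs.directional:
            assert 0 <= d.nnf <= 1
            assert -1 - 1e-12 <= d.mean_sim <= 1 + 1e-12
            assert 0 <= d.p_value <= 1
            assert round(d.p_value * 8, 6) == int(round(d.p_value * 8))
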