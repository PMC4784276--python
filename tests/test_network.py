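import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coincide import (ClusterNetwork, PairComparison, build_network,
                      detect_meta_clusters, similarity_density,
                      suggest_threshold)
from coincide.cluster import Clustering


def pair(a, b, nnf=0.9, sim=0.8, p_a=0.001, p_b=0.001, reciprocal=True):
    return PairComparison(cluster_a=a, cluster_b=b, reciprocal=reciprocal,
                          nnf_avg=nnf if reciprocal else None,
                          sim_avg=sim if reciprocal else None,
                          p_a=p_a, p_b=p_b, size_a=10, size_b=10,
                          n_shared_genes=50)


class TestSimilarityDensity:
    def test_single_peak_at_common_value(self):
        grid, dens = similarity_density([0.42] * 25)
        assert grid[np.argmax(dens)] == pytest.approx(0.42, abs=0.02)

    def test_integrates_to_one(self, rng):
        grid, dens = similarity_density(rng.uniform(-0.5, 0.9, 200))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)

    def test_bimodal_sample_two_maxima(self):
        vals = np.r_[np.full(40, 0.1), np.full(40, 0.6)]
        vals = vals + np.linspace(-0.02, 0.02, 80)  # tiny jitter, fixed
        grid, dens = similarity_density(vals)
        from scipy.signal import argrelextrema

        maxima = grid[argrelextrema(dens, np.greater)[0]]
        assert any(abs(m - 0.1) < 0.05 for m in maxima)
        assert any(abs(m - 0.6) < 0.05 for m in maxima)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="manual"):
            similarity_density([0.5] * 5)


class TestSuggestThreshold:
    def _density(self, peaks, heights, width=0.04):
        grid = np.linspace(-1, 1, 801)
        dens = np.zeros_like(grid)
        for p, h in zip(peaks, heights):
            dens += h * np.exp(-0.5 * ((grid - p) / width) ** 2)
        return grid, dens

    def test_unimodal(self):
        grid, dens = self._density([0.5], [2.0])
        assert suggest_threshold(grid, dens).primary == pytest.approx(0.5, abs=0.01)

    def test_two_maxima_reports_both(self):
        grid, dens = self._density([0.5, 0.7], [2.0, 1.5])
        s = suggest_threshold(grid, dens)
        assert s.primary == pytest.approx(0.5, abs=0.01)
        assert len(s.alternates) == 2
        assert s.alternates[1] == pytest.approx(0.7, abs=0.01)

    def test_peak_below_baseline_only_is_error(self):
        grid, dens = self._density([0.05], [2.0])
        with pytest.raises(ValueError, match="manual"):
            suggest_threshold(grid, dens, baseline=0.1)


class TestBuildNetwork:
    def test_nnf_just_below_threshold_no_edge(self):
        net = build_network([pair(("d1", 1), ("d2", 1), nnf=0.69)],
                            sim_threshold=0.15)
        assert net.edges == []

    def test_both_p_values_must_pass(self):
        net = build_network([pair(("d1", 1), ("d2", 1), p_a=0.005, p_b=0.02)],
                            sim_threshold=0.15)
        assert net.edges == []

    def test_inclusive_thresholds_and_weight(self):
        p = pair(("d1", 1), ("d2", 1), nnf=0.7, sim=0.15, p_a=0.01, p_b=0.01)
        net = build_network([p], sim_threshold=0.15)
        assert len(net.edges) == 1
        assert net.edges[0][2] == pytest.approx(0.15)

    def test_non_reciprocal_never_edges(self):
        net = build_network([pair(("d1", 1), ("d2", 1), reciprocal=False)],
                            sim_threshold=0.0)
        assert net.edges == []
        assert ("d1", 1) in net.nodes  # kept for diagnostics

    def test_same_dataset_edge_rejected(self):
        with pytest.raises(ValueError, match="within dataset"):
            ClusterNetwork(nodes=[("d1", 1), ("d1", 2)],
                           sizes={("d1", 1): 5, ("d1", 2): 5},
                           edges=[(("d1", 1), ("d1", 2), 0.9)])

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                    min_size=1, max_size=20),
           st.floats(0, 1), st.floats(0, 1))
    def test_raising_threshold_monotone(self, sims_nnfs, t_lo, t_hi):
        t_lo, t_hi = min(t_lo, t_hi), max(t_lo, t_hi)
        pairs = [pair(("a", 1), (f"d{i}", 1), nnf=nnf, sim=s)
                 for i, (s, nnf) in enumerate(sims_nnfs)]
        lo = {(a, b) for a, b, _ in build_network(pairs, t_lo).edges}
        hi = {(a, b) for a, b, _ in build_network(pairs, t_hi).edges}
        assert hi <= lo


def clique_network(offset, datasets, weight=0.9):
    nodes = [(f"d{offset + i}", 1) for i in range(datasets)]
    edges = [(a, b, weight) for i, a in enumerate(nodes)
             for b in nodes[i + 1:]]
    return nodes, edges


class TestDetectMetaClusters:
    def test_two_bridged_cliques_split(self):
        n1, e1 = clique_network(0, 4)
        n2, e2 = clique_network(4, 4)
        bridge = [(n1[0], n2[0], 0.3)]
        net = ClusterNetwork(nodes=n1 + n2, sizes={n: 5 for n in n1 + n2},
                             edges=e1 + e2 + bridge)
        res = detect_meta_clusters(net, min_datasets=3)
        parts = {frozenset(res.members(m)) for m in set(res.community.values())}
        assert parts == {frozenset(n1), frozenset(n2)}

    def test_small_community_pruned(self):
        n1, e1 = clique_network(0, 4)
        n2, e2 = clique_network(4, 2)  # only 2 datasets
        net = ClusterNetwork(nodes=n1 + n2, sizes={n: 5 for n in n1 + n2},
                             edges=e1 + e2)
        res = detect_meta_clusters(net, min_datasets=3)
        assert set(res.community) == set(n1)
        assert sorted(res.removed_nodes) == sorted(n2)
        assert all(v >= 3 for v in res.datasets_per_meta.values())

    def test_disconnected_components_never_merge(self):
        n1, e1 = clique_network(0, 3)
        n2, e2 = clique_network(3, 3)
        net = ClusterNetwork(nodes=n1 + n2, sizes={n: 5 for n in n1 + n2},
                             edges=e1 + e2)
        res = detect_meta_clusters(net, min_datasets=3)
        coms = {res.community[n] for n in n1}
        assert len(coms) == 1
        assert coms != {res.community[n] for n in n2}

    def test_node_order_invariance(self):
        n1, e1 = clique_network(0, 4)
        n2, e2 = clique_network(4, 4)
        edges = e1 + e2 + [(n1[0], n2[0], 0.2)]
        net_a = ClusterNetwork(nodes=n1 + n2, sizes={n: 5 for n in n1 + n2},
                               edges=edges)
        net_b = ClusterNetwork(nodes=(n1 + n2)[::-1],
                               sizes={n: 5 for n in n1 + n2},
                               edges=edges[::-1])
        parts = []
        for net in (net_a, net_b):
            res = detect_meta_clusters(net, min_datasets=1)
            parts.append({frozenset(res.members(m))
                          for m in set(res.community.values())})
        assert parts[0] == parts[1]

    def test_sample_assignments_cover_retained_nodes(self):
        n1, e1 = clique_network(0, 3)
        net = ClusterNetwork(nodes=n1, sizes={n: 2 for n in n1}, edges=e1)
        clus = [Clustering(ds, {f"{ds}_a": 1, f"{ds}_b": 1}, 1, {})
                for ds, _ in n1]
        res = detect_meta_clusters(net, min_datasets=3, clusterings=clus)
        assert set(res.sample_assignments) == {
            (ds, s) for ds, _ in n1 for s in (f"{ds}_a", f"{ds}_b")}

    def test_empty_network_errors(self):
        with pytest.raises(ValueError, match="empty"):
            detect_meta_clusters(ClusterNetwork([], {}, []))
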