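import itertools

import networkx as nx
import numpy as np
import pytest

from microclubs import (CorrelationEstimate, OtuTable, build_network,
                        club_statistics, heatmap_order, mcl_cluster,
                        rival_clubs)


def estimate(rho, pvals, taxa=None):
    rho = np.asarray(rho, dtype=float)
    taxa = taxa or [f"T{j}" for j in range(rho.shape[0])]
    return CorrelationEstimate(taxa, rho, np.asarray(pvals, dtype=float))


def uniform_rel(taxa, n_samples=4):
    d = len(taxa)
    return OtuTable([f"s{i}" for i in range(n_samples)], list(taxa),
                    np.full((n_samples, d), 1.0 / d), kind="relative")


def clique_graph(*cliques, weight=0.8):
    g = nx.Graph()
    for members in cliques:
        g.add_nodes_from(members)
        for u, v in itertools.combinations(members, 2):
            g.add_edge(u, v, correlation=weight)
    return g


class TestBuildNetwork:
    def _est(self):
        rho = np.eye(4)
        p = np.ones((4, 4))
        rho[0, 1] = rho[1, 0] = 0.9
        p[0, 1] = p[1, 0] = 0.01
        rho[2, 3] = rho[3, 2] = 0.3
        p[2, 3] = p[3, 2] = 0.02
        return estimate(rho, p)

    def test_all_insignificant_empty(self):
        est = estimate(np.eye(3), np.ones((3, 3)))
        g = build_network(est, uniform_rel(est.taxon_ids))
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_alpha_and_weight(self):
        est = self._est()
        g = build_network(est, uniform_rel(est.taxon_ids), alpha=0.05)
        assert set(map(frozenset, g.edges)) == {frozenset({"T0", "T1"}),
                                                frozenset({"T2", "T3"})}
        assert g.edges["T0", "T1"]["correlation"] == 0.9
        assert g.nodes["T0"]["relative_abundance"] == pytest.approx(0.25)

    def test_min_abs_r_drops_weak_significant_edge(self):
        est = self._est()
        g = build_network(est, uniform_rel(est.taxon_ids), alpha=0.05, min_abs_r=0.5)
        assert list(map(sorted, g.edges)) == [["T0", "T1"]]

    def test_taxa_mismatch_errors(self):
        est = self._est()
        with pytest.raises(ValueError, match="taxa"):
            build_network(est, uniform_rel(["X", "Y", "Z", "W"]))


class TestMclCluster:
    def test_disjoint_triangles_two_clusters(self):
        g = clique_graph(["a", "b", "c"], ["x", "y", "z"])
        cl = mcl_cluster(g)
        assert cl.n_clusters == 2
        assert {cl.assignment["a"], cl.assignment["b"], cl.assignment["c"]} \
            != {cl.assignment["x"]}
        assert len({cl.assignment[n] for n in "abc"}) == 1
        assert len({cl.assignment[n] for n in "xyz"}) == 1

    def test_complete_graph_one_cluster(self):
        cl = mcl_cluster(clique_graph(list("abcde"), weight=0.5))
        assert cl.n_clusters == 1

    def test_two_block_matches_modularity_oracle(self):
        nodes_a = [f"A{i}" for i in range(6)]
        nodes_b = [f"B{i}" for i in range(6)]
        g = clique_graph(nodes_a, nodes_b, weight=0.8)
        g.add_edge("A0", "B0", correlation=0.1)
        for u, v, data in g.edges(data=True):
            data["weight"] = data["correlation"]
        cl = mcl_cluster(g)
        got = frozenset(frozenset(cl.members(c))
                        for c in set(cl.assignment.values()))
        # exhaustive search over all bipartitions for maximum modularity
        nodes = sorted(g.nodes)
        best, best_q = None, -np.inf
        for mask in range(1, 2 ** (len(nodes) - 1)):
            part_a = {nodes[0]} | {nodes[i] for i in range(1, len(nodes))
                                   if mask >> (i - 1) & 1}
            part_b = set(nodes) - part_a
            if not part_b:
                continue
            q = nx.community.modularity(g, [part_a, part_b], weight="weight")
            if q > best_q:
                best_q, best = q, frozenset(map(frozenset, (part_a, part_b)))
        assert got == best

    def test_isolated_nodes_singletons(self):
        g = clique_graph(["a", "b", "c"])
        g.add_node("lonely")
        cl = mcl_cluster(g)
        assert cl.members(cl.assignment["lonely"]) == ["lonely"]

    def test_negative_edges_ignored_by_flow(self):
        g = clique_graph(["a", "b", "c"], ["x", "y", "z"])
        g.add_edge("a", "x", correlation=-0.9)
        assert mcl_cluster(g).n_clusters == 2

    def test_min_weight_filters_weak_bridge(self):
        g = clique_graph(["a", "b", "c"], ["x", "y", "z"])
        g.add_edge("c", "x", correlation=0.2)
        assert mcl_cluster(g, min_weight=0.3).n_clusters == 2

    def test_relabeling_invariance_and_determinism(self):
        g = clique_graph(["a", "b", "c", "d"], ["x", "y", "z"], weight=0.6)
        g.add_edge("d", "x", correlation=0.15)
        cl1 = mcl_cluster(g)
        mapping = {n: f"zz_{n}" for n in g.nodes}
        cl2 = mcl_cluster(nx.relabel_nodes(g, mapping))
        parts1 = frozenset(frozenset(cl1.members(c))
                           for c in set(cl1.assignment.values()))
        parts2 = frozenset(frozenset(m.removeprefix("zz_") for m in cl2.members(c))
                           for c in set(cl2.assignment.values()))
        assert parts1 == parts2
        assert mcl_cluster(g).assignment == cl1.assignment

    def test_clusters_respect_components(self):
        g = clique_graph(["a", "b", "c"], ["x", "y"], ["p", "q", "r", "s"])
        cl = mcl_cluster(g)
        comp_of = {}
        for k, comp in enumerate(nx.connected_components(g)):
            for n in comp:
                comp_of[n] = k
        for cid in set(cl.assignment.values()):
            assert len({comp_of[m] for m in cl.members(cid)}) == 1

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.Graph())


class TestClubStatistics:
    def test_constant_clique_tightness(self):
        g = clique_graph(["a", "b", "c", "d"], weight=0.8)
        cl = mcl_cluster(g)
        report = club_statistics(g, cl)
        assert len(report.social) == 1
        club = report.social[0]
        assert club["size"] == 4 and club["n_edges"] == 6
        assert club["tightness_mean"] == pytest.approx(0.8)
        assert club["tightness_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_singletons_give_no_clubs(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        report = club_statistics(g, mcl_cluster(g))
        assert report.social == []

    def test_min_size_filter(self):
        g = clique_graph(["a", "b"], ["x", "y", "z"], weight=0.5)
        report = club_statistics(g, mcl_cluster(g), min_club_size=3)
        assert [c["size"] for c in report.social] == [3]


class TestRivalClubs:
    def _two_clubs(self, cross_weight, n_cross=None):
        g = clique_graph(["a", "b", "c"], ["x", "y", "z"], weight=0.8)
        pairs = list(itertools.product("abc", "xyz"))
        for u, v in pairs[:n_cross or len(pairs)]:
            g.add_edge(u, v, correlation=cross_weight)
        return g

    def test_fully_negative_connection(self):
        g = self._two_clubs(-0.8)
        cl = mcl_cluster(g)
        report = rival_clubs(g, cl)
        assert len(report.rivals) == 1
        assert report.rivals[0]["mean_correlation"] == pytest.approx(-0.8)
        assert report.rivals[0]["n_edges"] == 9

    def test_positive_connection_not_rival(self):
        g = clique_graph(["a", "b", "c"], ["x", "y", "z"], weight=0.8)
        g.add_edge("a", "x", correlation=0.5)
        report = rival_clubs(g, mcl_cluster(g, min_weight=0.6))
        assert report.rivals == []

    def test_min_edges_threshold(self):
        g = self._two_clubs(-0.8, n_cross=2)
        report = rival_clubs(g, mcl_cluster(g), min_rival_edges=3)
        assert report.rivals == []


class TestHeatmapOrder:
    def test_all_singletons_stable_order(self):
        est = estimate(np.eye(4), np.ones((4, 4)), taxa=["d", "b", "a", "c"])
        cl = type("C", (), {"assignment": {t: i for i, t in enumerate(est.taxon_ids)}})
        assert heatmap_order(est, cl) == ["a", "b", "c", "d"]

    def test_larger_cluster_first(self):
        taxa = [f"T{j}" for j in range(8)]
        rho = np.eye(8)
        cl = type("C", (), {"assignment": {t: (0 if j < 3 else 1)
                                           for j, t in enumerate(taxa)}})
        order = heatmap_order(estimate(rho, np.ones((8, 8)), taxa), cl)
        assert set(order[:5]) == set(taxa[3:])

    def test_block_structure_restored(self):
        rng = np.random.default_rng(0)
        d = 12
        rho = np.full((d, d), 0.05)
        blocks = [list(range(0, 4)), list(range(4, 8)), list(range(8, 12))]
        for blk in blocks:
            for i, j in itertools.combinations(blk, 2):
                rho[i, j] = rho[j, i] = 0.8
        np.fill_diagonal(rho, 1.0)
        perm = rng.permutation(d)
        taxa = [f"T{j:02d}" for j in range(d)]
        shuffled = estimate(rho[np.ix_(perm, perm)], np.ones((d, d)),
                            [taxa[i] for i in perm])
        assignment = {taxa[i]: b for b, blk in enumerate(blocks) for i in blk}
        cl = type("C", (), {"assignment": assignment})
        order = heatmap_order(shuffled, cl)
        oidx = [shuffled.taxon_ids.index(t) for t in order]
        reordered = shuffled.rho[np.ix_(oidx, oidx)]
        diag_blocks = [reordered[0:4, 0:4], reordered[4:8, 4:8], reordered[8:12, 8:12]]
        off = reordered[0:4, 4:12]
        within_mean = np.mean([np.abs(b[~np.eye(4, dtype=bool)]).mean()
                               for b in diag_blocks])
        assert within_mean > np.abs(off).mean() + 0.5
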