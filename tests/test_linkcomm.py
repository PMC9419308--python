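"""Link communities: edge similarity, single-linkage clustering, density cuts."""

import itertools

import numpy as np
import pytest

import dietnet as dn
from conftest import make_network


# ---------------------------------------------------------------------------
# independent oracle: brute-force link communities for small graphs


def oracle_similarity(edges, e1, e2):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    shared = set(e1) & set(e2)
    (k,) = shared
    i = e1[0] if e1[1] == k else e1[1]
    j = e2[0] if e2[1] == k else e2[1]
    ni = adj[i] | {i}
    nj = adj[j] | {j}
    return len(ni & nj) / len(ni | nj)


def oracle_best_cut(edges):
    """Exhaustive search over all single-linkage cuts; returns (D, n_communities)."""
    edges = [tuple(sorted(e)) for e in edges]
    sims = {}
    for e1, e2 in itertools.combinations(edges, 2):
        if len(set(e1) & set(e2)) == 1:
            sims[(e1, e2)] = oracle_similarity(edges, e1, e2)
    thresholds = sorted(set(sims.values()), reverse=True) + [float("inf")]

    def partition(t):
        parent = {e: e for e in edges}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for (e1, e2), s in sims.items():
            if s >= t:
                r1, r2 = find(e1), find(e2)
                if r1 != r2:
                    parent[r1] = r2
        groups = {}
        for e in edges:
            groups.setdefault(find(e), set()).add(e)
        return list(groups.values())

    def density(comms):
        total = 0.0
        for comm in comms:
            m = len(comm)
            nodes = {n for e in comm for n in e}
            nc = len(nodes)
            if nc > 2:
                total += m * (m - (nc - 1)) / ((nc - 2) * (nc - 1))
        return 2.0 / len(edges) * total

    best = None
    for t in thresholds:
        comms = partition(t)
        key = (-density(comms), len(comms))
        if best is None or key < best:
            best = key
    return -best[0], best[1]


# ---------------------------------------------------------------------------


class TestEdgeSimilarity:
    def test_closed_triad_has_similarity_one(self):
        net = make_network([("i", "k"), ("j", "k"), ("i", "j")])
        assert dn.edge_similarity(net, ("i", "k"), ("j", "k")) == pytest.approx(1.0)

    def test_bare_path_gives_one_third(self):
        net = make_network([("i", "k"), ("j", "k")])
        assert dn.edge_similarity(net, ("i", "k"), ("j", "k")) == pytest.approx(1 / 3)

    def test_disjoint_outside_neighborhoods_by_enumeration(self):
        # i and j share only k; each has two private neighbors
        net = make_network([("i", "k"), ("j", "k"), ("i", "p"), ("i", "q"), ("j", "r"), ("j", "s")])
        # N+(i) = {i,k,p,q}, N+(j) = {j,k,r,s}; intersection {k}, union 7 nodes
        assert dn.edge_similarity(net, ("i", "k"), ("j", "k")) == pytest.approx(1 / 7)

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(3)
        nodes = list("abcdefg")
        for _ in range(20):
            edges = [
                (a, b)
                for a, b in itertools.combinations(nodes, 2)
                if rng.random() < 0.3
            ]
            if len(edges) < 2:
                continue
            net = make_network(edges)
            canon = [tuple(sorted(e)) for e in edges]
            for e1, e2 in itertools.combinations(canon, 2):
                if len(set(e1) & set(e2)) == 1:
                    assert dn.edge_similarity(net, e1, e2) == pytest.approx(
                        oracle_similarity(canon, e1, e2)
                    )

    def test_rejects_edges_sharing_zero_or_two_nodes(self):
        net = make_network([("a", "b"), ("c", "d"), ("a", "c")])
        with pytest.raises(dn.ValidationError):
            dn.edge_similarity(net, ("a", "b"), ("c", "d"))
        with pytest.raises(dn.ValidationError):
            dn.edge_similarity(net, ("a", "b"), ("a", "b"))


class TestClusterEdges:
    def test_two_shared_triangles_split_into_two_clusters(self, two_triangles):
        dendro = dn.cluster_edges(two_triangles)
        assert len(dendro.leaves) == 6
        # below the top similarity the two triangles separate
        comm = dn.cut_at_max_density(dendro)
        assert len(comm) == 2

    def test_single_edge_degenerate_dendrogram(self):
        net = make_network([("a", "b")])
        dendro = dn.cluster_edges(net)
        assert dendro.leaves == (("a", "b"),)
        assert dendro.merges == ()

    def test_equal_similarities_collapse_at_one_height(self):
        # star: all edge pairs share the hub and have identical similarity
        net = make_network([("h", "a"), ("h", "b"), ("h", "c")])
        dendro = dn.cluster_edges(net)
        assert len(set(dendro.heights)) == 1

    def test_heights_non_increasing(self, two_triangles):
        dendro = dn.cluster_edges(two_triangles)
        h = dendro.heights
        assert all(h[i] >= h[i + 1] for i in range(len(h) - 1))


class TestPartitionDensity:
    def test_triangle_community_has_density_one(self):
        comms = [frozenset({("a", "b"), ("a", "c"), ("b", "c")})]
        assert dn.partition_density(comms, 3) == pytest.approx(1.0)

    def test_fully_fragmented_partition_has_density_zero(self):
        comms = [frozenset({("a", "b")}), frozenset({("c", "d")})]
        assert dn.partition_density(comms, 2) == pytest.approx(0.0)

    def test_tree_community_has_zero_density(self):
        # chain of 3 edges over 4 nodes: m=3, n=4 -> zero contribution
        comms = [frozenset({("a", "b"), ("b", "c"), ("c", "d")})]
        assert dn.partition_density(comms, 3) == pytest.approx(0.0)

    def test_empty_community_rejected(self):
        with pytest.raises(dn.ValidationError):
            dn.partition_density([frozenset()], 1)

    def test_invariant_to_node_relabeling(self):
        comms = [
            frozenset({("a", "b"), ("a", "c"), ("b", "c")}),
            frozenset({("c", "d"), ("d", "e")}),
        ]
        relabel = {"a": "z", "b": "y", "c": "x", "d": "w", "e": "v"}
        mapped = [
            frozenset(tuple(sorted((relabel[u], relabel[v]))) for u, v in comm)
            for comm in comms
        ]
        assert dn.partition_density(comms, 5) == pytest.approx(dn.partition_density(mapped, 5))


class TestCutAtMaxDensity:
    def test_two_triangles_give_two_communities_with_shared_membership(self, two_triangles):
        comm = dn.cut_at_max_density(dn.cluster_edges(two_triangles))
        assert len(comm) == 2
        assert comm.membership["v"] == 2
        assert all(comm.membership[n] == 1 for n in "abxy")

    def test_single_triangle_is_one_clique_community(self):
        net = make_network([("a", "b"), ("a", "c"), ("b", "c")])
        comm = dn.cut_at_max_density(dn.cluster_edges(net))
        assert len(comm) == 1
        assert comm.partition_density_value == pytest.approx(1.0)

    def test_equals_exhaustive_oracle_on_small_graph_library(self):
        """Every connected graph on <= 7 nodes with <= 7 edges, against brute force."""
        from networkx.generators.atlas import graph_atlas_g
        import networkx as nx

        checked = 0
        for g in graph_atlas_g():
            if (
                g.number_of_nodes() < 3
                or g.number_of_nodes() > 7
                or g.number_of_edges() < 2
                or g.number_of_edges() > 7
                or not nx.is_connected(g)
            ):
                continue
            labels = {i: chr(ord("a") + i) for i in g.nodes}
            edges = [(labels[u], labels[v]) for u, v in g.edges]
            net = make_network(edges)
            comm = dn.cut_at_max_density(dn.cluster_edges(net))
            d_oracle, k_oracle = oracle_best_cut(edges)
            assert comm.partition_density_value == pytest.approx(d_oracle), edges
            assert len(comm) == k_oracle, edges
            checked += 1
        assert checked == 107  # the atlas library really was exhausted

    def test_membership_counts_sum_to_community_sizes(self, two_triangles):
        comm = dn.cut_at_max_density(dn.cluster_edges(two_triangles))
        assert sum(comm.membership.values()) == sum(len(ns) for ns in comm.node_sets)


class TestHealthyShapeRecovery:
    def test_hub_sharing_two_community_block_recovered_end_to_end(self):
        """A healthy-like block — two dense food-group clusters sharing the
        cooked-vegetables hub — comes back as exactly two link communities
        with hub membership 2 in >= 90% of synthetic replicates."""
        import itertools

        A = ["cooked_vegetables", "mushroom", "grains", "legumes"]
        B = ["cooked_vegetables", "fresh_fruits", "green_leafy_vegetables", "nuts"]
        edges = tuple(
            (a, b, 0.20) for grp in (A, B) for a, b in itertools.combinations(grp, 2)
        )
        structure = dn.PlantedStructure(blocks=(dn.Block("healthy_like", edges),))
        groups = tuple(sorted({n for e in edges for n in e[:2]}))
        omega = dn.build_planted_precision(structure, groups=groups)
        ok = 0
        for rep in range(10):
            cfg = dn.CohortConfig(
                n_subjects=5000, seed=500 + rep, marginals={g: (10.0, 2.0) for g in groups}
            )
            z, _ = dn.standardize(dn.simulate_intakes(cfg, omega))
            rho = dn.precision_to_partial(dn.estimate_precision(z, dn.select_lambda(z).lam))
            nets = dn.extract_networks(rho)
            if len(nets) != 1:
                continue
            comm = dn.cut_at_max_density(dn.cluster_edges(nets.networks[0]))
            if len(comm) == 2 and comm.membership.get("cooked_vegetables", 0) == 2:
                ok += 1
        assert ok >= 9


class TestCentralityReport:
    def test_shared_node_of_two_triangles_is_central(self, two_triangles):
        comm = dn.cut_at_max_density(dn.cluster_edges(two_triangles))
        report = dn.centrality_report(comm, two_triangles)
        assert report.loc["v", "primary_central"]
        assert report.loc["v", "membership"] == 2
        assert not report.loc["a", "central"]

    def test_path_midpoint_wins_degree_tiebreak(self):
        net = make_network([("a", "b"), ("b", "c")])
        comm = dn.cut_at_max_density(dn.cluster_edges(net))
        report = dn.centrality_report(comm, net)
        assert report.loc["b", "primary_central"]
        assert report.loc["b", "degree"] == 2

    def test_clique_tie_flags_all_and_picks_alphabetical(self):
        net = make_network([("a", "b"), ("a", "c"), ("b", "c")])
        comm = dn.cut_at_max_density(dn.cluster_edges(net))
        report = dn.centrality_report(comm, net)
        assert report["central"].all()  # tie disclosed
        assert report[report["primary_central"]].index.tolist() == ["a"]
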