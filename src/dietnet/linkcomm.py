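"""Overlapping link communities within a dietary network.

Communities are detected on the *edges* of a network rather than its nodes,
so a food group may belong to several communities.  The procedure is the
classic link-community construction: every pair of adjacent edges (sharing
exactly one node) gets a similarity score — the Jaccard index of the inclusive
neighborhoods of the two non-shared endpoints — the edges are merged by
single-linkage agglomeration on that similarity, and the dendrogram is cut at
the height maximizing the partition density

    D = (2/M) * sum_c m_c (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1)),

summed over communities with n_c > 2 nodes (m_c edges), which is 1 when every
community is a clique and 0 for tree-like or fully fragmented partitions.

A food group's community-membership count is its centrality signal: the group
in the most communities (ties broken by degree, then alphabetically) is the
hub around which the network is consumed.

All orderings and tie-breaks are lexicographic on edge labels, so repeated
runs give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .ggm import Network

__all__ = [
    "EdgeDendrogram",
    "CommunitySet",
    "edge_similarity",
    "cluster_edges",
    "partition_density",
    "cut_at_max_density",
    "centrality_report",
]

Edge = tuple[str, str]


def _canon(edge) -> Edge:
    a, b = edge[0], edge[1]
    return (a, b) if a <= b else (b, a)


def _adjacency(network: Network) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {n: set() for n in network.nodes}
    for a, b, *_ in network.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _weights(network: Network) -> dict[Edge, float]:
    return {_canon((a, b)): abs(rho) for a, b, rho, _ in network.edges}


def edge_similarity(
    network: Network,
    e1: Edge,
    e2: Edge,
    weighted: bool = False,
) -> float:
    """Similarity of two edges that share exactly one endpoint.

    Unweighted (default): Jaccard index of the inclusive neighborhoods
    N+(x) = {x} + neighbors(x) of the two non-shared endpoints.  Weighted:
    Tanimoto coefficient of the |rho|-weighted inclusive neighborhood vectors.
    """
    e1, e2 = _canon(e1), _canon(e2)
    shared = set(e1) & set(e2)
    if len(shared) != 1:
        raise ValidationError(
            f"edges {e1} and {e2} share {len(shared)} nodes; similarity needs exactly one"
        )
    (k,) = shared
    i = e1[0] if e1[1] == k else e1[1]
    j = e2[0] if e2[1] == k else e2[1]
    adj = _adjacency(network)
    if not weighted:
        ni = adj[i] | {i}
        nj = adj[j] | {j}
        return len(ni & nj) / len(ni | nj)
    w = _weights(network)
    mean_w = {n: (sum(w[_canon((n, m))] for m in adj[n]) / len(adj[n]) if adj[n] else 0.0) for n in network.nodes}

    def vec(x: str) -> dict[str, float]:
        v = {m: w[_canon((x, m))] for m in adj[x]}
        v[x] = mean_w[x]
        return v

    ai, aj = vec(i), vec(j)
    dot = sum(ai[n] * aj[n] for n in set(ai) & set(aj))
    ni2 = sum(v * v for v in ai.values())
    nj2 = sum(v * v for v in aj.values())
    denom = ni2 + nj2 - dot
    return dot / denom if denom > 0 else 0.0


@dataclass
class EdgeDendrogram:
    """Single-linkage merge history over the edges of one network."""

    leaves: tuple[Edge, ...]  # lexicographically sorted edges
    # merges in execution order: (similarity height, cluster_a_repr, cluster_b_repr)
    merges: tuple[tuple[float, int, int], ...]
    # pairwise similarities actually computed (adjacent edge pairs)
    pair_sims: tuple[tuple[int, int, float], ...]

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(h for h, _, _ in self.merges)

    def partition_at(self, threshold: float) -> list[set[int]]:
        """Edge clusters after applying every merge with height >= threshold."""
        parent = list(range(len(self.leaves)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for h, a, b in self.merges:
            if h >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
        clusters: dict[int, set[int]] = {}
        for idx in range(len(self.leaves)):
            clusters.setdefault(find(idx), set()).add(idx)
        return [clusters[k] for k in sorted(clusters)]


@dataclass
class CommunitySet:
    """Edge communities at the chosen dendrogram cut."""

    communities: list[frozenset[Edge]]  # each a set of edges
    node_sets: list[tuple[str, ...]]  # induced node set per community, sorted
    membership: dict[str, int]  # per-node community-membership count
    partition_density_value: float
    cut_height: float

    def __len__(self) -> int:
        return len(self.communities)


def cluster_edges(network: Network, weighted: bool = False) -> EdgeDendrogram:
    """Single-linkage agglomerative clustering of a network's edges.

    Similarities are computed for every adjacent edge pair; merges are applied
    in decreasing similarity, ties broken by lexicographic edge order, so the
    dendrogram is fully deterministic.  A single-edge network yields a
    degenerate one-leaf dendrogram.
    """
    edges = sorted(_canon((a, b)) for a, b, *_ in network.edges)
    index = {e: i for i, e in enumerate(edges)}
    adj = _adjacency(network)
    pairs: list[tuple[int, int, float]] = []
    for k, neigh in sorted(adj.items()):
        incident = sorted(_canon((k, m)) for m in neigh)
        for x in range(len(incident)):
            for y in range(x + 1, len(incident)):
                e1, e2 = incident[x], incident[y]
                s = edge_similarity(network, e1, e2, weighted=weighted)
                pairs.append((index[e1], index[e2], s))
    # decreasing similarity; ties by edge indices for determinism
    order = sorted(pairs, key=lambda t: (-t[2], t[0], t[1]))
    parent = list(range(len(edges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges: list[tuple[float, int, int]] = []
    for i, j, s in order:
        ri, rj = find(i), find(j)
        if ri != rj:
            merges.append((s, min(ri, rj), max(ri, rj)))
            parent[max(ri, rj)] = min(ri, rj)
    return EdgeDendrogram(tuple(edges), tuple(merges), tuple(sorted(pairs)))


def partition_density(communities: list[frozenset[Edge]], n_edges_total: int) -> float:
    """Partition density D of an edge partition.

    Communities with two nodes (a single link) contribute 0; a community with
    no edges is invalid.
    """
    if n_edges_total <= 0:
        raise ValidationError("total edge count must be positive")
    total = 0.0
    for comm in communities:
        m = len(comm)
        if m == 0:
            raise ValidationError("empty edge community")
        nodes = {n for e in comm for n in e}
        n_c = len(nodes)
        if n_c <= 2:
            continue
        total += m * (m - (n_c - 1)) / ((n_c - 2) * (n_c - 1))
    return 2.0 / n_edges_total * total


def _partition_to_communities(dendro: EdgeDendrogram, clusters: list[set[int]]) -> list[frozenset[Edge]]:
    return [frozenset(dendro.leaves[i] for i in cl) for cl in clusters]


def cut_at_max_density(dendrogram: EdgeDendrogram) -> CommunitySet:
    """Cut the edge dendrogram at the partition-density maximum.

    Every distinct merge height is evaluated (plus the fully fragmented cut);
    ties go to the partition with fewer communities, then to the higher cut.
    """
    m_total = len(dendrogram.leaves)
    # candidate thresholds: just above every height (fragmented side) and the
    # heights themselves; evaluating at each distinct height applies all
    # merges at >= that similarity.
    heights = sorted(set(dendrogram.heights), reverse=True)
    candidates = [float("inf")] + heights  # inf => no merges applied
    best: tuple[float, int, float, list[set[int]]] | None = None
    for t in candidates:
        clusters = dendrogram.partition_at(t)
        communities = _partition_to_communities(dendrogram, clusters)
        d = partition_density(communities, m_total)
        key = (-d, len(clusters), -t)
        if best is None or key < (-best[0], best[1], -best[2]):
            best = (d, len(clusters), t, clusters)
    assert best is not None
    d, _, t, clusters = best
    communities = _partition_to_communities(dendrogram, clusters)
    node_sets = [tuple(sorted({n for e in comm for n in e})) for comm in communities]
    membership: dict[str, int] = {}
    for ns in node_sets:
        for n in ns:
            membership[n] = membership.get(n, 0) + 1
    order = sorted(range(len(communities)), key=lambda i: node_sets[i])
    return CommunitySet(
        communities=[communities[i] for i in order],
        node_sets=[node_sets[i] for i in order],
        membership=membership,
        partition_density_value=d,
        cut_height=t,
    )


def centrality_report(communities: CommunitySet, network: Network) -> pd.DataFrame:
    """Per-node membership counts, degrees and the central-group flag.

    Central group(s): maximal community membership, ties broken by maximal
    degree, then alphabetically; every node tied on (membership, degree) with
    the winner is flagged so ties are visible in the output.
    """
    degree = network.degree()
    rows = []
    for node in sorted(network.nodes):
        rows.append(
            {
                "node": node,
                "membership": communities.membership.get(node, 0),
                "degree": degree.get(node, 0),
            }
        )
    df = pd.DataFrame(rows)
    ranked = df.sort_values(["membership", "degree", "node"], ascending=[False, False, True])
    top = ranked.iloc[0]
    df["central"] = (df["membership"] == top["membership"]) & (df["degree"] == top["degree"])
    df["primary_central"] = df["node"] == top["node"]
    return df.set_index("node")
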