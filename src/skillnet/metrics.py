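"""Graph statistics for the participant networks.

Density, Jaccard similarity between session networks, global clustering, and
modularity with greedy community detection.  Clustering defaults to the mean
of local clustering coefficients (nodes of degree < 2 contribute 0); the
transitivity variant is available behind a flag.  Modularity Q is always
re-evaluated from the Newman–Girvan formula on the returned partition, so the
reported Q never depends on internals of the community search.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping

import networkx as nx

from .errors import UndefinedMetricError
from .network import SimilarityNetwork, require_same_roster


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as tabulated reports conventionally do
    (banker's rounding would turn 0.305 into 0.30, not 0.31)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    density: float
    clustering_coefficient: float | None
    modularity_Q: float | None
    partition: dict[str, int] | None


@dataclass
class SessionComparison:
    """Jaccard overlap of the edge sets of two session networks."""

    pair: tuple[int, int]
    jaccard: float
    shared_edges: int
    union_edges: int

    @property
    def percent_difference(self) -> float:
        """How much the two session networks differ, as (1 - J) x 100."""
        return (1.0 - self.jaccard) * 100.0


def density(net: SimilarityNetwork) -> float:
    """Fraction of realised edges: 2E / (N(N-1))."""
    n = net.n_nodes
    if n < 2:
        raise UndefinedMetricError(f"density undefined for {n} node(s)")
    return 2.0 * net.n_edges / (n * (n - 1))


def jaccard_similarity(g1: SimilarityNetwork, g2: SimilarityNetwork) -> float:
    """|E1 ∩ E2| / |E1 ∪ E2| over a shared roster.

    Two empty networks are maximally similar by convention: J(∅, ∅) = 1.
    """
    require_same_roster(g1, g2)
    union = g1.edges | g2.edges
    if not union:
        return 1.0
    return len(g1.edges & g2.edges) / len(union)


def global_clustering(net: SimilarityNetwork, variant: str = "average") -> float:
    """Global clustering coefficient.

    ``variant='average'`` (default) is the mean local clustering coefficient;
    ``variant='transitivity'`` is 3 x triangles / connected triples.
    """
    if net.n_nodes < 3:
        raise UndefinedMetricError(
            f"clustering undefined for {net.n_nodes} node(s)"
        )
    g = net.to_networkx()
    if variant == "average":
        return nx.average_clustering(g)
    if variant == "transitivity":
        return nx.transitivity(g)
    raise UndefinedMetricError(f"unknown clustering variant {variant!r}")


def modularity_q(net: SimilarityNetwork, partition: Mapping[str, int]) -> float:
    """Newman–Girvan modularity of a given partition:
    Q = sum_c [ L_c / m - (d_c / 2m)^2 ]."""
    m = net.n_edges
    if m == 0:
        raise UndefinedMetricError("modularity undefined for an edgeless graph")
    missing = [p for p in net.participants if p not in partition]
    if missing:
        raise UndefinedMetricError(f"partition does not cover nodes {missing}")
    intra: dict[int, int] = {}
    deg_sum: dict[int, int] = {}
    for node in net.participants:
        deg_sum.setdefault(partition[node], 0)
    for u, v in net.edges:
        deg_sum[partition[u]] += 1
        deg_sum[partition[v]] += 1
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0) + 1
    q = 0.0
    for c, d_c in deg_sum.items():
        q += intra.get(c, 0) / m - (d_c / (2.0 * m)) ** 2
    return q


def modularity(net: SimilarityNetwork) -> tuple[dict[str, int], float]:
    """Greedy modularity maximisation with a deterministic community order.

    Communities from the greedy agglomerative (CNM) search are renumbered by
    their lowest participant id, so identical graphs always yield identical
    partitions.  Returns ``(partition, Q)`` with Q re-evaluated from the
    standard formula on that partition.
    """
    if net.n_edges == 0:
        raise UndefinedMetricError("modularity undefined for an edgeless graph")
    g = net.to_networkx()
    communities = nx.community.greedy_modularity_communities(g)
    ordered = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    partition = {node: i for i, comm in enumerate(ordered) for node in comm}
    return partition, modularity_q(net, partition)


def subnetwork_density(net: SimilarityNetwork) -> dict[int, dict]:
    """Density of each connected component (sub-network).

    Components are numbered by their lowest participant id.  Singleton
    components are reported with ``density: None`` since density is undefined
    below two nodes.
    """
    if net.n_nodes < 2:
        raise UndefinedMetricError("need at least 2 nodes")
    g = net.to_networkx()
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    out: dict[int, dict] = {}
    for i, members in enumerate(comps):
        if len(members) < 2:
            d = None
        else:
            sub = SimilarityNetwork(
                participants=members,
                edges={e for e in net.edges if e[0] in set(members)},
            )
            d = density(sub)
        out[i] = {"members": members, "density": d}
    return out


def network_metrics(net: SimilarityNetwork, clustering_variant: str = "average") -> NetworkMetrics:
    """Bundle the per-network statistics; clustering and modularity fall back
    to None where undefined (too few nodes, no edges) so degenerate networks
    still flow through the pipeline."""
    try:
        cc = global_clustering(net, clustering_variant)
    except UndefinedMetricError:
        cc = None
    try:
        partition, q = modularity(net)
    except UndefinedMetricError:
        partition, q = None, None
    return NetworkMetrics(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        density=density(net),
        clustering_coefficient=cc,
        modularity_Q=q,
        partition=partition,
    )


def compare_sessions(
    nets: Mapping[int, SimilarityNetwork]
) -> list[SessionComparison]:
    """Jaccard similarity for every unordered pair of session networks."""
    if len(nets) < 2:
        raise UndefinedMetricError("need at least 2 sessions to compare")
    sessions = sorted(nets)
    base = nets[sessions[0]]
    for s in sessions[1:]:
        require_same_roster(base, nets[s])
    out = []
    for a, b in combinations(sessions, 2):
        g1, g2 = nets[a], nets[b]
        shared = len(g1.edges & g2.edges)
        union = len(g1.edges | g2.edges)
        j = 1.0 if union == 0 else shared / union
        out.append(
            SessionComparison(pair=(a, b), jaccard=j, shared_edges=shared, union_edges=union)
        )
    return out
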