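"""Hand-rolled brute-force graph oracles, independent of the package and of
networkx: plain loops over node pairs and triples.  Used to cross-check the
implementation's metrics on exhaustively enumerated small graphs."""

from itertools import combinations


def density_bf(nodes, edges):
    n = len(nodes)
    possible = n * (n - 1) // 2
    return len(edges) / possible


def neighbors_bf(node, edges):
    out = set()
    for u, v in edges:
        if u == node:
            out.add(v)
        elif v == node:
            out.add(u)
    return out


def avg_clustering_bf(nodes, edges):
    eset = {frozenset(e) for e in edges}
    total = 0.0
    for node in nodes:
        nbrs = sorted(neighbors_bf(node, edges))
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in combinations(nbrs, 2) if frozenset((a, b)) in eset
        )
        total += links / (k * (k - 1) / 2)
    return total / len(nodes)


def jaccard_bf(edges1, edges2):
    e1 = {frozenset(e) for e in edges1}
    e2 = {frozenset(e) for e in edges2}
    union = e1 | e2
    if not union:
        return 1.0
    return len(e1 & e2) / len(union)


def modularity_bf(nodes, edges, partition):
    """Q via the pairwise form: (1/2m) sum_ij (A_ij - d_i d_j / 2m) delta."""
    m = len(edges)
    eset = {frozenset(e) for e in edges}
    deg = {u: len(neighbors_bf(u, edges)) for u in nodes}
    q = 0.0
    for i in nodes:
        for j in nodes:
            if partition[i] != partition[j]:
                continue
            a_ij = 1.0 if i != j and frozenset((i, j)) in eset else 0.0
            q += a_ij - deg[i] * deg[j] / (2.0 * m)
    return q / (2.0 * m)


def all_graphs(nodes):
    """Yield every labelled simple graph on the given nodes as an edge set."""
    pairs = list(combinations(nodes, 2))
    for mask in range(1 << len(pairs)):
        yield {pairs[i] for i in range(len(pairs)) if mask >> i & 1}
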