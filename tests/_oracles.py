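"""Independent brute-force reference implementations used only by tests.

Everything here is written deliberately naively (dicts, explicit loops,
breadth-first search) so that it shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


# ---------------------------------------------------------------------------
# graphs as adjacency sets over nodes 0..n-1
# ---------------------------------------------------------------------------


def edges_to_adj(n, edges):
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj, start):
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def is_connected(adj):
    n = len(adj)
    return n <= 1 or len(bfs_distances(adj, next(iter(adj)))) == n


def degree_list(adj):
    return [len(adj[i]) for i in sorted(adj)]


def degree_distribution(adj):
    n = len(adj)
    out = {}
    for k in degree_list(adj):
        out[k] = out.get(k, 0) + 1
    return {k: c / n for k, c in out.items()}


def clustering_coefficients(adj):
    out = []
    for i in sorted(adj):
        nbrs = sorted(adj[i])
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
        out.append(2.0 * links / (k * (k - 1)))
    return out


def sum_pairwise_distances(adj):
    total = 0
    for i in adj:
        dist = bfs_distances(adj, i)
        if len(dist) != len(adj):
            raise ValueError("disconnected")
        total += sum(dist.values())
    return total  # over ordered pairs


def average_path_length(adj):
    n = len(adj)
    return sum_pairwise_distances(adj) / (n * (n - 1))


def cohesion(adj):
    n = len(adj)
    if n == 1:
        return 1.0
    return (n - 1) / sum_pairwise_distances(adj)


def contract(adj, i):
    """Merge i and its neighbourhood into one supernode (labelled -1)."""
    merged = {i} | adj[i]
    kept = [u for u in adj if u not in merged]
    new_nodes = kept + [-1]
    new_adj = {u: set() for u in new_nodes}
    for u in kept:
        for v in adj[u]:
            if v in merged:
                new_adj[u].add(-1)
                new_adj[-1].add(u)
            elif v in new_adj:
                new_adj[u].add(v)
    return new_adj


def node_importance(adj):
    """IMC via direct recomputation of pairwise distances before/after."""
    base = cohesion(adj)
    out = []
    for i in sorted(adj):
        contracted = contract(adj, i)
        out.append(1.0 - base / cohesion(contracted))
    return out


def all_connected_graphs(n):
    """Yield edge sets of every connected labelled graph on n nodes."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if bits >> k & 1]
        adj = edges_to_adj(n, edges)
        if is_connected(adj):
            yield edges


# ---------------------------------------------------------------------------
# histogram entropies from integer symbol series
# ---------------------------------------------------------------------------


def symbol_entropy(seq):
    n = len(seq)
    counts = {}
    for s in seq:
        counts[s] = counts.get(s, 0) + 1
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def symbol_joint_entropy(a, b):
    return symbol_entropy(list(zip(a, b)))


def symbol_mutual_information(a, b):
    return symbol_entropy(a) + symbol_entropy(b) - symbol_joint_entropy(a, b)
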