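"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, Floyd-Warshall, direct
formula evaluation) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def set_partitions(items):
    """All set partitions of ``items`` (Bell-number many)."""
    items = list(items)
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for k, subset in enumerate(smaller):
            yield smaller[:k] + [[first] + subset] + smaller[k + 1 :]
        yield [[first]] + smaller


def partition_to_labels(partition, n):
    labels = np.zeros(n, dtype=int)
    for k, block in enumerate(partition):
        labels[block] = k + 1
    return labels


def signed_q_direct(w, labels):
    """Signed asymmetric modularity computed pairwise from the definition."""
    w = np.asarray(w, float).copy()
    np.fill_diagonal(w, 0.0)
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    vp, vn = wp.sum(), wn.sum()

    def q_part(a, v):
        if v == 0:
            return 0.0
        s = a.sum(axis=1)
        q = 0.0
        n = len(a)
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    q += (a[i, j] - s[i] * s[j] / v) / v
        return q

    return q_part(wp, vp) - (vn / (vp + vn)) * q_part(wn, vn)


def exhaustive_best_q(w):
    """Maximum signed modularity over ALL partitions of the nodes."""
    n = len(w)
    best = -np.inf
    for part in set_partitions(range(n)):
        q = signed_q_direct(w, partition_to_labels(part, n))
        best = max(best, q)
    return best


def floyd_warshall_lengths(weights):
    """All-pairs shortest-path lengths on edge lengths 1/weight."""
    n = len(weights)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                dist[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def brute_path_length(weights):
    dist = floyd_warshall_lengths(weights)
    iu = np.triu_indices(len(weights), 1)
    return dist[iu].mean()


def brute_global_efficiency(weights):
    dist = floyd_warshall_lengths(weights)
    iu = np.triu_indices(len(weights), 1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[iu]
    inv[np.isinf(dist[iu])] = 0.0
    return inv.mean()


def brute_onnela_clustering(weights):
    """Per-node geometric-mean triangle intensity, weights scaled by the max."""
    n = len(weights)
    w = np.asarray(weights, float) / weights.max()
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(weights[i] > 0)
        k = len(nb)
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.permutations(nb, 2):
            if weights[j, h] > 0:
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def brute_betweenness(weights):
    """Betweenness by enumerating all simple paths between every pair."""
    n = len(weights)
    adj = {i: [j for j in range(n) if weights[i, j] > 0] for i in range(n)}

    def all_paths(s, t):
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, length = stack.pop()
            if node == t:
                yield path, length
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt], length + 1.0 / weights[node, nxt]))

    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = list(all_paths(s, t))
            if not paths:
                continue
            best = min(length for _, length in paths)
            shortest = [p for p, length in paths if np.isclose(length, best)]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def greedy_threshold_reference(weights, density):
    """Literal ascending-removal thresholding that skips bridges.

    Removes positive edges weakest-first; an edge whose removal would
    disconnect the graph is retained; stops when the retained count reaches
    round(density * N(N-1)/2).
    """
    import networkx as nx

    w = np.asarray(weights, float)
    n = len(w)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, weight=w[i, j])
    target = int(np.floor(density * n * (n - 1) / 2.0 + 0.5))
    edges = sorted(g.edges(data="weight"), key=lambda e: (e[2], e[0], e[1]))
    for u, v, wt in edges:
        if g.number_of_edges() <= target:
            break
        g.remove_edge(u, v)
        if not nx.is_connected(g):
            g.add_edge(u, v, weight=wt)
    out = np.zeros_like(w)
    for u, v, wt in g.edges(data="weight"):
        out[u, v] = out[v, u] = wt
    return out


def random_connected_weighted_graph(n, density, rng, signed=False):
    """Random symmetric weight matrix whose positive part is connected."""
    while True:
        w = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        mask = rng.random(len(iu[0])) < density
        vals = rng.uniform(0.1, 1.0, size=len(iu[0])) * mask
        if signed:
            vals *= np.where(rng.random(len(iu[0])) < 0.4, -1.0, 1.0)
        w[iu] = vals
        w = w + w.T
        pos = w > 0
        # connectivity of positive part via BFS
        seen = {0}
        frontier = [0]
        while frontier:
            nxt = []
            for i in frontier:
                for j in np.flatnonzero(pos[i]):
                    if j not in seen:
                        seen.add(j)
                        nxt.append(j)
            frontier = nxt
        if len(seen) == n:
            return w
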