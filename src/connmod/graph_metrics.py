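"""Connectivity-preserving thresholding and weighted graph topology metrics.

Penalized matrices are rendered sparse by discarding the weakest positive
edges while never disconnecting the graph; the surviving weighted graph is
summarised by path length, clustering, efficiency, betweenness and a
small-world index normalised against degree-preserving random references.
Shortest-path quantities use edge lengths 1/weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from connmod.connectivity import ConnectivityMatrix
from connmod.exceptions import (
    DegenerateReferenceError,
    DisconnectedGraphError,
    InvalidArgumentError,
)


@dataclass(frozen=True)
class SparseGraph:
    """Symmetric nonnegative weighted graph with zero diagonal."""

    weights: np.ndarray
    density: float
    target_missed: bool = False  # True when connectivity forbade the exact edge count

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            w = float(self.weights[i, j])
            g.add_edge(i, j, weight=w, length=1.0 / w)
        return g


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-brain metrics at one threshold (n = normalised to random references)."""

    threshold: float
    PL: float
    CC: float
    GE: float
    LE: float
    PLn: float = np.nan
    CCn: float = np.nan
    SWI: float = np.nan


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def edge_target(n_nodes: int, density: float) -> int:
    """Retained-edge count for a proportional threshold."""
    return _round_half_away(density * n_nodes * (n_nodes - 1) / 2.0)


def threshold_graph(
    conn: ConnectivityMatrix | np.ndarray, density: float
) -> SparseGraph:
    """Discard the weakest positive edges, keeping the graph connected.

    Equivalent to removing edges in ascending weight order while skipping any
    edge whose removal would disconnect the graph, until the retained count
    reaches ``round(density * N(N-1)/2)``: by the spanning-tree cycle/cut
    properties this keeps exactly the maximum spanning tree plus the
    strongest remaining edges. Negative and zero weights are never retained.
    """
    if not 0 < density <= 1:
        raise InvalidArgumentError("density must lie in (0, 1]")
    w = conn.weights if isinstance(conn, ConnectivityMatrix) else np.asarray(conn)
    n = w.shape[0]
    pos = np.where(np.triu(w, 1) > 0, np.triu(w, 1), 0.0)

    n_comp, _ = connected_components(csr_matrix(pos + pos.T), directed=False)
    if n_comp > 1:
        raise DisconnectedGraphError(
            "positive weights do not span a connected graph"
        )

    target = edge_target(n, density)
    mst = minimum_spanning_tree(csr_matrix(-pos - pos.T))
    keep = np.zeros((n, n), dtype=bool)
    mi, mj = mst.nonzero()
    keep[mi, mj] = True
    keep = keep | keep.T
    keep = np.triu(keep, 1)

    n_kept = int(keep.sum())
    missed = False
    if n_kept >= target:
        missed = n_kept > target  # density below spanning-tree density
    else:
        ii, jj = np.nonzero(pos * ~keep)
        order = np.lexsort((jj, ii, -pos[ii, jj]))
        n_fill = min(target - n_kept, len(order))
        keep[ii[order[:n_fill]], jj[order[:n_fill]]] = True
        missed = n_kept + n_fill < target  # not enough positive edges
    out = np.where(keep, pos, 0.0)
    out = out + out.T
    return SparseGraph(out, density, target_missed=missed)


def _pair_distances(g: SparseGraph) -> np.ndarray:
    nxg = g.to_networkx()
    n = g.n_nodes
    dist = np.full((n, n), np.inf)
    for src, lengths in nx.all_pairs_dijkstra_path_length(nxg, weight="length"):
        for dst, d in lengths.items():
            dist[src, dst] = d
    np.fill_diagonal(dist, 0.0)
    return dist


def path_length(g: SparseGraph) -> float:
    """Mean shortest-path length over all unordered node pairs."""
    dist = _pair_distances(g)
    iu = np.triu_indices(g.n_nodes, 1)
    vals = dist[iu]
    if np.any(np.isinf(vals)):
        raise DisconnectedGraphError("path length undefined on a disconnected graph")
    return float(vals.mean())


def global_efficiency(g: SparseGraph, nodal: bool = False):
    """Mean inverse shortest-path length (disconnected pairs contribute 0)."""
    dist = _pair_distances(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    nodal_ge = inv.sum(axis=1) / max(g.n_nodes - 1, 1)
    return nodal_ge if nodal else float(nodal_ge.mean())


def local_efficiency(g: SparseGraph, nodal: bool = False):
    """Latora-Marchiori local efficiency: efficiency of each neighbourhood subgraph."""
    w = g.weights
    n = g.n_nodes
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if len(nb) < 2:
            continue
        sub = SparseGraph(w[np.ix_(nb, nb)], density=1.0)
        out[i] = global_efficiency(sub)
    return out if nodal else float(out.mean())


def clustering_coefficient(g: SparseGraph, nodal: bool = False):
    """Onnela geometric-mean weighted clustering, averaged over nodes."""
    cc = nx.clustering(g.to_networkx(), weight="weight")
    vals = np.array([cc[i] for i in range(g.n_nodes)])
    return vals if nodal else float(vals.mean())


def betweenness(g: SparseGraph) -> np.ndarray:
    """Unnormalised shortest-path betweenness on lengths 1/weight."""
    bc = nx.betweenness_centrality(
        g.to_networkx(), weight="length", normalized=False
    )
    return np.array([bc[i] for i in range(g.n_nodes)])


def random_reference(
    g: SparseGraph, seed: int, n_swaps_per_edge: int = 10
) -> SparseGraph:
    """Degree-preserving double-edge swaps carrying weights with the edges.

    Swaps creating self-loops, parallel edges or disconnection are rejected,
    so the degree sequence and the weight multiset are preserved exactly and
    the result stays connected.
    """
    rng = np.random.default_rng(seed)
    nxg = g.to_networkx()
    edges = [(u, v, d["weight"]) for u, v, d in nxg.edges(data=True)]
    m = len(edges)
    if m < 2:
        return SparseGraph(g.weights.copy(), g.density, g.target_missed)
    target = n_swaps_per_edge * m
    attempts = 0
    swaps = 0
    while swaps < target and attempts < 50 * target:
        attempts += 1
        i1, i2 = rng.choice(m, size=2, replace=False)
        a, b, w1 = edges[i1]
        c, d, w2 = edges[i2]
        if rng.integers(2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if nxg.has_edge(a, d) or nxg.has_edge(c, b):
            continue
        nxg.remove_edge(a, b)
        nxg.remove_edge(c, d)
        nxg.add_edge(a, d, weight=w1, length=1.0 / w1)
        nxg.add_edge(c, b, weight=w2, length=1.0 / w2)
        if not nx.is_connected(nxg):
            nxg.remove_edge(a, d)
            nxg.remove_edge(c, b)
            nxg.add_edge(a, b, weight=w1, length=1.0 / w1)
            nxg.add_edge(c, d, weight=w2, length=1.0 / w2)
            continue
        edges[i1] = (a, d, w1)
        edges[i2] = (c, b, w2)
        swaps += 1
    out = np.zeros_like(g.weights)
    for u, v, w in edges:
        out[u, v] = out[v, u] = w
    return SparseGraph(out, g.density, g.target_missed)


def small_world_index(
    g: SparseGraph, references: list[SparseGraph]
) -> tuple[float, float, float]:
    """(SWI, CCn, PLn) against a reference ensemble: SWI = CCn / PLn."""
    if not references:
        raise InvalidArgumentError("need at least one reference graph")
    cc = clustering_coefficient(g)
    pl = path_length(g)
    cc_rand = float(np.mean([clustering_coefficient(r) for r in references]))
    pl_rand = float(np.mean([path_length(r) for r in references]))
    if cc_rand == 0:
        raise DegenerateReferenceError("reference ensemble has zero clustering")
    ccn = cc / cc_rand
    pln = pl / pl_rand
    return ccn / pln, ccn, pln


DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.10, 0.3501, 0.01), 2))


def global_metrics_at(
    conn: ConnectivityMatrix,
    density: float,
    n_refs: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> GlobalMetrics:
    """Threshold at one density and compute raw plus reference-normalised metrics."""
    g = threshold_graph(conn, density)
    refs = [
        random_reference(g, seed=seed + 7 * k + 1, n_swaps_per_edge=n_swaps_per_edge)
        for k in range(n_refs)
    ]
    pl = path_length(g)
    cc = clustering_coefficient(g)
    ge = global_efficiency(g)
    le = local_efficiency(g)
    if refs:
        swi, ccn, pln = small_world_index(g, refs)
    else:
        swi = ccn = pln = np.nan
    return GlobalMetrics(density, pl, cc, ge, le, pln, ccn, swi)


def metric_threshold_curve(
    conn: ConnectivityMatrix,
    thresholds: tuple[float, ...] | None = None,
    n_refs: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> list[GlobalMetrics]:
    """Global metrics across a proportional-threshold grid (default 10-35%, 1% steps)."""
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else tuple(thresholds)
    return [
        global_metrics_at(
            conn, t, n_refs=n_refs, n_swaps_per_edge=n_swaps_per_edge,
            seed=seed + 1000 * k,
        )
        for k, t in enumerate(thresholds)
    ]


def curve_auc(thresholds: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area of a metric-vs-threshold curve (sorted internally)."""
    thresholds = np.asarray(thresholds, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(thresholds) < 2:
        raise InvalidArgumentError("need at least 2 curve points")
    order = np.argsort(thresholds)
    return float(np.trapezoid(values[order], thresholds[order]))


NODE_METRICS = ("degree", "strength", "BC", "CC", "LE", "GE", "LEGE")


def node_metric_table(g: SparseGraph, region_names=None) -> pd.DataFrame:
    """Per-node degree, strength, betweenness, clustering and efficiency metrics.

    LEGE is nodal local efficiency divided by nodal global efficiency, a
    node-wise ratio of neighbourhood to whole-network integration.
    """
    w = g.weights
    degree = (w > 0).sum(axis=1)
    strength = w.sum(axis=1)
    bc = betweenness(g)
    cc = clustering_coefficient(g, nodal=True)
    le = local_efficiency(g, nodal=True)
    ge = global_efficiency(g, nodal=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        lege = np.where(ge > 0, le / ge, 0.0)
    tab = pd.DataFrame(
        {
            "degree": degree,
            "strength": strength,
            "BC": bc,
            "CC": cc,
            "LE": le,
            "GE": ge,
            "LEGE": lege,
        }
    )
    if region_names is not None:
        tab.index = pd.Index(region_names, name="region")
    return tab


def write_edge_list(g: SparseGraph, path, region_names=None) -> None:
    """Weighted edge list as TSV (node_i, node_j, weight)."""
    ii, jj = np.nonzero(np.triu(g.weights, 1))
    names = region_names if region_names is not None else list(range(g.n_nodes))
    pd.DataFrame(
        {
            "node_i": [names[i] for i in ii],
            "node_j": [names[j] for j in jj],
            "weight": g.weights[ii, jj],
        }
    ).to_csv(path, sep="\t", index=False)


def write_graphml(g: SparseGraph, path) -> None:
    nx.write_graphml(g.to_networkx(), path)
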