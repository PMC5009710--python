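"""Twelve hub-centrality indices and hub selection.

The indices follow the cytoHubba conventions for undirected, unweighted,
simple graphs: MCC (maximal clique centrality), DMNC (density of maximum
neighborhood component), MNC (maximum neighborhood component), degree, EPC
(edge percolated component), BottleNeck, eccentricity, closeness,
radiality, betweenness, stress and clustering coefficient.

Two normalizations are chosen so that larger always means more central and
disconnected networks stay well defined: closeness is *harmonic* closeness
(sum of reciprocal distances) and the eccentricity column is the
*reciprocal* of the graph-theoretic eccentricity within a node's component.

Ranks use dense ranking (ties share a rank: 1, 2, 2, 3), which keeps hub
sets reproducible.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

INDEX_COLUMNS = (
    "degree",
    "mcc",
    "dmnc",
    "mnc",
    "epc",
    "bottleneck",
    "eccentricity_score",
    "closeness",
    "radiality",
    "betweenness",
    "stress",
    "clustering_coefficient",
)


@dataclass(frozen=True)
class CentralityParams:
    """Tunable parameters of the stochastic / parameterized indices.

    dmnc_epsilon : exponent of the DMNC node-count denominator (default 1.7).
    epc_realizations : Monte-Carlo sample count for EPC (default 1000).
    epc_keep_probability : per-edge retention probability (default 0.5).
    epc_seed : RNG seed for EPC (default 0).
    bottleneck_fraction : subtree-size threshold as a fraction of the
        shortest-path tree (default 0.25).
    mcc_max_nodes : guard aborting maximal-clique enumeration on graphs
        larger than this (default 5000).
    """

    dmnc_epsilon: float = 1.7
    epc_realizations: int = 1000
    epc_keep_probability: float = 0.5
    epc_seed: int = 0
    bottleneck_fraction: float = 0.25
    mcc_max_nodes: int = 5000

    def __post_init__(self) -> None:
        if self.dmnc_epsilon <= 0 or self.bottleneck_fraction <= 0:
            raise ValueError("dmnc_epsilon and bottleneck_fraction must be positive")
        if not (0 < self.epc_keep_probability <= 1):
            raise ValueError("epc_keep_probability must be in (0, 1]")


def _as_graph(network) -> nx.Graph:
    inner = getattr(network, "graph", None)
    return inner if isinstance(inner, nx.Graph) else network


# ---------------------------------------------------------------------------
# local indices
# ---------------------------------------------------------------------------

def compute_local_indices(network) -> dict[str, dict]:
    """Degree and clustering coefficient per node."""
    graph = _as_graph(network)
    degree = {v: graph.degree(v) for v in graph}
    clustering: dict = {}
    for v in graph:
        neigh = list(graph.neighbors(v))
        k = len(neigh)
        if k < 2:
            clustering[v] = 0.0
            continue
        links = 0
        neigh_set = set(neigh)
        for i, u in enumerate(neigh):
            links += sum(1 for w in neigh[i + 1 :] if w in graph[u] and w in neigh_set)
        clustering[v] = 2.0 * links / (k * (k - 1))
    return {"degree": degree, "clustering_coefficient": clustering}


# ---------------------------------------------------------------------------
# shortest-path indices (single BFS sweep per source, Brandes accumulation)
# ---------------------------------------------------------------------------

def compute_path_indices(network) -> dict[str, dict]:
    """Betweenness, stress, harmonic closeness, reciprocal eccentricity and
    radiality, all from unweighted shortest paths.

    Betweenness and stress count each unordered source/target pair once.
    Radiality of v is (1/(n_c-1)) * sum over u in v's component of
    (diameter_c + 1 - d(v, u)); isolated nodes score 0 on all of these.
    """
    graph = _as_graph(network)
    nodes = list(graph)
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    closeness = {v: 0.0 for v in nodes}
    eccentricity: dict = {}
    dist_sum = {v: 0.0 for v in nodes}

    components = [sorted(c) for c in nx.connected_components(graph)]
    comp_of = {}
    for ci, comp in enumerate(components):
        for v in comp:
            comp_of[v] = ci
    diameters = [0] * len(components)

    for s in nodes:
        # Brandes: BFS with path counts, then dependency accumulation.
        sigma = {s: 1.0}
        dist = {s: 0}
        parents: dict = {s: []}
        order = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in graph.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0.0
                    parents[w] = []
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    parents[w].append(v)
        delta = {v: 0.0 for v in order}
        delta_stress = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in parents[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
                delta_stress[v] += (sigma[v] / sigma[w]) * (sigma[w] + delta_stress[w])
            if w != s:
                betweenness[w] += delta[w]
                stress[w] += delta_stress[w]
                d = dist[w]
                closeness[s] += 1.0 / d
                dist_sum[s] += d
        ecc = max(dist.values()) if len(dist) > 1 else 0
        eccentricity[s] = ecc
        ci = comp_of[s]
        diameters[ci] = max(diameters[ci], ecc)

    # each unordered pair was accumulated from both endpoints
    betweenness = {v: b / 2.0 for v, b in betweenness.items()}
    stress = {v: s_ / 2.0 for v, s_ in stress.items()}

    ecc_score = {v: (1.0 / eccentricity[v] if eccentricity[v] > 0 else 0.0) for v in nodes}
    radiality: dict = {}
    for v in nodes:
        comp = components[comp_of[v]]
        n_c = len(comp)
        if n_c < 2:
            radiality[v] = 0.0
            continue
        diameter = diameters[comp_of[v]]
        radiality[v] = ((diameter + 1) * (n_c - 1) - dist_sum[v]) / (n_c - 1)
    return {
        "betweenness": betweenness,
        "stress": stress,
        "closeness": closeness,
        "eccentricity_score": ecc_score,
        "radiality": radiality,
    }


# ---------------------------------------------------------------------------
# neighborhood indices
# ---------------------------------------------------------------------------

def compute_neighborhood_indices(network, params: CentralityParams | None = None) -> dict[str, dict]:
    """MNC, DMNC and MCC.

    MNC(v): node count of the largest connected component of the subgraph
    induced by N(v).  DMNC(v): edge count of that component divided by its
    node count raised to epsilon.  MCC(v): sum of (|C|-1)! over the maximal
    cliques C of size >= 2 that contain v.  Isolated nodes score 0 on all
    three.
    """
    params = params or CentralityParams()
    graph = _as_graph(network)
    if graph.number_of_nodes() > params.mcc_max_nodes:
        raise ValueError(
            f"maximal-clique enumeration guard: {graph.number_of_nodes()} nodes "
            f"exceeds mcc_max_nodes={params.mcc_max_nodes}"
        )
    mnc: dict = {}
    dmnc: dict = {}
    for v in graph:
        neigh = list(graph.neighbors(v))
        if not neigh:
            mnc[v] = 0.0
            dmnc[v] = 0.0
            continue
        sub = graph.subgraph(neigh)
        best = max(
            (sub.subgraph(c) for c in nx.connected_components(sub)),
            key=lambda g: (g.number_of_nodes(), g.number_of_edges(), sorted(g.nodes())),
        )
        mnc[v] = float(best.number_of_nodes())
        dmnc[v] = best.number_of_edges() / best.number_of_nodes() ** params.dmnc_epsilon

    mcc = {v: 0.0 for v in graph}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        weight = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += weight
    return {"mnc": mnc, "dmnc": dmnc, "mcc": mcc}


# ---------------------------------------------------------------------------
# bottleneck
# ---------------------------------------------------------------------------

def compute_bottleneck(network, params: CentralityParams | None = None) -> dict[str, dict]:
    """BottleNeck scores from deterministic BFS shortest-path trees.

    For each source the BFS tree picks the smallest-id candidate parent.  A
    node v != s is a bottleneck for source s when its subtree (including
    itself) holds more than ``bottleneck_fraction`` of the tree's nodes;
    BottleNeck(v) counts the sources for which v is a bottleneck.
    """
    params = params or CentralityParams()
    graph = _as_graph(network)
    score = {v: 0.0 for v in graph}
    for s in graph:
        dist = {s: 0}
        parent: dict = {}
        order = [s]
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in sorted(graph.neighbors(v)):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                    order.append(w)
        for w in order:
            if w == s:
                continue
            parent[w] = min(u for u in graph.neighbors(w) if dist.get(u) == dist[w] - 1)
        subtree = {v: 1 for v in order}
        for w in reversed(order):
            if w != s:
                subtree[parent[w]] += subtree[w]
        threshold = params.bottleneck_fraction * len(order)
        for v in order:
            if v != s and subtree[v] > threshold:
                score[v] += 1.0
    return {"bottleneck": score}


# ---------------------------------------------------------------------------
# edge percolated component
# ---------------------------------------------------------------------------

def compute_epc(network, params: CentralityParams | None = None) -> dict[str, dict]:
    """Monte-Carlo edge-percolation centrality.

    Each realization deletes every edge independently with probability
    1 - keep_probability; epc(v) is the mean over realizations of the size
    of v's surviving component divided by the total node count.
    Reproducible for a fixed ``epc_seed``.
    """
    params = params or CentralityParams()
    if params.epc_realizations < 1:
        raise ValueError("epc_realizations must be >= 1")
    graph = _as_graph(network)
    nodes = list(graph)
    n = len(nodes)
    if n == 0:
        return {"epc": {}}
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges()]
    rng = np.random.default_rng(params.epc_seed)
    totals = np.zeros(n)

    parent = np.empty(n, dtype=np.int64)
    size = np.empty(n, dtype=np.int64)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    m = len(edges)
    for _ in range(params.epc_realizations):
        parent[:] = np.arange(n)
        size[:] = 1
        if m:
            keep = rng.random(m) < params.epc_keep_probability
            for (a, b), kept in zip(edges, keep):
                if not kept:
                    continue
                ra, rb = find(a), find(b)
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
        for i in range(n):
            totals[i] += size[find(i)]
    epc = {v: totals[index[v]] / (params.epc_realizations * n) for v in nodes}
    return {"epc": epc}


# ---------------------------------------------------------------------------
# assembly, ranking, hub selection
# ---------------------------------------------------------------------------

def compute_centrality_table(network, params: CentralityParams | None = None) -> pd.DataFrame:
    """All 12 indices plus dense ranks, one row per node.

    Columns: the 12 score columns of :data:`INDEX_COLUMNS` plus a
    ``rank_<index>`` column for each (rank 1 = most central; ties share a
    rank).
    """
    params = params or CentralityParams()
    graph = _as_graph(network)
    scores: dict[str, dict] = {}
    scores.update(compute_local_indices(graph))
    scores.update(compute_path_indices(graph))
    scores.update(compute_neighborhood_indices(graph, params))
    scores.update(compute_bottleneck(graph, params))
    scores.update(compute_epc(graph, params))

    nodes = sorted(graph.nodes)
    table = pd.DataFrame(
        {col: [float(scores[col].get(v, 0.0)) for v in nodes] for col in INDEX_COLUMNS},
        index=pd.Index(nodes, name="node"),
    )
    for col in INDEX_COLUMNS:
        table[f"rank_{col}"] = dense_rank(table[col])
    return table


def dense_rank(values: pd.Series) -> pd.Series:
    """Dense descending rank: equal scores share a rank (1, 2, 2, 3)."""
    return values.rank(method="dense", ascending=False).astype(int)


def rank_and_select_hubs(table: pd.DataFrame, k: int, m: int) -> list[str]:
    """Nodes placed in the positional top *k* for at least *m* indices.

    Per index, nodes are ordered by (score descending, node id ascending)
    and the first *k* are in that index's top set.  Output is sorted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (1 <= m <= len(INDEX_COLUMNS)):
        raise ValueError(f"m must be in 1..{len(INDEX_COLUMNS)}")
    counts: dict[str, int] = {str(v): 0 for v in table.index}
    for col in INDEX_COLUMNS:
        ordered = sorted(table.index, key=lambda v: (-table.at[v, col], str(v)))
        for v in ordered[:k]:
            counts[str(v)] += 1
    return sorted(v for v, c in counts.items() if c >= m)
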