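"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (exhaustive enumeration, bitmask DP)
and shares no code with the package's algorithms.
"""

from itertools import combinations, permutations

import networkx as nx


def all_shortest_paths_stats(graph):
    """Exhaustive per-node betweenness/stress/closeness/ecc/radiality.

    Enumerates every simple path between every pair, keeps the shortest
    ones, and accumulates the five path statistics directly from their
    definitions (unordered pairs).
    """
    nodes = sorted(graph.nodes)
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    closeness = {v: 0.0 for v in nodes}
    dist = {}

    for s, t in combinations(nodes, 2):
        paths = list(nx.all_simple_paths(graph, s, t))
        if not paths:
            continue
        d = min(len(p) - 1 for p in paths)
        shortest = [p for p in paths if len(p) - 1 == d]
        dist[(s, t)] = d
        closeness[s] += 1.0 / d
        closeness[t] += 1.0 / d
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            if through:
                bet[v] += through / sigma
                stress[v] += through

    comps = [sorted(c) for c in nx.connected_components(graph)]
    ecc = {}
    radiality = {}
    for comp in comps:
        if len(comp) < 2:
            for v in comp:
                ecc[v] = 0.0
                radiality[v] = 0.0
            continue
        dists = {
            v: {u: dist[tuple(sorted((u, v)))] for u in comp if u != v} for v in comp
        }
        diameter = max(max(d.values()) for d in dists.values())
        for v in comp:
            emax = max(dists[v].values())
            ecc[v] = 1.0 / emax
            radiality[v] = sum(diameter + 1 - d for d in dists[v].values()) / (len(comp) - 1)
    return {
        "betweenness": bet,
        "stress": stress,
        "closeness": closeness,
        "eccentricity_score": ecc,
        "radiality": radiality,
    }


def maximal_cliques_bruteforce(graph):
    """All maximal cliques by subset enumeration (graphs up to ~12 nodes)."""
    nodes = sorted(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if all(graph.has_edge(a, b) for a, b in combinations(sub, 2)):
                cliques.append(set(sub))
    return [c for c in cliques if not any(c < other for other in cliques)]


def mcc_bruteforce(graph):
    from math import factorial

    cliques = [c for c in maximal_cliques_bruteforce(graph) if len(c) >= 2]
    return {
        v: float(sum(factorial(len(c) - 1) for c in cliques if v in c))
        for v in graph.nodes
    }


def neighborhood_component_bruteforce(graph, epsilon=1.7):
    mnc = {}
    dmnc = {}
    for v in graph.nodes:
        neigh = list(graph.neighbors(v))
        if not neigh:
            mnc[v] = 0.0
            dmnc[v] = 0.0
            continue
        sub = graph.subgraph(neigh)
        comps = list(nx.connected_components(sub))
        size = max(len(c) for c in comps)
        # among largest components prefer the one with most edges
        edges = max(
            sub.subgraph(c).number_of_edges() for c in comps if len(c) == size
        )
        mnc[v] = float(size)
        dmnc[v] = edges / size**epsilon
    return mnc, dmnc


def simple_cycles_bruteforce(graph, max_len=None):
    """All simple cycles (length >= 3) by permutation enumeration."""
    nodes = sorted(graph.nodes)
    limit = max_len or len(nodes)
    found = set()
    for k in range(3, limit + 1):
        for sub in combinations(nodes, k):
            for perm in permutations(sub[1:]):
                cycle = (sub[0],) + perm
                ok = all(
                    graph.has_edge(cycle[i], cycle[(i + 1) % k]) for i in range(k)
                )
                if ok:
                    rotated = cycle
                    backward = (rotated[0],) + tuple(reversed(rotated[1:]))
                    found.add(min(rotated, backward))
    return sorted(found)


def longest_path_length_dp(graph):
    """Maximum simple-path node count via bitmask dynamic programming."""
    nodes = sorted(graph.nodes)
    if not nodes:
        return 0
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in graph.edges():
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    best = 1
    # states[mask] = set of possible end nodes for simple paths over mask
    states = {}
    for i in range(len(nodes)):
        states[(1 << i, i)] = True
    frontier = list(states)
    while frontier:
        nxt = []
        for mask, end in frontier:
            neighbors = adj[end] & ~mask
            while neighbors:
                bit = neighbors & (-neighbors)
                neighbors ^= bit
                j = bit.bit_length() - 1
                key = (mask | bit, j)
                if key not in states:
                    states[key] = True
                    nxt.append(key)
                    best = max(best, bin(mask | bit).count("1"))
        frontier = nxt
    return best


def gecn_edges_bruteforce(db, currency):
    """Pairwise compound-set intersection over enzyme reaction compounds."""
    compounds = {}
    for ec in db.enzymes:
        touched = set()
        for rxn in db.reactions.values():
            if ec in rxn.ec_numbers:
                touched |= (rxn.substrate_ids | rxn.product_ids) - currency
        compounds[ec] = touched
    edges = {}
    ecs = sorted(db.enzymes)
    for i, e1 in enumerate(ecs):
        for e2 in ecs[i + 1 :]:
            shared = compounds[e1] & compounds[e2]
            if shared:
                edges[(e1, e2)] = shared
    return edges


def random_graph(rng, n_max=8, p=None):
    """Random G(n, p) graph with string node labels."""
    n = int(rng.integers(2, n_max + 1))
    p = p if p is not None else float(rng.uniform(0.15, 0.7))
    graph = nx.Graph()
    labels = [f"n{i:02d}" for i in range(n)]
    graph.add_nodes_from(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                graph.add_edge(labels[i], labels[j])
    return graph
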