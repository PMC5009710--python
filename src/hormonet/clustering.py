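"""Overlapping community detection by greedy cohesiveness growth.

A candidate cluster V scores cohesiveness

    f(V) = w_in / (w_in + w_bound + p * |V|)

where w_in counts edges with both ends inside V, w_bound counts edges with
exactly one end inside, and p is a penalty standing in for unobserved
boundary edges (unit edge weights throughout).  Clusters are grown greedily
from seeds by best-improvement single-node moves, overlapping clusters are
merged to a fixed point, and small or sparse clusters are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class ClusterParams:
    penalty: float = 2.0
    merge_overlap: float = 0.8
    min_size: int = 3
    min_density: float = 0.5

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        if not (0 < self.merge_overlap <= 1):
            raise ValueError("merge_overlap must be in (0, 1]")


@dataclass(frozen=True)
class Cluster:
    members: frozenset[str]
    cohesiveness: float
    density: float

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def _as_graph(network) -> nx.Graph:
    inner = getattr(network, "graph", None)
    return inner if isinstance(inner, nx.Graph) else network


def _edge_counts(graph: nx.Graph, members: set) -> tuple[int, int]:
    w_in = 0
    w_bound = 0
    for v in members:
        for u in graph.neighbors(v):
            if u in members:
                w_in += 1  # counted from both ends
            else:
                w_bound += 1
    return w_in // 2, w_bound


def cohesiveness(network, node_set, p: float) -> float:
    """Cohesiveness w_in / (w_in + w_bound + p * |V|) of *node_set*."""
    graph = _as_graph(network)
    members = set(node_set)
    if not members:
        raise ValueError("cohesiveness of an empty set is undefined")
    missing = members - set(graph)
    if missing:
        raise KeyError(f"nodes not in network: {sorted(missing)}")
    w_in, w_bound = _edge_counts(graph, members)
    denom = w_in + w_bound + p * len(members)
    return w_in / denom if denom > 0 else 0.0


def density(network, node_set) -> float:
    """Internal edge density w_in / (|V| choose 2); 1.0 for singletons."""
    graph = _as_graph(network)
    members = set(node_set)
    n = len(members)
    if n < 2:
        return 1.0
    w_in, _ = _edge_counts(graph, members)
    return 2.0 * w_in / (n * (n - 1))


def grow_cluster(network, seed_node, params: ClusterParams | None = None) -> Cluster:
    """Grow a cluster from *seed_node* by greedy best improvement.

    At each step every boundary addition and every removal (never the seed)
    is evaluated; the move with the highest resulting cohesiveness is
    applied if it strictly improves the current value.  Ties are broken by
    preferring additions, then the smaller node id, which makes the result
    deterministic.
    """
    params = params or ClusterParams()
    graph = _as_graph(network)
    if seed_node not in graph:
        raise KeyError(f"seed {seed_node!r} not in network")
    members = {seed_node}
    current = cohesiveness(graph, members, params.penalty)
    while True:
        candidates: list[tuple[float, int, str]] = []
        boundary = {u for v in members for u in graph.neighbors(v)} - members
        for u in sorted(boundary):
            value = cohesiveness(graph, members | {u}, params.penalty)
            candidates.append((value, 0, u))
        for u in sorted(members - {seed_node}):
            value = cohesiveness(graph, members - {u}, params.penalty)
            candidates.append((value, 1, u))
        if not candidates:
            break
        best = min(candidates, key=lambda t: (-t[0], t[1], t[2]))
        if best[0] <= current:
            break
        current = best[0]
        if best[1] == 0:
            members.add(best[2])
        else:
            members.remove(best[2])
    return Cluster(
        members=frozenset(members),
        cohesiveness=current,
        density=density(graph, members),
    )


def overlap_score(a: frozenset, b: frozenset) -> float:
    """Match coefficient omega(A, B) = |A n B|^2 / (|A| * |B|)."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def detect_clusters(network, params: ClusterParams | None = None) -> list[Cluster]:
    """Grow, merge and filter clusters over the whole network.

    Seeds are processed in degree-descending order (ties by id), skipping
    nodes already covered by an accepted cluster.  Grown clusters are merged
    while any pair overlaps with omega >= merge_overlap (merge = union,
    cohesiveness recomputed), iterated to a fixed point; clusters smaller
    than min_size or sparser than min_density are then discarded.  Output is
    sorted by cohesiveness descending (ties by member list).
    """
    params = params or ClusterParams()
    graph = _as_graph(network)
    seeds = sorted(graph.nodes, key=lambda v: (-graph.degree(v), str(v)))
    covered: set = set()
    grown: list[Cluster] = []
    for seed in seeds:
        if seed in covered:
            continue
        cluster = grow_cluster(graph, seed, params)
        grown.append(cluster)
        covered |= cluster.members

    member_sets = [c.members for c in grown]
    changed = True
    while changed:
        changed = False
        for i in range(len(member_sets)):
            if member_sets[i] is None:
                continue
            for j in range(i + 1, len(member_sets)):
                if member_sets[j] is None:
                    continue
                if overlap_score(member_sets[i], member_sets[j]) >= params.merge_overlap:
                    member_sets[i] = member_sets[i] | member_sets[j]
                    member_sets[j] = None
                    changed = True
    result = []
    for members in member_sets:
        if members is None or len(members) < params.min_size:
            continue
        dens = density(graph, members)
        if dens < params.min_density:
            continue
        result.append(
            Cluster(
                members=members,
                cohesiveness=cohesiveness(graph, members, params.penalty),
                density=dens,
            )
        )
    return sorted(result, key=lambda c: (-c.cohesiveness, sorted(c.members)))
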