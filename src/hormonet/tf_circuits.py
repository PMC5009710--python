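"""TF co-target networks, circular control units, and PPI routes.

Two transcription factors are joined in the co-target network when they
regulate at least one common target gene; the shared targets are the edge
provenance.  Simple cycles of length >= 3 in this network are the circular
control structures; cycles are grouped into *control units* by the
transitive closure of edge sharing, the closest testable formalization of
hand-curated unit drawings.  Within a unit, the longest simple path in the
protein–protein interaction graph induced on the unit's members is the
unit's consecutive PPI route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .pathway_io import PPIRecord, RegulationRecord

log = logging.getLogger(__name__)

ALL = "ALL"


@dataclass
class TFNetwork:
    """Undirected TF graph; edge provenance is the shared-target set."""

    graph: nx.Graph


@dataclass(frozen=True)
class ControlUnit:
    """A group of edge-sharing simple cycles of TFs.

    ``regulated_enzyme_genes`` are the shared-target genes on the unit's
    cycle edges that encode enzymes of the crosstalk network.
    """

    members: frozenset[str]
    cycles: tuple[tuple[str, ...], ...]
    regulated_enzyme_genes: frozenset[str]


def build_cotarget_network(
    regulation: list[RegulationRecord], target_filter=ALL
) -> TFNetwork:
    """Co-target network: edge between TFs sharing >= 1 (filtered) target."""
    allowed = None if target_filter is ALL else set(target_filter)
    targets_of: dict[str, set[str]] = {}
    for rec in regulation:
        if allowed is not None and rec.target_gene_id not in allowed:
            continue
        targets_of.setdefault(rec.tf_gene_id, set()).add(rec.target_gene_id)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(targets_of))
    tfs = sorted(targets_of)
    by_target: dict[str, list[str]] = {}
    for tf, targets in targets_of.items():
        for g in targets:
            by_target.setdefault(g, []).append(tf)
    shared: dict[tuple[str, str], set[str]] = {}
    for g, tf_list in by_target.items():
        tf_list = sorted(set(tf_list))
        for i, t1 in enumerate(tf_list):
            for t2 in tf_list[i + 1 :]:
                shared.setdefault((t1, t2), set()).add(g)
    for (t1, t2), genes in shared.items():
        graph.add_edge(t1, t2, provenance=frozenset(genes))
    return TFNetwork(graph)


def canonical_cycle(cycle) -> tuple[str, ...]:
    """Rotate so the smallest id comes first, oriented toward the smaller
    second element."""
    cycle = list(cycle)
    pivot = cycle.index(min(cycle))
    rotated = cycle[pivot:] + cycle[:pivot]
    backward = [rotated[0]] + list(reversed(rotated[1:]))
    return tuple(min(rotated, backward))


def enumerate_cycles(network: TFNetwork, max_len: int = 15) -> list[tuple[str, ...]]:
    """All simple cycles of length 3..max_len, canonical, sorted, unique."""
    if max_len < 3:
        raise ValueError("max_len must be >= 3")
    graph = network.graph
    seen: set[tuple[str, ...]] = set()
    truncated = False
    for cycle in nx.simple_cycles(graph, length_bound=max_len):
        if len(cycle) < 3:
            continue
        seen.add(canonical_cycle(cycle))
    # detect whether the cap may have truncated longer cycles
    if graph.number_of_nodes() > max_len:
        truncated = True
    if truncated:
        log.info("cycle enumeration capped at length %d", max_len)
    return sorted(seen)


def _cycle_edges(cycle: tuple[str, ...]) -> set[frozenset]:
    pairs = list(zip(cycle, cycle[1:])) + [(cycle[-1], cycle[0])]
    return {frozenset(p) for p in pairs}


def assemble_units(
    cycles: list[tuple[str, ...]],
    network: TFNetwork,
    enzyme_gene_set,
) -> list[ControlUnit]:
    """Group cycles into control units by transitive edge sharing.

    Unit members are the union of the grouped cycles' TFs;
    ``regulated_enzyme_genes`` intersects the provenance targets on the
    unit's edges with *enzyme_gene_set*.  Units are sorted by size
    descending (ties by member list).
    """
    enzyme_genes = set(enzyme_gene_set)
    edge_sets = [_cycle_edges(c) for c in cycles]
    parent = list(range(len(cycles)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    owner: dict[frozenset, int] = {}
    for i, edges in enumerate(edge_sets):
        for edge in edges:
            if edge in owner:
                ri, rj = find(i), find(owner[edge])
                if ri != rj:
                    parent[rj] = ri
            else:
                owner[edge] = i

    groups: dict[int, list[int]] = {}
    for i in range(len(cycles)):
        groups.setdefault(find(i), []).append(i)

    units = []
    for indices in groups.values():
        grouped = tuple(sorted(cycles[i] for i in indices))
        members = frozenset(tf for cycle in grouped for tf in cycle)
        regulated: set[str] = set()
        for i in indices:
            for edge in edge_sets[i]:
                u, v = tuple(edge)
                regulated |= network.graph.edges[u, v]["provenance"] & enzyme_genes
        units.append(
            ControlUnit(
                members=members,
                cycles=grouped,
                regulated_enzyme_genes=frozenset(regulated),
            )
        )
    return sorted(units, key=lambda u: (-len(u.members), sorted(u.members)))


def find_ppi_route(unit: ControlUnit, ppi: list[PPIRecord]) -> list[str]:
    """Longest simple path in the PPI graph induced on the unit's members.

    Exhaustive search (unit sizes are small); returns the lexicographically
    smallest canonical path among ties, or [] when the induced graph has no
    edge.
    """
    graph = nx.Graph()
    members = unit.members
    for rec in ppi:
        if rec.gene_a in members and rec.gene_b in members:
            graph.add_edge(rec.gene_a, rec.gene_b)
    if graph.number_of_edges() == 0:
        return []

    best: list[tuple[str, ...]] = []
    best_len = 0

    def dfs(path: list, visited: set) -> None:
        nonlocal best, best_len
        extended = False
        for w in graph.neighbors(path[-1]):
            if w in visited:
                continue
            extended = True
            path.append(w)
            visited.add(w)
            dfs(path, visited)
            visited.remove(w)
            path.pop()
        if not extended:
            tup = tuple(path) if path[0] <= path[-1] else tuple(reversed(path))
            if len(tup) > best_len:
                best_len = len(tup)
                best = [tup]
            elif len(tup) == best_len:
                best.append(tup)

    for start in sorted(graph):
        dfs([start], {start})
    return list(min(best))
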