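"""Producer/consumer coupling graphs and consecutive metabolic routes.

Two enzymes are *coupled* when a non-currency compound is a product of a
reaction of one and a substrate of a reaction of the other (reversible
reactions contribute both sides).  A consecutive metabolic route is a
maximum-cardinality simple path in the coupling graph; the linking
metabolite between consecutive steps is recorded per edge.

Coupling is kept undirected: published route chains mix biosynthetic
directions across pathways (one step may produce what the previous step
consumes), so direction is recorded in provenance but not used for path
finding.  Longest-simple-path search is NP-hard in general; the exact
exhaustive search is guarded by a node-count limit with a greedy beam
fallback, which is adequate because hub enzyme sets are small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .network_build import CurrencyPolicy, _enzyme_compound_sides
from .pathway_io import HormoneAnnotation, PathwayDB

log = logging.getLogger(__name__)


@dataclass
class CouplingGraph:
    """Undirected enzyme graph; edge provenance is the linking-compound set."""

    graph: nx.Graph

    def linking_compounds(self, e1: str, e2: str) -> frozenset[str]:
        return self.graph.edges[e1, e2]["provenance"]


@dataclass(frozen=True)
class MetabolicRoute:
    """An ordered enzyme chain with one linking metabolite per transition."""

    steps: tuple[str, ...]
    links: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.steps) != len(set(self.steps)):
            raise ValueError("route steps must be distinct")
        if len(self.links) != max(len(self.steps) - 1, 0):
            raise ValueError("need exactly len(steps)-1 links")

    def __len__(self) -> int:
        return len(self.steps)


def build_coupling_graph(
    db: PathwayDB,
    enzyme_set,
    policy: CurrencyPolicy | None = None,
) -> CouplingGraph:
    """Producer/consumer coupling graph over *enzyme_set*.

    Edge (e1, e2) exists iff some non-currency compound is produced by a
    reaction of one enzyme and consumed by a reaction of the other;
    provenance collects all such compounds.
    """
    policy = policy or CurrencyPolicy()
    enzymes = sorted(enzyme_set)
    unknown = [e for e in enzymes if e not in db.enzymes]
    if unknown:
        raise KeyError(f"enzymes not in database: {unknown}")
    _, produced, consumed = _enzyme_compound_sides(db, policy)
    graph = nx.Graph()
    graph.add_nodes_from(enzymes)
    for i, e1 in enumerate(enzymes):
        for e2 in enzymes[i + 1 :]:
            linkers = (produced[e1] & consumed[e2]) | (produced[e2] & consumed[e1])
            if linkers:
                graph.add_edge(e1, e2, provenance=frozenset(linkers))
    return CouplingGraph(graph)


def _all_longest_paths_exact(graph: nx.Graph) -> list[tuple[str, ...]]:
    """All maximum-cardinality simple paths, canonicalized and deduplicated."""
    best_len = 1
    best: set[tuple[str, ...]] = {(v,) for v in graph} if graph.number_of_nodes() else set()

    def canon(path: tuple[str, ...]) -> tuple[str, ...]:
        return path if path[0] <= path[-1] else tuple(reversed(path))

    def dfs(path: list, visited: set) -> None:
        nonlocal best_len, best
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
            if len(path) > best_len:
                best_len = len(path)
                best = {canon(tuple(path))}
            elif len(path) == best_len:
                best.add(canon(tuple(path)))

    for start in graph:
        dfs([start], {start})
    return sorted(best)


def _longest_paths_beam(graph: nx.Graph, beam_width: int = 200) -> list[tuple[str, ...]]:
    """Greedy beam search for long simple paths (used above the exact guard)."""
    frontier: list[tuple[str, ...]] = [(v,) for v in sorted(graph)]
    best: list[tuple[str, ...]] = list(frontier)
    best_len = 1 if frontier else 0
    while frontier:
        nxt: set[tuple[str, ...]] = set()
        for path in frontier:
            for w in graph.neighbors(path[-1]):
                if w not in path:
                    nxt.add(path + (w,))
        if not nxt:
            break
        ranked = sorted(nxt, key=lambda p: (-graph.degree(p[-1]), p))[:beam_width]
        frontier = ranked
        longest = max(len(p) for p in frontier)
        if longest > best_len:
            best_len = longest
            best = [p for p in frontier if len(p) == longest]
        elif longest == best_len:
            best.extend(p for p in frontier if len(p) == longest)
    canon = {p if p[0] <= p[-1] else tuple(reversed(p)) for p in best if len(p) == best_len}
    return sorted(canon)


def extract_routes(coupling: CouplingGraph, max_exact_nodes: int = 50) -> list[MetabolicRoute]:
    """All maximum-cardinality consecutive routes, canonical and sorted.

    Exhaustive when the graph has at most *max_exact_nodes* nodes, otherwise
    a greedy beam search with a logged warning.  Routes are canonicalized so
    the lexicographically smaller endpoint comes first; each link is the
    lexicographically smallest compound shared by the step pair.
    """
    graph = coupling.graph
    if graph.number_of_nodes() == 0:
        return []
    if graph.number_of_nodes() <= max_exact_nodes:
        paths = _all_longest_paths_exact(graph)
    else:
        log.warning(
            "coupling graph has %d nodes > max_exact_nodes=%d; using beam search",
            graph.number_of_nodes(),
            max_exact_nodes,
        )
        paths = _longest_paths_beam(graph)
    routes = []
    for path in paths:
        links = tuple(
            min(graph.edges[a, b]["provenance"]) for a, b in zip(path, path[1:])
        )
        routes.append(MetabolicRoute(steps=path, links=links))
    return sorted(routes, key=lambda r: r.steps)


def route_report(
    route: MetabolicRoute,
    db: PathwayDB,
    annotations: list[HormoneAnnotation],
) -> list[dict]:
    """One row per route step: index, EC, link to the next step, hormone tags.

    A step is tagged with every hormone whose annotated pathways contain at
    least one reaction of the step's enzyme.
    """
    pathways_of_hormone: dict[str, set[str]] = {}
    for ann in annotations:
        pathways_of_hormone.setdefault(ann.hormone, set()).add(ann.pathway_id)
    rows = []
    for i, ec in enumerate(route.steps):
        enzyme_pathways: set[str] = set()
        for rxn in db.reactions_of_enzyme(ec):
            enzyme_pathways |= rxn.pathway_ids
        tags = sorted(
            h for h, pids in pathways_of_hormone.items() if pids & enzyme_pathways
        )
        rows.append(
            {
                "step": i + 1,
                "ec": ec,
                "link_to_next": route.links[i] if i < len(route.links) else "",
                "crosstalk": tags,
            }
        )
    return rows
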