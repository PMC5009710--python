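"""Shared-substrate enzyme networks and the hormone-crosstalk subnetwork.

Two networks are built from a pathway database:

* the genome-scale enzyme correlation network (GECN): enzymes are nodes and
  an undirected edge joins two enzymes whose reactions involve at least one
  common non-currency compound, on either reaction side;
* the enzyme-based phytohormone crosstalk network (EAPCN): the GECN
  restricted to enzymes acting in hormone-annotated pathways, with one
  additional node per hormone and ``acts_in`` edges from each enzyme to the
  hormones whose annotated pathways it catalyses reactions in.

Currency metabolites (ATP, NAD(P)H, water, ...) are excluded from edge
formation so ubiquitous cofactors do not turn the network into a hairball;
the set is fully configurable.  S-adenosyl-L-methionine and UDP-D-glucose
are deliberately *not* currency by default: they act as route-relevant
substrates in hormone conjugation and methylation steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .pathway_io import HormoneAnnotation, IntegrityError, PathwayDB, is_valid_ec

log = logging.getLogger(__name__)

#: Default currency compound identifiers (matched against compound ids).
DEFAULT_CURRENCY_IDS = frozenset(
    {
        "WATER",
        "PROTON",
        "ATP",
        "ADP",
        "AMP",
        "Pi",
        "PPi",
        "NAD",
        "NADH",
        "NADP",
        "NADPH",
        "CO2",
        "O2",
        "CoA",
        "UDP",
    }
)


@dataclass(frozen=True)
class CurrencyPolicy:
    """Compound ids excluded from enzyme–enzyme edge formation."""

    currency_ids: frozenset[str] = DEFAULT_CURRENCY_IDS

    def restricted_to(self, db: PathwayDB) -> frozenset[str]:
        unknown = self.currency_ids - set(db.compounds)
        if unknown:
            log.warning("currency ids not in database (ignored): %s", sorted(unknown))
        return frozenset(self.currency_ids & set(db.compounds))


@dataclass
class CrosstalkNetwork:
    """Typed node/edge graph with edge provenance.

    Node kinds are ``enzyme``, ``hormone`` or ``tf``; every edge carries a
    ``relation`` label and a non-empty ``provenance`` frozenset (shared
    compound ids, pathway ids and roles, or shared target genes).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, node_id: str, kind: str) -> None:
        if kind not in ("enzyme", "hormone", "tf"):
            raise ValueError(f"unknown node kind {kind!r}")
        self.graph.add_node(node_id, kind=kind)

    def add_edge(self, u: str, v: str, relation: str, provenance) -> None:
        if u == v:
            raise ValueError(f"self-edge not allowed: {u}")
        prov = frozenset(provenance)
        if not prov:
            raise ValueError(f"edge {u}–{v} requires non-empty provenance")
        self.graph.add_edge(u, v, relation=relation, provenance=prov)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind)


@dataclass(frozen=True)
class NetworkSummary:
    nodes_by_kind: dict
    edge_count: int
    component_count: int
    connected_pairs: int


def ec_match(ec: str, pattern: str) -> bool:
    """True iff every non-wildcard field of *pattern* equals the same field of *ec*.

    ``ec_match("2.4.1.203", "2.4.1.-")`` is true; dashes in *ec* itself only
    match an identical dash or a wildcard in the pattern position.
    """
    if not is_valid_ec(ec):
        raise ValueError(f"malformed EC string {ec!r}")
    if not is_valid_ec(pattern):
        raise ValueError(f"malformed EC pattern {pattern!r}")
    for got, want in zip(ec.split("."), pattern.split(".")):
        if want != "-" and got != want:
            return False
    return True


def _enzyme_compound_sides(db: PathwayDB, policy: CurrencyPolicy):
    """Per enzyme: (all compounds, produced compounds, consumed compounds).

    Reversible reactions contribute both sides to both the produced and the
    consumed set.  Currency compounds are dropped.
    """
    currency = policy.restricted_to(db)
    touched: dict[str, set[str]] = {ec: set() for ec in db.enzymes}
    produced: dict[str, set[str]] = {ec: set() for ec in db.enzymes}
    consumed: dict[str, set[str]] = {ec: set() for ec in db.enzymes}
    for rxn in db.reactions.values():
        subs = rxn.substrate_ids - currency
        prods = rxn.product_ids - currency
        for ec in rxn.ec_numbers:
            if ec not in touched:
                continue
            touched[ec] |= subs | prods
            if rxn.reversible:
                produced[ec] |= subs | prods
                consumed[ec] |= subs | prods
            else:
                produced[ec] |= prods
                consumed[ec] |= subs
    return touched, produced, consumed


def build_gecn(db: PathwayDB, policy: CurrencyPolicy | None = None) -> CrosstalkNetwork:
    """Build the genome-scale enzyme correlation network.

    Every enzyme of the database is a node; two distinct enzymes are joined
    when some non-currency compound participates (substrate or product side)
    in at least one reaction of each.  Edge provenance is the full shared
    compound set.
    """
    policy = policy or CurrencyPolicy()
    touched, _, _ = _enzyme_compound_sides(db, policy)
    net = CrosstalkNetwork()
    for ec in db.enzymes:
        net.add_node(ec, kind="enzyme")
    # invert: compound -> enzymes touching it
    by_compound: dict[str, list[str]] = {}
    for ec, compounds in touched.items():
        for cid in compounds:
            by_compound.setdefault(cid, []).append(ec)
    shared: dict[tuple[str, str], set[str]] = {}
    for cid, enzymes in by_compound.items():
        enzymes = sorted(set(enzymes))
        for i, e1 in enumerate(enzymes):
            for e2 in enzymes[i + 1 :]:
                shared.setdefault((e1, e2), set()).add(cid)
    for (e1, e2), compounds in shared.items():
        net.add_edge(e1, e2, relation="shares_compound", provenance=compounds)
    return net


def build_eapcn(
    db: PathwayDB,
    annotations: list[HormoneAnnotation],
    policy: CurrencyPolicy | None = None,
) -> CrosstalkNetwork:
    """Build the hormone-crosstalk subnetwork.

    One hormone node per hormone occurring in *annotations*; an enzyme node
    for every enzyme catalysing a reaction in at least one annotated
    pathway; ``acts_in`` edges (provenance: pathway ids and roles) between
    enzymes and their hormones; enzyme–enzyme edges are the GECN edges
    restricted to the included enzymes.
    """
    policy = policy or CurrencyPolicy()
    missing = sorted({a.pathway_id for a in annotations} - set(db.pathways))
    if missing:
        raise IntegrityError(f"annotations reference unknown pathways: {missing}")

    net = CrosstalkNetwork()
    if not annotations:
        return net

    hormones = sorted({a.hormone for a in annotations})
    for hormone in hormones:
        net.add_node(hormone, kind="hormone")

    # enzyme -> hormone -> provenance strings
    acts_in: dict[str, dict[str, set[str]]] = {}
    for ann in annotations:
        for rxn in db.reactions_of_pathway(ann.pathway_id):
            for ec in rxn.ec_numbers:
                if ec not in db.enzymes:
                    continue
                prov = acts_in.setdefault(ec, {}).setdefault(ann.hormone, set())
                prov.add(ann.pathway_id)
                prov.add(f"role:{ann.role}")

    for ec in sorted(acts_in):
        net.add_node(ec, kind="enzyme")
    for ec, per_hormone in acts_in.items():
        for hormone, prov in per_hormone.items():
            net.add_edge(ec, hormone, relation="acts_in", provenance=prov)

    gecn = build_gecn(db, policy)
    included = set(acts_in)
    for u, v, data in gecn.graph.edges(data=True):
        if u in included and v in included:
            net.add_edge(u, v, relation="shares_compound", provenance=data["provenance"])
    return net


def shared_crosstalk_enzymes(
    network: CrosstalkNetwork, hormone_a: str, hormone_b: str
) -> list[str]:
    """Enzymes adjacent (``acts_in`` edges) to both hormone nodes, sorted."""
    graph = network.graph
    for hormone in (hormone_a, hormone_b):
        if hormone not in graph or graph.nodes[hormone].get("kind") != "hormone":
            raise KeyError(f"no hormone node {hormone!r} in network")

    def acts_in_neighbors(hormone: str) -> set[str]:
        return {
            n
            for n in graph.neighbors(hormone)
            if graph.edges[hormone, n].get("relation") == "acts_in"
        }

    return sorted(acts_in_neighbors(hormone_a) & acts_in_neighbors(hormone_b))


def network_summary(network: CrosstalkNetwork) -> NetworkSummary:
    """Node/edge counts, component count and number of connected node pairs.

    Connected pairs are summed per component: n_c * (n_c - 1) / 2.
    """
    graph = network.graph
    by_kind: dict[str, int] = {}
    for _, data in graph.nodes(data=True):
        kind = data.get("kind", "enzyme")
        by_kind[kind] = by_kind.get(kind, 0) + 1
    components = list(nx.connected_components(graph))
    pairs = sum(len(c) * (len(c) - 1) // 2 for c in components)
    return NetworkSummary(
        nodes_by_kind=by_kind,
        edge_count=graph.number_of_edges(),
        component_count=len(components),
        connected_pairs=pairs,
    )
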