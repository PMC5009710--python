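"""Readers and writers for pathway flat-files, annotation tables and networks.

The pathway database dialect is the BioCyc attribute–value flat-file format:
one ``ATTRIBUTE - VALUE`` pair per line, ``//`` terminates a record, lines
beginning with ``/`` continue the previous value and ``#`` starts a comment.
Four files describe a database: compounds, reactions, enzymes and pathways.

All identifiers are case-sensitive; surrounding whitespace is stripped.
EC numbers may contain ``-`` wildcards (e.g. ``6.3.-.-``); they are kept
verbatim here — wildcard matching is a separate, explicit operation
(:func:`hormonet.network_build.ec_match`), never applied silently at parse
time.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

HORMONES = (
    "abscisic acid",
    "auxin",
    "brassinosteroid",
    "cytokinin",
    "ethylene",
    "gibberellin",
    "jasmonic acid",
    "salicylic acid",
)

ANNOTATION_ROLES = ("biosynthesis", "inactivation", "degradation", "conjugation")

_EC_RE = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")
# Arabidopsis-style locus: two letters, chromosome digit, 'G', numeric tail.
_LOCUS_RE = re.compile(r"^[A-Za-z]{2}\d[Gg]\d+$")


class ParseError(ValueError):
    """A malformed line or record in an input stream."""


class IntegrityError(ValueError):
    """A reference that does not resolve within the database."""


class VocabularyError(ValueError):
    """A value outside a closed controlled vocabulary."""


def is_valid_ec(text: str) -> bool:
    """True if *text* is a four-field EC string (wildcards allowed)."""
    return bool(_EC_RE.match(text))


def is_locus_like(text: str) -> bool:
    """Shape check for Arabidopsis-style locus identifiers (AT4G37770)."""
    return bool(_LOCUS_RE.match(text))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compound:
    compound_id: str
    name: str
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    ec_numbers: tuple[str, ...] = ()
    substrate_ids: frozenset[str] = frozenset()
    product_ids: frozenset[str] = frozenset()
    reversible: bool = False
    pathway_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Enzyme:
    """An enzymatic activity, keyed by its EC string.

    ``gene_ids`` may be empty: family-level activities such as EC 1.14.13.-
    exist in curated pathway databases without a locus assignment.
    """

    ec: str
    display_name: str = ""
    gene_ids: frozenset[str] = frozenset()
    protein_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str = ""


@dataclass(frozen=True)
class HormoneAnnotation:
    hormone: str
    pathway_id: str
    role: str


@dataclass(frozen=True)
class RegulationRecord:
    tf_gene_id: str
    target_gene_id: str


@dataclass(frozen=True)
class PPIRecord:
    """An unordered protein–protein interaction pair (gene_a < gene_b)."""

    gene_a: str
    gene_b: str

    @staticmethod
    def make(a: str, b: str) -> "PPIRecord":
        if a == b:
            raise ValueError(f"self-interaction not allowed: {a}")
        return PPIRecord(*sorted((a, b)))


@dataclass(frozen=True)
class EvidenceSets:
    expressed_gene_ids: frozenset[str]
    detected_protein_gene_ids: frozenset[str]
    context: str = ""


@dataclass
class PathwayDB:
    """Keyed collections of compounds, reactions, enzymes and pathways.

    Enzymes are keyed by EC string; reactions link to enzymes through their
    ``ec_numbers`` by exact string equality (a reaction annotated
    ``6.3.-.-`` is catalysed by the family-level enzyme record ``6.3.-.-``).
    """

    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    enzymes: dict[str, Enzyme] = field(default_factory=dict)
    pathways: dict[str, Pathway] = field(default_factory=dict)

    def reactions_of_enzyme(self, ec: str) -> list[Reaction]:
        return self._by_enzyme().get(ec, [])

    def reactions_of_pathway(self, pathway_id: str) -> list[Reaction]:
        return self._by_pathway().get(pathway_id, [])

    def _by_enzyme(self) -> dict[str, list[Reaction]]:
        index: dict[str, list[Reaction]] = {}
        for rxn in self.reactions.values():
            for ec in rxn.ec_numbers:
                index.setdefault(ec, []).append(rxn)
        return index

    def _by_pathway(self) -> dict[str, list[Reaction]]:
        index: dict[str, list[Reaction]] = {}
        for rxn in self.reactions.values():
            for pid in rxn.pathway_ids:
                index.setdefault(pid, []).append(rxn)
        return index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayDB):
            return NotImplemented
        return (
            self.compounds == other.compounds
            and self.reactions == other.reactions
            and self.enzymes == other.enzymes
            and self.pathways == other.pathways
        )


@dataclass
class ValidationReport:
    dangling_references: list[tuple[str, str, str]] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    empty_reactions: list[str] = field(default_factory=list)
    duplicate_ec_warnings: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.dangling_references
            or self.duplicate_ids
            or self.empty_reactions
            or self.duplicate_ec_warnings
        )

    def __bool__(self) -> bool:  # truthy when problems were found
        return not self.is_empty()


# ---------------------------------------------------------------------------
# attribute–value flat-file parsing
# ---------------------------------------------------------------------------

def _iter_records(stream) -> list[list[tuple[str, str]]]:
    """Split an attribute–value stream into records of (attribute, value)."""
    if isinstance(stream, (str, bytes)):
        stream = io.StringIO(stream if isinstance(stream, str) else stream.decode())
    records: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            continue
        if line.strip() == "//":
            if current:
                records.append(current)
                current = []
            continue
        if line.startswith("/"):
            if not current:
                raise ParseError(f"line {lineno}: continuation with no open record")
            attr, value = current[-1]
            current[-1] = (attr, value + " " + line[1:].strip())
            continue
        if " - " not in line:
            raise ParseError(f"line {lineno}: expected 'ATTRIBUTE - VALUE', got {line!r}")
        attr, _, value = line.partition(" - ")
        current.append((attr.strip(), value.strip()))
    if current:
        records.append(current)
    return records


def _first(record: list[tuple[str, str]], attr: str, default: str = "") -> str:
    for a, v in record:
        if a == attr:
            return v
    return default


def _all(record: list[tuple[str, str]], attr: str) -> list[str]:
    return [v for a, v in record if a == attr]


def parse_pathway_flatfiles(
    compound_text,
    reaction_text,
    enzyme_text,
    pathway_text,
) -> PathwayDB:
    """Parse the four flat-files into a validated :class:`PathwayDB`.

    Unknown attributes are ignored.  Duplicate ``UNIQUE-ID`` records raise
    :class:`ParseError`; references that do not resolve raise
    :class:`IntegrityError` listing every offender.
    """
    db = PathwayDB()

    for record in _iter_records(compound_text):
        cid = _first(record, "UNIQUE-ID")
        if not cid:
            raise ParseError("compound record without UNIQUE-ID")
        if cid in db.compounds:
            raise ParseError(f"duplicate compound id {cid!r}")
        db.compounds[cid] = Compound(
            compound_id=cid,
            name=_first(record, "COMMON-NAME", cid),
            synonyms=tuple(_all(record, "SYNONYMS")),
        )

    for record in _iter_records(pathway_text):
        pid = _first(record, "UNIQUE-ID")
        if not pid:
            raise ParseError("pathway record without UNIQUE-ID")
        if pid in db.pathways:
            raise ParseError(f"duplicate pathway id {pid!r}")
        db.pathways[pid] = Pathway(pathway_id=pid, name=_first(record, "COMMON-NAME", pid))

    for record in _iter_records(enzyme_text):
        ec = _first(record, "UNIQUE-ID")
        if not ec:
            raise ParseError("enzyme record without UNIQUE-ID")
        if not is_valid_ec(ec):
            raise ParseError(f"enzyme id {ec!r} is not an EC string")
        if ec in db.enzymes:
            raise ParseError(f"duplicate enzyme id {ec!r}")
        db.enzymes[ec] = Enzyme(
            ec=ec,
            display_name=_first(record, "COMMON-NAME", ec),
            gene_ids=frozenset(_all(record, "GENE")),
            protein_ids=frozenset(_all(record, "PROTEIN")),
        )

    for record in _iter_records(reaction_text):
        rid = _first(record, "UNIQUE-ID")
        if not rid:
            raise ParseError("reaction record without UNIQUE-ID")
        if rid in db.reactions:
            raise ParseError(f"duplicate reaction id {rid!r}")
        ecs = tuple(_all(record, "EC-NUMBER"))
        for ec in ecs:
            if not is_valid_ec(ec):
                raise ParseError(f"reaction {rid}: malformed EC {ec!r}")
        db.reactions[rid] = Reaction(
            reaction_id=rid,
            ec_numbers=ecs,
            substrate_ids=frozenset(_all(record, "LEFT")),
            product_ids=frozenset(_all(record, "RIGHT")),
            reversible=_first(record, "REVERSIBLE", "F").upper() in ("T", "TRUE", "YES"),
            pathway_ids=frozenset(_all(record, "IN-PATHWAY")),
        )

    report = validate_db(db)
    if report.dangling_references:
        offenders = ", ".join(f"{r}.{f}->{m}" for r, f, m in report.dangling_references)
        raise IntegrityError(f"dangling references: {offenders}")
    if report.empty_reactions:
        raise IntegrityError(
            "reactions with no substrates and no products: "
            + ", ".join(report.empty_reactions)
        )
    return db


def validate_db(db: PathwayDB) -> ValidationReport:
    """Referential-integrity report for a database.  Never raises.

    An empty report means the database is valid.
    """
    report = ValidationReport()
    for rxn in db.reactions.values():
        for cid in sorted(rxn.substrate_ids | rxn.product_ids):
            if cid not in db.compounds:
                report.dangling_references.append((rxn.reaction_id, "compound", cid))
        for pid in sorted(rxn.pathway_ids):
            if pid not in db.pathways:
                report.dangling_references.append((rxn.reaction_id, "pathway", pid))
        if not rxn.substrate_ids and not rxn.product_ids:
            report.empty_reactions.append(rxn.reaction_id)
    seen_ec: dict[str, str] = {}
    for key, enz in db.enzymes.items():
        if enz.ec in seen_ec and seen_ec[enz.ec] != key:
            report.duplicate_ec_warnings.append(enz.ec)
        seen_ec.setdefault(enz.ec, key)
    return report


# ---------------------------------------------------------------------------
# tables and lists
# ---------------------------------------------------------------------------

def _lines(stream) -> list[str]:
    if isinstance(stream, (str, bytes)):
        stream = io.StringIO(stream if isinstance(stream, str) else stream.decode())
    return [line.rstrip("\n") for line in stream]


def parse_hormone_annotations(table_text) -> list[HormoneAnnotation]:
    """Parse a tab-separated hormone→pathway annotation table.

    Columns (header required): hormone, pathway_id, role.  Hormones outside
    the eight-element vocabulary are rejected; whether pathway ids resolve is
    checked at validation time against a database, not here.
    """
    lines = [ln for ln in _lines(table_text) if ln.strip() and not ln.startswith("#")]
    if not lines:
        log.warning("empty annotation table")
        return []
    header = [h.strip() for h in lines[0].split("\t")]
    if header[:3] != ["hormone", "pathway_id", "role"]:
        raise ParseError(f"annotation header must be hormone/pathway_id/role, got {header}")
    out: list[HormoneAnnotation] = []
    for ln in lines[1:]:
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) < 3:
            raise ParseError(f"annotation row with fewer than 3 columns: {ln!r}")
        hormone, pathway_id, role = parts[0], parts[1], parts[2]
        if hormone not in HORMONES:
            raise VocabularyError(f"unknown hormone {hormone!r}")
        if role not in ANNOTATION_ROLES:
            raise VocabularyError(f"unknown annotation role {role!r}")
        out.append(HormoneAnnotation(hormone=hormone, pathway_id=pathway_id, role=role))
    return out


def parse_regulation_table(table_text, strict_loci: bool = False) -> list[RegulationRecord]:
    """Parse two-column TF→target rows; duplicates are collapsed."""
    seen: set[tuple[str, str]] = set()
    out: list[RegulationRecord] = []
    rows = [ln for ln in _lines(table_text) if ln.strip() and not ln.startswith("#")]
    if not rows:
        log.warning("empty regulation table")
        return []
    for ln in rows:
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ParseError(f"regulation row needs two ids: {ln!r}")
        if parts[0].lower() in ("tf_gene_id", "tf"):  # optional header
            continue
        tf, target = parts[0], parts[1]
        if strict_loci and not (is_locus_like(tf) and is_locus_like(target)):
            raise ParseError(f"non-locus identifier in row {ln!r}")
        if (tf, target) not in seen:
            seen.add((tf, target))
            out.append(RegulationRecord(tf_gene_id=tf, target_gene_id=target))
    return out


def parse_ppi_table(table_text, strict_loci: bool = False) -> list[PPIRecord]:
    """Parse two-column interaction pairs, normalized to unordered form."""
    seen: set[tuple[str, str]] = set()
    out: list[PPIRecord] = []
    rows = [ln for ln in _lines(table_text) if ln.strip() and not ln.startswith("#")]
    if not rows:
        log.warning("empty PPI table")
        return []
    for ln in rows:
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ParseError(f"PPI row needs two ids: {ln!r}")
        if parts[0].lower() in ("gene_a", "protein_a"):
            continue
        if strict_loci and not (is_locus_like(parts[0]) and is_locus_like(parts[1])):
            raise ParseError(f"non-locus identifier in row {ln!r}")
        rec = PPIRecord.make(parts[0], parts[1])
        key = (rec.gene_a, rec.gene_b)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def parse_expression_lists(gene_text, protein_text, context: str = "") -> EvidenceSets:
    """Parse one-id-per-line expressed-gene and detected-protein lists."""
    genes = frozenset(
        ln.strip() for ln in _lines(gene_text) if ln.strip() and not ln.startswith("#")
    )
    proteins = frozenset(
        ln.strip() for ln in _lines(protein_text) if ln.strip() and not ln.startswith("#")
    )
    if not genes:
        log.warning("empty expressed-gene list (context=%s)", context)
    if not proteins:
        log.warning("empty detected-protein list (context=%s)", context)
    return EvidenceSets(
        expressed_gene_ids=genes, detected_protein_gene_ids=proteins, context=context
    )


# ---------------------------------------------------------------------------
# flat-file writing (round-trip partner of parse_pathway_flatfiles)
# ---------------------------------------------------------------------------

def write_pathway_flatfiles(db: PathwayDB) -> dict[str, str]:
    """Serialize a database back to the four flat-file texts.

    Output is deterministic (records and multi-valued attributes sorted), so
    ``parse(write(db)) == db`` up to that canonical ordering.
    """
    chunks: dict[str, list[str]] = {"compounds": [], "reactions": [], "enzymes": [], "pathways": []}

    for cid in sorted(db.compounds):
        c = db.compounds[cid]
        rec = [f"UNIQUE-ID - {c.compound_id}", f"COMMON-NAME - {c.name}"]
        rec += [f"SYNONYMS - {s}" for s in c.synonyms]
        chunks["compounds"].append("\n".join(rec) + "\n//")

    for pid in sorted(db.pathways):
        p = db.pathways[pid]
        chunks["pathways"].append(f"UNIQUE-ID - {p.pathway_id}\nCOMMON-NAME - {p.name}\n//")

    for ec in sorted(db.enzymes):
        e = db.enzymes[ec]
        rec = [f"UNIQUE-ID - {e.ec}", f"COMMON-NAME - {e.display_name}"]
        rec += [f"GENE - {g}" for g in sorted(e.gene_ids)]
        rec += [f"PROTEIN - {p}" for p in sorted(e.protein_ids)]
        chunks["enzymes"].append("\n".join(rec) + "\n//")

    for rid in sorted(db.reactions):
        r = db.reactions[rid]
        rec = [f"UNIQUE-ID - {r.reaction_id}"]
        rec += [f"EC-NUMBER - {ec}" for ec in r.ec_numbers]
        rec += [f"LEFT - {c}" for c in sorted(r.substrate_ids)]
        rec += [f"RIGHT - {c}" for c in sorted(r.product_ids)]
        rec.append(f"REVERSIBLE - {'T' if r.reversible else 'F'}")
        rec += [f"IN-PATHWAY - {p}" for p in sorted(r.pathway_ids)]
        chunks["reactions"].append("\n".join(rec) + "\n//")

    return {name: "\n".join(records) + ("\n" if records else "") for name, records in chunks.items()}


# ---------------------------------------------------------------------------
# network writing
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "edge-tsv")


def write_network(network, format: str) -> str:
    """Serialize a crosstalk network to SIF, GraphML or edge-TSV text.

    Output is byte-stable for a fixed network: nodes and edges are emitted in
    sorted order.  SIF relations are ``shares_compound``, ``acts_in`` or
    ``co_targets``; GraphML carries node ``kind`` and edge ``relation`` plus
    ``provenance`` (sorted, ``|``-joined) attributes.
    """
    import networkx as nx

    inner = getattr(network, "graph", None)
    graph = inner if isinstance(inner, nx.Graph) else network
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")

    edges = sorted((min(u, v), max(u, v), data) for u, v, data in graph.edges(data=True))

    if fmt == "sif":
        lines = [f"{u}\t{d.get('relation', 'shares_compound')}\t{v}" for u, v, d in edges]
        return "\n".join(lines) + ("\n" if lines else "")

    if fmt == "edge-tsv":
        lines = ["source\ttarget\trelation\tprovenance"]
        for u, v, d in edges:
            prov = "|".join(sorted(d.get("provenance", ())))
            lines.append(f"{u}\t{v}\t{d.get('relation', '')}\t{prov}")
        return "\n".join(lines) + "\n"

    out = nx.Graph()
    for node in sorted(graph.nodes):
        out.add_node(node, kind=graph.nodes[node].get("kind", "enzyme"))
    for u, v, d in edges:
        out.add_edge(
            u,
            v,
            relation=d.get("relation", ""),
            provenance="|".join(sorted(d.get("provenance", ()))),
        )
    buffer = io.BytesIO()
    nx.write_graphml(out, buffer, named_key_ids=True, edge_id_from_attribute=None)
    return buffer.getvalue().decode()


def read_network_graphml(text: str):
    """Read a network written by :func:`write_network` back into a graph.

    The ``provenance`` attribute is split back into a frozenset.
    """
    import networkx as nx

    graph = nx.read_graphml(io.BytesIO(text.encode()))
    out = nx.Graph()
    for node, data in graph.nodes(data=True):
        out.add_node(node, kind=data.get("kind", "enzyme"))
    for u, v, data in graph.edges(data=True):
        prov = data.get("provenance", "")
        out.add_edge(
            u,
            v,
            relation=data.get("relation", ""),
            provenance=frozenset(p for p in prov.split("|") if p),
        )
    return out
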