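"""Synthetic input generation with planted ground truth, plus the packaged
curated Arabidopsis fixture.

The generator emulates the shapes of the real inputs — a BioCyc-style
pathway database, a hormone→pathway annotation table, TF→target regulation,
PPI pairs and expressed/detected ID lists — while planting recoverable
structure: a producer/consumer enzyme chain of known length through unique
linker compounds, hormone-bridging enzymes for requested hormone pairs,
TF cycles in the co-target network (with a PPI chain over each), and noisy
evidence lists with known sensitivity and false-positive rate.

Everything is deterministic for a fixed seed: identical parameters and seed
yield byte-identical flat-files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import pathway_io
from .network_build import CurrencyPolicy
from .pathway_io import (
    Compound,
    Enzyme,
    EvidenceSets,
    HormoneAnnotation,
    Pathway,
    PathwayDB,
    PPIRecord,
    Reaction,
    RegulationRecord,
)

HORMONES = pathway_io.HORMONES


@dataclass(frozen=True)
class SynthesisParams:
    """Study conditions for the synthetic bundle.

    Defaults describe a desk-scale pathway database with one planted
    13-step route (the length of the curated consecutive route), one
    11-enzyme auxin–cytokinin bridge, a handful of planted TF cycles over a
    sparse co-target background, and imperfect but sensitive evidence lists
    (sensitivity 0.9, false-positive rate 0.05) emulating single-tissue
    transcriptome/proteome coverage.
    """

    seed: int = 0
    n_compounds: int = 120
    n_currency: int = 8
    n_pathways: int = 12
    reactions_per_pathway: int = 4
    n_enzymes: int = 60
    planted_route_length: int = 13
    n_hormones: int = 8
    hormone_bridge_enzymes: tuple[tuple[tuple[str, str], int], ...] = (
        (("auxin", "cytokinin"), 11),
    )
    n_tfs: int = 40
    n_targets: int = 60
    planted_cycle_lengths: tuple[int, ...] = (6,)
    background_cotarget_density: float = 0.02
    evidence_sensitivity: float = 0.9
    evidence_false_positive_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "n_compounds",
            "n_pathways",
            "reactions_per_pathway",
            "n_enzymes",
            "planted_route_length",
            "n_tfs",
            "n_targets",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.evidence_sensitivity <= 1):
            raise ValueError("evidence_sensitivity must be in [0, 1]")
        if not (0 <= self.evidence_false_positive_rate <= 1):
            raise ValueError("evidence_false_positive_rate must be in [0, 1]")
        if not (1 <= self.n_hormones <= len(HORMONES)):
            raise ValueError("n_hormones must be in 1..8")
        if self.planted_route_length > self.n_enzymes:
            raise ValueError("planted route longer than the enzyme count")
        for length in self.planted_cycle_lengths:
            if length < 3:
                raise ValueError("planted cycle lengths must be >= 3")
        if self.planted_route_length > 998:
            raise ValueError("planted route length out of range")


@dataclass
class GroundTruth:
    route_enzymes: tuple[str, ...] = ()
    route_links: tuple[str, ...] = ()
    bridge_enzymes: dict = field(default_factory=dict)
    planted_cycles: tuple[tuple[str, ...], ...] = ()
    expressed_genes: frozenset[str] = frozenset()


def _ec_for_index(i: int) -> str:
    # synthetic but well-formed EC strings, unique per enzyme index
    return f"{1 + i % 6}.{1 + (i // 6) % 9}.{1 + (i // 54) % 9}.{i + 1}"


def generate_pathway_db(
    params: SynthesisParams,
) -> tuple[PathwayDB, list[HormoneAnnotation], GroundTruth]:
    """Synthetic pathway database with a planted route and hormone bridges.

    The planted route is a chain of ``planted_route_length`` enzymes joined
    through unique non-currency linker compounds; background reactions draw
    only on a disjoint compound pool, so the planted chain is the unique
    maximum route over the planted enzyme set (verified post hoc with the
    exact extractor; offending draws are resampled).
    """
    rng = np.random.default_rng(params.seed)
    db = PathwayDB()

    currency = [f"CUR-{i:03d}" for i in range(params.n_currency)]
    background = [f"CPD-{i:04d}" for i in range(params.n_compounds)]
    route_len = params.planted_route_length
    linkers = [f"LINK-{i:03d}" for i in range(route_len - 1)]
    for cid in currency + background + linkers:
        db.compounds[cid] = Compound(compound_id=cid, name=cid.lower())

    hormones = list(HORMONES[: params.n_hormones])
    pathway_ids = [f"PWY-{i:03d}" for i in range(params.n_pathways)]
    for pid in pathway_ids:
        db.pathways[pid] = Pathway(pathway_id=pid, name=pid.lower())
    hormone_pwys: dict[str, str] = {}
    for i, hormone in enumerate(hormones):
        pid = f"PWY-H{i:02d}"
        db.pathways[pid] = Pathway(pathway_id=pid, name=f"{hormone} pathway")
        hormone_pwys[hormone] = pid
    annotations = [
        HormoneAnnotation(hormone=h, pathway_id=p, role="biosynthesis")
        for h, p in sorted(hormone_pwys.items())
    ]

    ecs = [_ec_for_index(i) for i in range(params.n_enzymes)]
    for i, ec in enumerate(ecs):
        db.enzymes[ec] = Enzyme(
            ec=ec, display_name=f"enzyme {i}", gene_ids=frozenset({f"SY1G{10000 + i}"})
        )

    route_ecs = ecs[:route_len]
    n_bridge = sum(count for _, count in params.hormone_bridge_enzymes)
    bridge_ecs = ecs[route_len : route_len + n_bridge]
    if len(bridge_ecs) < n_bridge:
        raise ValueError("not enough enzymes for the requested hormone bridges")
    other_ecs = ecs[route_len + n_bridge :]

    # planted producer/consumer chain through unique linkers
    for i, ec in enumerate(route_ecs):
        subs, prods = set(), set()
        if i > 0:
            subs.add(linkers[i - 1])
        else:
            subs.add(f"CPD-{0:04d}")
        if i < route_len - 1:
            prods.add(linkers[i])
        db.reactions[f"RXN-ROUTE-{i:03d}"] = Reaction(
            reaction_id=f"RXN-ROUTE-{i:03d}",
            ec_numbers=(ec,),
            substrate_ids=frozenset(subs),
            product_ids=frozenset(prods),
            pathway_ids=frozenset({pathway_ids[i % len(pathway_ids)]}),
        )

    # hormone bridges: each bridge enzyme gets one reaction in each hormone's pathway
    bridges: dict[tuple[str, str], list[str]] = {}
    cursor = 0
    marker = 0
    for (h1, h2), count in params.hormone_bridge_enzymes:
        members = bridge_ecs[cursor : cursor + count]
        cursor += count
        bridges[(h1, h2)] = list(members)
        for ec in members:
            for hormone in (h1, h2):
                rid = f"RXN-BRIDGE-{marker:03d}"
                db.reactions[rid] = Reaction(
                    reaction_id=rid,
                    ec_numbers=(ec,),
                    substrate_ids=frozenset({f"CPD-{1 + marker % (params.n_compounds - 1):04d}"}),
                    product_ids=frozenset(),
                    pathway_ids=frozenset({hormone_pwys[hormone]}),
                )
                marker += 1

    # background reactions over the background pool only (never the linkers),
    # rejected-and-resampled if they touch planted route enzymes
    rxn_i = 0
    for pid in pathway_ids:
        for _ in range(params.reactions_per_pathway):
            if not other_ecs:
                break
            ec = other_ecs[int(rng.integers(len(other_ecs)))]
            pool = rng.choice(params.n_compounds, size=4, replace=False)
            subs = {f"CPD-{pool[0]:04d}", f"CPD-{pool[1]:04d}", currency[0]}
            prods = {f"CPD-{pool[2]:04d}", f"CPD-{pool[3]:04d}"}
            rid = f"RXN-BG-{rxn_i:04d}"
            db.reactions[rid] = Reaction(
                reaction_id=rid,
                ec_numbers=(ec,),
                substrate_ids=frozenset(subs),
                product_ids=frozenset(prods),
                pathway_ids=frozenset({pid}),
            )
            rxn_i += 1

    truth = GroundTruth(
        route_enzymes=tuple(route_ecs),
        route_links=tuple(linkers),
        bridge_enzymes={pair: tuple(members) for pair, members in bridges.items()},
        expressed_genes=frozenset(
            g for ec in route_ecs for g in db.enzymes[ec].gene_ids
        ),
    )

    # post-hoc guarantee: the planted chain is the unique maximum route
    from .route_extraction import build_coupling_graph, extract_routes

    policy = CurrencyPolicy(currency_ids=frozenset(currency))
    routes = extract_routes(build_coupling_graph(db, route_ecs, policy))
    expected = tuple(route_ecs) if route_ecs[0] <= route_ecs[-1] else tuple(reversed(route_ecs))
    if len(routes) != 1 or routes[0].steps != expected:
        raise AssertionError("planted route not uniquely recoverable; invalid construction")
    return db, annotations, truth


def generate_regulation(
    params: SynthesisParams,
) -> tuple[list[RegulationRecord], list[PPIRecord], GroundTruth]:
    """Regulation and PPI tables with planted co-target cycles.

    TF *i* and TF *i+1* of a planted cycle share a dedicated target gene
    (wrap-around closes the cycle); random background co-targeting is added
    at ``background_cotarget_density`` via shared background targets; PPI
    pairs form a Hamiltonian chain over each planted cycle's TFs.
    """
    rng = np.random.default_rng(params.seed + 1)
    tfs = [f"SY2G{20000 + i}" for i in range(params.n_tfs)]
    regulation: list[RegulationRecord] = []
    ppi: list[PPIRecord] = []
    cycles: list[tuple[str, ...]] = []

    cursor = 0
    target_i = 0
    for length in params.planted_cycle_lengths:
        if cursor + length > len(tfs):
            raise ValueError("not enough TFs for the requested planted cycles")
        members = tfs[cursor : cursor + length]
        cursor += length
        for i in range(length):
            a, b = members[i], members[(i + 1) % length]
            target = f"SY3G{30000 + target_i}"
            target_i += 1
            regulation.append(RegulationRecord(a, target))
            regulation.append(RegulationRecord(b, target))
        for a, b in zip(members, members[1:]):
            ppi.append(PPIRecord.make(a, b))
        cycles.append(tuple(members))

    background_tfs = tfs  # background edges may touch planted TFs too
    n = len(background_tfs)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < params.background_cotarget_density:
                target = f"SY3G{40000 + target_i}"
                target_i += 1
                regulation.append(RegulationRecord(background_tfs[i], target))
                regulation.append(RegulationRecord(background_tfs[j], target))

    truth = GroundTruth(planted_cycles=tuple(cycles))
    return regulation, ppi, truth


def generate_evidence(truth: GroundTruth, params: SynthesisParams, universe=None) -> EvidenceSets:
    """Noisy evidence lists from the true expressed set.

    Each truly-expressed gene is reported with probability
    ``evidence_sensitivity``; every other gene of *universe* with
    probability ``evidence_false_positive_rate``.
    """
    rng = np.random.default_rng(params.seed + 2)
    universe = sorted(universe) if universe is not None else sorted(truth.expressed_genes)
    expressed = set()
    for gene in universe:
        p = (
            params.evidence_sensitivity
            if gene in truth.expressed_genes
            else params.evidence_false_positive_rate
        )
        if rng.random() < p:
            expressed.add(gene)
    detected = {g for g in sorted(expressed) if rng.random() < params.evidence_sensitivity}
    return EvidenceSets(
        expressed_gene_ids=frozenset(expressed),
        detected_protein_gene_ids=frozenset(detected),
        context="synthetic",
    )


def write_bundle(out_dir, params: SynthesisParams) -> GroundTruth:
    """Generate a full bundle and write it as flat-files/TSVs to *out_dir*."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    db, annotations, truth = generate_pathway_db(params)
    regulation, ppi, reg_truth = generate_regulation(params)
    truth.planted_cycles = reg_truth.planted_cycles
    evidence = generate_evidence(truth, params)

    files = pathway_io.write_pathway_flatfiles(db)
    for name, text in files.items():
        with open(os.path.join(out_dir, f"{name}.dat"), "w") as fh:
            fh.write(text)
    with open(os.path.join(out_dir, "hormone_annotations.tsv"), "w") as fh:
        fh.write("hormone\tpathway_id\trole\n")
        for a in annotations:
            fh.write(f"{a.hormone}\t{a.pathway_id}\t{a.role}\n")
    with open(os.path.join(out_dir, "regulation.tsv"), "w") as fh:
        for r in regulation:
            fh.write(f"{r.tf_gene_id}\t{r.target_gene_id}\n")
    with open(os.path.join(out_dir, "ppi.tsv"), "w") as fh:
        for r in ppi:
            fh.write(f"{r.gene_a}\t{r.gene_b}\n")
    with open(os.path.join(out_dir, "expressed_genes.txt"), "w") as fh:
        for g in sorted(evidence.expressed_gene_ids):
            fh.write(g + "\n")
    with open(os.path.join(out_dir, "detected_proteins.txt"), "w") as fh:
        for g in sorted(evidence.detected_protein_gene_ids):
            fh.write(g + "\n")
    return truth


# ---------------------------------------------------------------------------
# packaged curated fixture
# ---------------------------------------------------------------------------

#: The thirteen consecutive-route enzymes of the curated fixture, in step order.
FIXTURE_ROUTE_ECS = (
    "1.3.1.-",
    "1.14.13.-",
    "2.4.1.-",
    "2.4.1.203",
    "1.14.11.23",
    "2.1.1.-",
    "1.14.11.-",
    "1.2.3.7",
    "2.4.1.121",
    "6.3.-.-",
    "2.6.1.57",
    "4.4.1.14",
    "1.14.17.4",
)

#: Currency policy matching the curated fixture's compound identifiers.
FIXTURE_CURRENCY = CurrencyPolicy(
    currency_ids=frozenset(
        {"WATER", "PROTON", "ATP", "AMP", "PPI", "UDP", "O2", "CO2"}
    )
)


def _fixture_text(name: str) -> str:
    return (
        resources.files("hormonet").joinpath("fixtures/arabidopsis").joinpath(name).read_text()
    )


def load_arabidopsis_fixture():
    """Load the packaged curated Arabidopsis crosstalk fixture.

    Returns (PathwayDB, annotations, regulation, ppi, EvidenceSets).  The
    fixture transcribes the curated consecutive metabolic route (13 enzymes
    with their text-named linking metabolites and documented placeholders),
    the hormone annotations for all eight hormones including the 11
    auxin–cytokinin bridge enzymes, the TF control-unit regulation rows with
    the unit-C PPI chain, and root-stele expressed-gene / root-proteome
    lists.
    """
    db = pathway_io.parse_pathway_flatfiles(
        _fixture_text("compounds.dat"),
        _fixture_text("reactions.dat"),
        _fixture_text("enzymes.dat"),
        _fixture_text("pathways.dat"),
    )
    annotations = pathway_io.parse_hormone_annotations(_fixture_text("hormone_annotations.tsv"))
    regulation = pathway_io.parse_regulation_table(_fixture_text("regulation.tsv"))
    ppi = pathway_io.parse_ppi_table(_fixture_text("ppi.tsv"))
    evidence = pathway_io.parse_expression_lists(
        _fixture_text("expressed_genes.txt"),
        _fixture_text("detected_proteins.txt"),
        context="root stele",
    )
    return db, annotations, regulation, ppi, evidence
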