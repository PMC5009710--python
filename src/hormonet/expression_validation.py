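"""Transcript/protein evidence overlay on metabolic routes.

Evidence is presence/absence: a route step is transcript-supported when at
least one gene encoding its enzyme appears in the expressed-gene list, and
protein-supported when at least one appears in the detected-protein list.
Family-level (wildcard) EC steps aggregate the genes of every matching
enzyme record, because curated tables list many loci per family-level row.
A permutation null (random equal-size enzyme sets from the database) turns
the descriptive coverage into a p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_build import ec_match
from .pathway_io import EvidenceSets, HormoneAnnotation, PathwayDB, RegulationRecord
from .route_extraction import MetabolicRoute, route_report


@dataclass(frozen=True)
class EvidenceRow:
    step: int
    ec: str
    gene_ids: frozenset[str]
    expressed_gene_ids: frozenset[str]
    protein_supported_gene_ids: frozenset[str]
    expressed_regulating_tfs: frozenset[str]
    crosstalk: tuple[str, ...]


@dataclass(frozen=True)
class CoverageSummary:
    steps_total: int
    steps_with_transcript: int
    steps_with_protein: int
    fraction_transcript: float
    fraction_protein: float


def genes_for_ec(db: PathwayDB, ec_pattern: str) -> frozenset[str]:
    """Genes of every database enzyme whose EC matches *ec_pattern*."""
    genes: set[str] = set()
    for enzyme in db.enzymes.values():
        if ec_match(enzyme.ec, ec_pattern):
            genes |= enzyme.gene_ids
    return frozenset(genes)


def annotate_evidence(
    route: MetabolicRoute,
    db: PathwayDB,
    regulation: list[RegulationRecord],
    evidence: EvidenceSets,
    annotations: list[HormoneAnnotation] | None = None,
) -> list[EvidenceRow]:
    """Per-step evidence report for a route.

    Regulating TFs of a step are the TFs whose targets intersect the step's
    genes, intersected with the expressed set.
    """
    annotations = annotations or []
    tf_targets: dict[str, set[str]] = {}
    for rec in regulation:
        tf_targets.setdefault(rec.tf_gene_id, set()).add(rec.target_gene_id)
    base = route_report(route, db, annotations)
    rows = []
    for entry in base:
        genes = genes_for_ec(db, entry["ec"])
        expressed = genes & evidence.expressed_gene_ids
        proteins = genes & evidence.detected_protein_gene_ids
        tfs = {
            tf
            for tf, targets in tf_targets.items()
            if targets & genes and tf in evidence.expressed_gene_ids
        }
        rows.append(
            EvidenceRow(
                step=entry["step"],
                ec=entry["ec"],
                gene_ids=genes,
                expressed_gene_ids=frozenset(expressed),
                protein_supported_gene_ids=frozenset(proteins),
                expressed_regulating_tfs=frozenset(tfs),
                crosstalk=tuple(entry["crosstalk"]),
            )
        )
    return rows


def coverage_summary(report: list[EvidenceRow]) -> CoverageSummary:
    """Step counts and coverage fractions of an evidence report."""
    if not report:
        raise ValueError("empty evidence report")
    total = len(report)
    with_transcript = sum(1 for row in report if row.expressed_gene_ids)
    with_protein = sum(1 for row in report if row.protein_supported_gene_ids)
    return CoverageSummary(
        steps_total=total,
        steps_with_transcript=with_transcript,
        steps_with_protein=with_protein,
        fraction_transcript=with_transcript / total,
        fraction_protein=with_protein / total,
    )


def permutation_support(
    route: MetabolicRoute,
    db: PathwayDB,
    evidence: EvidenceSets,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the route's transcript coverage.

    Draws *n_perm* random enzyme sets of the route's size from the database
    and counts those whose transcript coverage reaches the observed one:
    p = (1 + #{coverage >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    universe = sorted(db.enzymes)
    size = len(route.steps)
    if size > len(universe):
        raise ValueError("route larger than the enzyme universe")

    def coverage(ecs) -> float:
        supported = sum(
            1 for ec in ecs if genes_for_ec(db, ec) & evidence.expressed_gene_ids
        )
        return supported / len(ecs)

    observed = coverage(route.steps)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        sample = rng.choice(len(universe), size=size, replace=False)
        if coverage([universe[i] for i in sample]) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
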