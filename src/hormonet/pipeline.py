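"""End-to-end orchestration: parse → networks → hubs → clusters → routes →
TF units → evidence overlay, with deterministic, re-loadable outputs.

A single seed governs every stochastic stage (EPC realizations, the
permutation null) through fixed per-stage offsets, so one number reproduces
a run.  Every output file starts with a header comment recording the seed
and the stage parameters; no timestamps are written, making reruns
byte-identical.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import yaml

from . import pathway_io
from .centrality import CentralityParams, compute_centrality_table, rank_and_select_hubs
from .clustering import ClusterParams, detect_clusters
from .expression_validation import annotate_evidence, coverage_summary, permutation_support
from .network_build import (
    CurrencyPolicy,
    build_eapcn,
    build_gecn,
    network_summary,
    shared_crosstalk_enzymes,
)
from .route_extraction import build_coupling_graph, extract_routes
from .tf_circuits import assemble_units, build_cotarget_network, enumerate_cycles, find_ppi_route

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat key-value configuration of a pipeline run."""

    db_dir: str
    annotations_tsv: str
    out_dir: str
    regulation_tsv: str | None = None
    ppi_tsv: str | None = None
    expressed_txt: str | None = None
    proteins_txt: str | None = None
    currency_file: str | None = None
    seed: int = 0
    hub_k: int = 13
    hub_m: int = 6
    cluster_penalty: float = 2.0
    cluster_min_size: int = 3
    cluster_min_density: float = 0.5
    cycle_max_len: int = 15
    epc_realizations: int = 1000
    n_perm: int = 999
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        base = os.path.dirname(os.path.abspath(path))
        cfg = cls(**kwargs, extra=extra)
        for name in (
            "db_dir",
            "annotations_tsv",
            "regulation_tsv",
            "ppi_tsv",
            "expressed_txt",
            "proteins_txt",
            "currency_file",
            "out_dir",
        ):
            value = getattr(cfg, name)
            if value is not None and not os.path.isabs(value):
                setattr(cfg, name, os.path.join(base, value))
        return cfg


def _read(path: str) -> str:
    with open(path) as fh:
        return fh.read()


def _header(cfg: PipelineConfig, stage: str) -> str:
    return (
        f"# hormonet stage={stage} seed={cfg.seed} hub_k={cfg.hub_k} hub_m={cfg.hub_m} "
        f"penalty={cfg.cluster_penalty} cycle_max_len={cfg.cycle_max_len} "
        f"epc_realizations={cfg.epc_realizations}\n"
    )


def run_pipeline(config: PipelineConfig | str) -> dict:
    """Execute every stage and write all artifacts under ``out_dir``.

    Returns the summary dictionary (also written as summary.yaml).  Any
    stage error aborts with the stage name in the message; artifacts written
    before the failure are retained.
    """
    cfg = PipelineConfig.from_yaml(config) if isinstance(config, str) else config
    os.makedirs(cfg.out_dir, exist_ok=True)
    summary: dict = {"seed": cfg.seed}
    stage = "parse"
    try:
        db = pathway_io.parse_pathway_flatfiles(
            _read(os.path.join(cfg.db_dir, "compounds.dat")),
            _read(os.path.join(cfg.db_dir, "reactions.dat")),
            _read(os.path.join(cfg.db_dir, "enzymes.dat")),
            _read(os.path.join(cfg.db_dir, "pathways.dat")),
        )
        annotations = pathway_io.parse_hormone_annotations(_read(cfg.annotations_tsv))
        policy = CurrencyPolicy()
        if cfg.currency_file:
            ids = frozenset(
                ln.strip()
                for ln in _read(cfg.currency_file).splitlines()
                if ln.strip() and not ln.startswith("#")
            )
            policy = CurrencyPolicy(currency_ids=ids)
        summary["compounds"] = len(db.compounds)
        summary["reactions"] = len(db.reactions)
        summary["enzymes"] = len(db.enzymes)

        stage = "networks"
        gecn = build_gecn(db, policy)
        eapcn = build_eapcn(db, annotations, policy)
        for name, net in (("gecn", gecn), ("eapcn", eapcn)):
            with open(os.path.join(cfg.out_dir, f"{name}.graphml"), "w") as fh:
                fh.write(pathway_io.write_network(net, "graphml"))
            with open(os.path.join(cfg.out_dir, f"{name}.sif"), "w") as fh:
                fh.write(pathway_io.write_network(net, "sif"))
        stats = network_summary(eapcn)
        hormones = eapcn.nodes_of_kind("hormone")
        summary["hormone_nodes"] = len(hormones)
        summary["eapcn_edges"] = stats.edge_count
        summary["connected_pairs"] = stats.connected_pairs
        pairwise = {}
        for i, h1 in enumerate(hormones):
            for h2 in hormones[i + 1 :]:
                pairwise[f"{h1}|{h2}"] = len(shared_crosstalk_enzymes(eapcn, h1, h2))
        summary["shared_enzymes_by_hormone_pair"] = pairwise

        stage = "centrality"
        enzyme_nodes = eapcn.nodes_of_kind("enzyme")
        enzyme_graph = eapcn.graph.subgraph(enzyme_nodes).copy()
        params = CentralityParams(
            epc_realizations=cfg.epc_realizations, epc_seed=cfg.seed + 101
        )
        table = compute_centrality_table(enzyme_graph, params)
        with open(os.path.join(cfg.out_dir, "centrality.tsv"), "w") as fh:
            fh.write(_header(cfg, "centrality"))
            fh.write(table.to_csv(sep="\t"))
        hubs = rank_and_select_hubs(table, k=cfg.hub_k, m=cfg.hub_m) if len(table) else []
        summary["hub_count"] = len(hubs)

        stage = "clustering"
        cparams = ClusterParams(
            penalty=cfg.cluster_penalty,
            min_size=cfg.cluster_min_size,
            min_density=cfg.cluster_min_density,
        )
        clusters = detect_clusters(enzyme_graph, cparams)
        with open(os.path.join(cfg.out_dir, "clusters.tsv"), "w") as fh:
            fh.write(_header(cfg, "clustering"))
            fh.write("members\tcohesiveness\tdensity\n")
            for cl in clusters:
                fh.write(f"{'|'.join(cl.sorted_members())}\t{cl.cohesiveness:.6f}\t{cl.density:.6f}\n")
        summary["cluster_count"] = len(clusters)

        stage = "routes"
        route_set = hubs if hubs else enzyme_nodes
        coupling = build_coupling_graph(db, route_set, policy)
        routes = extract_routes(coupling)
        with open(os.path.join(cfg.out_dir, "routes.tsv"), "w") as fh:
            fh.write(_header(cfg, "routes"))
            fh.write("steps\tlinks\n")
            for r in routes:
                fh.write(f"{'|'.join(r.steps)}\t{'|'.join(r.links)}\n")
        summary["route_count"] = len(routes)
        summary["max_route_steps"] = max((len(r) for r in routes), default=0)

        best_route = max(routes, key=len) if routes else None

        stage = "tf_circuits"
        units = []
        if cfg.regulation_tsv:
            regulation = pathway_io.parse_regulation_table(_read(cfg.regulation_tsv))
            enzyme_genes = {g for e in db.enzymes.values() for g in e.gene_ids}
            tf_net = build_cotarget_network(regulation, target_filter=enzyme_genes)
            cycles = enumerate_cycles(tf_net, max_len=cfg.cycle_max_len)
            units = assemble_units(cycles, tf_net, enzyme_genes)
            ppi = (
                pathway_io.parse_ppi_table(_read(cfg.ppi_tsv)) if cfg.ppi_tsv else []
            )
            with open(os.path.join(cfg.out_dir, "tf_units.tsv"), "w") as fh:
                fh.write(_header(cfg, "tf_circuits"))
                fh.write("members\tn_cycles\tregulated_enzyme_genes\tppi_route\n")
                for unit in units:
                    route = find_ppi_route(unit, ppi) if ppi else []
                    fh.write(
                        f"{'|'.join(sorted(unit.members))}\t{len(unit.cycles)}\t"
                        f"{'|'.join(sorted(unit.regulated_enzyme_genes))}\t{'|'.join(route)}\n"
                    )
            summary["tf_cycles"] = len(cycles)
            summary["control_units"] = len(units)

        stage = "evidence"
        if cfg.expressed_txt and best_route is not None:
            evidence = pathway_io.parse_expression_lists(
                _read(cfg.expressed_txt),
                _read(cfg.proteins_txt) if cfg.proteins_txt else "",
                context="pipeline",
            )
            regulation = (
                pathway_io.parse_regulation_table(_read(cfg.regulation_tsv))
                if cfg.regulation_tsv
                else []
            )
            report = annotate_evidence(best_route, db, regulation, evidence, annotations)
            with open(os.path.join(cfg.out_dir, "evidence.tsv"), "w") as fh:
                fh.write(_header(cfg, "evidence"))
                fh.write("step\tec\texpressed\tprotein\ttfs\tcrosstalk\n")
                for row in report:
                    fh.write(
                        f"{row.step}\t{row.ec}\t{'|'.join(sorted(row.expressed_gene_ids))}\t"
                        f"{'|'.join(sorted(row.protein_supported_gene_ids))}\t"
                        f"{'|'.join(sorted(row.expressed_regulating_tfs))}\t"
                        f"{'|'.join(row.crosstalk)}\n"
                    )
            cov = coverage_summary(report)
            summary["steps_with_transcript"] = cov.steps_with_transcript
            summary["fraction_transcript"] = round(cov.fraction_transcript, 6)
            summary["fraction_protein"] = round(cov.fraction_protein, 6)
            if len(db.enzymes) > len(best_route.steps):
                summary["permutation_p"] = permutation_support(
                    best_route, db, evidence, n_perm=cfg.n_perm, seed=cfg.seed + 202
                )
    except Exception as exc:  # noqa: BLE001 - stage context then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(cfg.out_dir, "summary.yaml"), "w") as fh:
        fh.write(_header(cfg, "summary"))
        yaml.safe_dump(summary, fh, sort_keys=True)
    return summary
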