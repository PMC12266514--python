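"""Factorial pipeline orchestration.

Runs the full comparison: pseudo-bulk creation x zero handling x gene
selection x inference algorithm x similarity metric x time-point
modeling, followed by network analysis, enrichment, differential
analysis, optional PPI intermediate-gene analysis, and the
meta-comparison of the resulting term sets.  Every artifact is written
under an output directory and recorded in a manifest JSON with its full
provenance tuple.

Grid validity rules (inapplicable cells are never expanded):

* zero handling applies only to the ``leiden`` and ``time`` pseudo-bulk
  methods; ``seacell`` aggregates its own values (zero_mode "n/a");
* ARACNE and CLR consume mutual information only; WGCNA accepts
  pearson, spearman, or mi;
* the consensus network is assembled from all algorithm x metric
  networks of the same (pseudo-bulk, selection, modeling) input.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from . import differential as diff_mod
from . import meta_comparison as meta
from .enrichment import EnrichmentResult, RankedGeneList, preranked_gsea, \
    hypergeometric_ora, read_gmt
from .gene_selection import select_genes
from .ig_analysis import ig_enrich, shortest_path_intermediates
from .network_analysis import CentralityTable, detect_communities, \
    network_size_metrics, node_centralities
from .network_inference import CoexpressionNetwork, NetworkProvenance, \
    assemble_time_point_inputs, consensus_network, infer_network
from .pseudobulk import make_pseudobulks
from .synthetic_data import ExpressionStudy, GeneSetCollection, ModuleSpec, \
    PPINetwork, SyntheticConfig, generate_expression_study, generate_gene_sets, \
    generate_ppi_network

__all__ = ["RunConfig", "run_comparison", "default_synthetic_study"]

logger = logging.getLogger(__name__)

VALID_PSEUDOBULK = ("leiden", "time", "seacell")
VALID_ZERO_MODES = ("ignore_zeros", "with_zeros", "n/a")
VALID_SELECTIONS = ("var", "sum", "deg")
VALID_ALGORITHMS = ("aracne", "clr", "wgcna")
VALID_METRICS = ("pearson", "spearman", "mi")
VALID_MODELINGS = ("combined", "single")
VALID_ANALYSES = ("gsea_deg", "gsea_bet", "gsea_cc", "community",
                  "differential_terms", "differential_centrality", "ig")

_CENTRALITY_OF = {"gsea_deg": "degree", "gsea_bet": "betweenness",
                  "gsea_cc": "closeness"}


@dataclass
class RunConfig:
    """Factorial grid and inputs of one comparison run."""

    out_dir: str = "coexnet_run"
    dataset: str = "synthetic"
    study_dir: str | None = None          # MTX directory; None -> synthetic
    gene_sets: str | None = None          # GMT path; None -> from planted truth
    ppi: str | None = None                # edge-list TSV; None -> synthetic if possible
    literature_counts: str | None = None  # term\tcount TSV

    pseudobulk_methods: tuple[str, ...] = ("time",)
    zero_modes: tuple[str, ...] = ("ignore_zeros",)
    gene_selections: tuple[str, ...] = ("var",)
    ks: tuple[int, ...] = (500,)
    algorithms: tuple[str, ...] = ("aracne", "clr", "wgcna")
    metrics: tuple[str, ...] = ("mi",)
    modelings: tuple[str, ...] = ("combined", "single")
    analyses: tuple[str, ...] = ("gsea_deg", "gsea_bet", "gsea_cc", "community",
                                 "differential_terms", "differential_centrality")
    consensus: bool = True

    seed: int = 0
    n_perm: int = 500
    n_extra_gene_sets: int = 30
    min_community_size: int = 5
    force: bool = False

    def __post_init__(self) -> None:
        self.pseudobulk_methods = tuple(self.pseudobulk_methods)
        self.zero_modes = tuple(self.zero_modes)
        self.gene_selections = tuple(self.gene_selections)
        self.ks = tuple(int(k) for k in self.ks)
        self.algorithms = tuple(self.algorithms)
        self.metrics = tuple(self.metrics)
        self.modelings = tuple(self.modelings)
        self.analyses = tuple(self.analyses)
        self.validate()

    # ------------------------------------------------------------ validity
    def validate(self) -> None:
        for name, values, valid in (
            ("pseudobulk_methods", self.pseudobulk_methods, VALID_PSEUDOBULK),
            ("zero_modes", self.zero_modes, VALID_ZERO_MODES),
            ("gene_selections", self.gene_selections, VALID_SELECTIONS),
            ("algorithms", self.algorithms, VALID_ALGORITHMS),
            ("metrics", self.metrics, VALID_METRICS),
            ("modelings", self.modelings, VALID_MODELINGS),
            ("analyses", self.analyses, VALID_ANALYSES),
        ):
            bad = [v for v in values if v not in valid]
            if bad:
                raise ValueError(f"invalid {name}: {bad}; valid: {valid}")
            if not values:
                raise ValueError(f"{name} must not be empty")
        # every requested element must occur in at least one valid grid cell
        for method in self.pseudobulk_methods:
            if method == "seacell":
                continue  # seacell always runs with zero_mode "n/a"
            if not any(self._zero_mode_valid(method, z) for z in self.zero_modes):
                raise ValueError(
                    f"grid cell invalid: pseudobulk method {method!r} with "
                    f"zero modes {self.zero_modes} (zero handling applies only "
                    "to leiden and time)")
        for zm in self.zero_modes:
            if not any(self._zero_mode_valid(m, zm) for m in self.pseudobulk_methods):
                raise ValueError(
                    f"grid cell invalid: zero mode {zm!r} with pseudobulk "
                    f"methods {self.pseudobulk_methods}")
        for algo in self.algorithms:
            if not any(self._metric_valid(algo, m) for m in self.metrics):
                raise ValueError(
                    f"grid cell invalid: algorithm {algo!r} with metrics "
                    f"{self.metrics} (ARACNE/CLR require mutual information)")

    @staticmethod
    def _zero_mode_valid(method: str, zero_mode: str) -> bool:
        if method in ("leiden", "time"):
            return zero_mode in ("ignore_zeros", "with_zeros")
        return zero_mode == "n/a"

    @staticmethod
    def _metric_valid(algorithm: str, metric: str) -> bool:
        if algorithm in ("aracne", "clr"):
            return metric == "mi"
        return metric in VALID_METRICS

    def pseudobulk_cells(self) -> Iterator[tuple[str, str]]:
        for method in self.pseudobulk_methods:
            if method == "seacell":
                yield method, "n/a"
                continue
            for zm in self.zero_modes:
                if self._zero_mode_valid(method, zm):
                    yield method, zm

    def algorithm_cells(self) -> Iterator[tuple[str, str]]:
        for algo in self.algorithms:
            for metric in self.metrics:
                if self._metric_valid(algo, metric):
                    yield algo, metric

    # ----------------------------------------------------------------- io
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def default_synthetic_study(seed: int = 0,
                            n_cells: int = 2000,
                            n_genes: int = 1500,
                            n_timepoints: int = 3) -> ExpressionStudy:
    """The default desk-scale synthetic study used when no data is supplied.

    Three planted modules of 30 genes at target correlation 0.9: one
    active at all time points, one active only at the last time point,
    one active at the first two; mild dropout and depth variation.
    """
    size = 30
    all_tp = tuple(range(n_timepoints))
    modules = (
        ModuleSpec(tuple(range(0, size)), all_tp, 0.9),
        ModuleSpec(tuple(range(size, 2 * size)), (n_timepoints - 1,), 0.9),
        ModuleSpec(tuple(range(2 * size, 3 * size)), all_tp[:-1], 0.9),
    )
    config = SyntheticConfig(
        n_cells=n_cells, n_genes=n_genes, n_timepoints=n_timepoints,
        modules=modules, dropout_rate=0.3, depth_dispersion=0.3, seed=seed)
    return generate_expression_study(config)


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------


def _stage_logger(out_dir: Path):
    log_path = out_dir / "run_log.jsonl"

    def log(stage: str, **info) -> None:
        entry = {"stage": stage, "time": time.time(), **info}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")
        logger.info("%s %s", stage, info)

    return log


def run_comparison(config: RunConfig) -> dict:
    """Execute the full factorial comparison; returns the manifest.

    Resumable: if the output directory already holds a manifest whose
    artifacts all exist and ``config.force`` is false, the stored
    manifest is returned without recomputation.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not config.force:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        if all((out_dir / e["path"]).exists() for e in manifest["artifacts"]):
            logger.info("existing complete manifest found; skipping recomputation")
            return manifest
    log = _stage_logger(out_dir)

    # ------------------------------------------------------------- inputs
    t0 = time.time()
    if config.study_dir is not None:
        study = ExpressionStudy.read_mtx(config.study_dir)
    else:
        study = default_synthetic_study(seed=config.seed)
    if config.gene_sets is not None:
        gene_sets = read_gmt(config.gene_sets)
    elif study.truth is not None:
        gene_sets = generate_gene_sets(
            study, n_extra=config.n_extra_gene_sets, seed=config.seed)
    else:
        raise ValueError("gene_sets must be supplied for non-synthetic studies")
    ppi: PPINetwork | None = None
    if "ig" in config.analyses:
        if config.ppi is not None:
            ppi = PPINetwork.read_tsv(config.ppi)
        elif study.truth is not None and study.truth.modules:
            ppi = generate_ppi_network(study, planted_paths=5,
                                       seed=config.seed)
        else:
            raise ValueError("ig analysis requires a PPI network file")
    log("inputs", n_cells=study.n_cells, n_genes=study.n_genes,
        n_gene_sets=len(gene_sets), elapsed=time.time() - t0)

    artifacts: list[dict] = []
    assignments: list[meta.TermAssignment] = []
    n_networks = {"combined": 0, "single": 0}

    def record(path: Path, kind: str, provenance: dict) -> None:
        artifacts.append({"path": str(path.relative_to(out_dir)),
                          "kind": kind, "provenance": provenance})

    def safe(name: str) -> str:
        return name.replace("/", "-").replace(":", "-")

    def add_assignment(result: EnrichmentResult, prov: NetworkProvenance,
                       analysis: str, positive_only: bool = False,
                       terms: frozenset[str] | None = None) -> None:
        params = {**prov.as_dict(), "analysis": analysis}
        if terms is None:
            terms = frozenset(result.significant_terms(positive_only=positive_only))
        rid = f"{prov.tag()}__{analysis}"
        assignments.append(meta.TermAssignment(rid, params, terms))

    # ------------------------------------------------ factorial main loop
    for pb_method, zero_mode in config.pseudobulk_cells():
        t_pb = time.time()
        pb = make_pseudobulks(study, method=pb_method,  # type: ignore[arg-type]
                              zero_mode=zero_mode if zero_mode != "n/a"
                              else "ignore_zeros",
                              seed=config.seed)
        pb_tag = f"{pb_method}_{safe(zero_mode)}"
        pb_path = out_dir / f"pseudobulk__{pb_tag}.tsv"
        pb.write_tsv(pb_path)
        record(pb_path, "pseudobulk", {"pseudobulk_method": pb_method,
                                       "zero_mode": zero_mode})
        log("pseudobulk", method=pb_method, zero_mode=zero_mode,
            n_pseudobulks=pb.n_pseudobulks, elapsed=time.time() - t_pb)

        for sel_strategy, k in product(config.gene_selections, config.ks):
            selection = select_genes(pb, sel_strategy, k)  # type: ignore[arg-type]
            sel_tag = f"{sel_strategy}{k}"
            sel_path = out_dir / f"genes__{pb_tag}__{sel_tag}.txt"
            selection.write(sel_path)
            record(sel_path, "gene_selection",
                   {"pseudobulk_method": pb_method, "zero_mode": zero_mode,
                    "gene_selection": sel_tag})

            for modeling in config.modelings:
                inputs = assemble_time_point_inputs(pb, modeling)  # type: ignore[arg-type]
                single_tables: dict[str, dict[str, CentralityTable]] = {}
                single_gsea: dict[str, dict[str, EnrichmentResult]] = {}

                for label, sub_pb in inputs:
                    model_tag = "combined" if modeling == "combined" else f"single:{label}"
                    base_prov = NetworkProvenance(
                        dataset=config.dataset, modeling=model_tag,
                        pseudobulk_method=pb_method, zero_mode=zero_mode,
                        gene_selection=sel_tag)
                    nets: list[CoexpressionNetwork] = []
                    for algo, metric in config.algorithm_cells():
                        t_net = time.time()
                        net = infer_network(sub_pb, selection, algo,
                                            metric=metric, seed=config.seed,
                                            provenance=base_prov)
                        nets.append(net)
                        _write_network(net, out_dir, record, log,
                                       time.time() - t_net)
                        n_networks[modeling] += 1
                    if config.consensus and len(nets) >= 2:
                        cons = consensus_network(nets, provenance=base_prov)
                        nets.append(cons)
                        _write_network(cons, out_dir, record, log, 0.0)
                        n_networks[modeling] += 1

                    for net in nets:
                        _analyze_network(
                            net, gene_sets, config, out_dir, record, log,
                            add_assignment, single_tables, single_gsea, label)

                if modeling == "single" and len(inputs) >= 2:
                    _differential_analyses(
                        config, gene_sets, single_tables, single_gsea,
                        out_dir, record, log, add_assignment)

    # ------------------------------------------------------- IG analysis
    if ppi is not None:
        t_ig = time.time()
        seeds = _ig_seeds(study, config)
        ig_result = shortest_path_intermediates(ppi, seeds, max_len=3)
        background = set(ppi.nodes)
        enr = ig_enrich(ig_result, background, gene_sets)
        ig_path = out_dir / "ig_enrichment.tsv"
        enr.write_tsv(ig_path)
        prov = NetworkProvenance(dataset=config.dataset, modeling="n/a",
                                 algorithm="ig")
        record(ig_path, "enrichment", {**prov.as_dict(), "analysis": "ig"})
        add_assignment(enr, prov, "ig")
        log("ig", n_seeds=len(seeds), n_intermediates=len(ig_result.frequencies),
            elapsed=time.time() - t_ig)

    # --------------------------------------------------- meta-comparison
    meta_out: dict = {}
    if len(assignments) >= 2:
        t_meta = time.time()
        assign_path = out_dir / "assignments.jsonl"
        meta.write_assignments(assignments, assign_path)
        record(assign_path, "assignments", {})
        dist = meta.jaccard_distance_matrix(assignments)
        labels = meta.cluster_similarity_graph(dist, seed=config.seed)
        enrichments = meta.parameter_overrepresentation(labels, assignments)
        cluster_path = out_dir / "parameter_enrichment.tsv"
        frames = []
        for ce in enrichments:
            sub = ce.table.copy()
            sub.insert(0, "cluster", ce.cluster_id)
            frames.append(sub)
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(cluster_path, sep="\t",
                                                    index=False)
        record(cluster_path, "parameter_enrichment", {})
        meta_out = {"n_assignments": len(assignments),
                    "n_clusters": int(labels.max()) + 1}
        if config.literature_counts is not None:
            counts = meta.read_literature_counts(config.literature_counts)
            all_terms = set(gene_sets.sets)
            lit_rows = []
            for a in assignments:
                score = meta.literature_score_test(a, all_terms, counts)
                lit_rows.append({"result_id": a.result_id, "t": score.t,
                                 "p": score.p, "testable": score.testable})
            lit_path = out_dir / "literature_scores.tsv"
            pd.DataFrame(lit_rows).to_csv(lit_path, sep="\t", index=False)
            record(lit_path, "literature_scores", {})
        log("meta_comparison", **meta_out, elapsed=time.time() - t_meta)

    manifest = {
        "dataset": config.dataset,
        "seed": config.seed,
        "n_networks": n_networks,
        "n_assignments": len(assignments),
        "meta": meta_out,
        "artifacts": artifacts,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _write_network(net: CoexpressionNetwork, out_dir: Path, record, log,
                   elapsed: float) -> None:
    tag = net.provenance.tag()
    path = out_dir / f"network__{tag}.tsv"
    net.write_tsv(path)
    record(path, "network", net.provenance.as_dict())
    record(path.with_suffix(path.suffix + ".provenance.json"),
           "network_provenance", net.provenance.as_dict())
    size = network_size_metrics(net) if net.n_nodes >= 2 else None
    log("network", tag=tag, n_edges=net.n_edges,
        density=getattr(size, "density", None), elapsed=elapsed)


def _analyze_network(net, gene_sets, config, out_dir, record, log,
                     add_assignment, single_tables, single_gsea, label) -> None:
    prov = net.provenance
    tag = prov.tag()
    wants_centrality = any(a in config.analyses for a in _CENTRALITY_OF) or \
        "differential_centrality" in config.analyses or \
        "differential_terms" in config.analyses
    table = None
    if wants_centrality and net.n_nodes >= 2:
        table = node_centralities(net)
        cent_path = out_dir / f"centrality__{tag}.tsv"
        table.write_tsv(cent_path)
        record(cent_path, "centrality", prov.as_dict())
        if prov.modeling.startswith("single:"):
            single_tables.setdefault(tag_without_time(prov), {})[label] = table

    for analysis, metric in _CENTRALITY_OF.items():
        if analysis not in config.analyses or table is None:
            continue
        ranking = RankedGeneList(list(table.table.index),
                                 table.ranking(metric).to_numpy())
        enr = preranked_gsea(ranking, gene_sets, n_perm=config.n_perm,
                             seed=config.seed)
        enr.provenance = {**prov.as_dict(), "analysis": analysis}
        enr_path = out_dir / f"enrichment__{tag}__{analysis}.tsv"
        enr.write_tsv(enr_path)
        record(enr_path, "enrichment", enr.provenance)
        add_assignment(enr, prov, analysis)
        if prov.modeling.startswith("single:") and analysis == "gsea_deg":
            single_gsea.setdefault(tag_without_time(prov), {})[label] = enr

    if "community" in config.analyses and net.n_edges > 0:
        partition = detect_communities(net, seed=config.seed)
        part_path = out_dir / f"communities__{tag}.tsv"
        partition.write_tsv(part_path)
        record(part_path, "communities", prov.as_dict())
        background = set(net.genes)
        sig_terms: set[str] = set()
        for cid, members in sorted(partition.communities(
                min_size=config.min_community_size).items()):
            enr = hypergeometric_ora(members, background, gene_sets)
            sig_terms |= enr.significant_terms()
        add_assignment(EnrichmentResult(), prov, "community",
                       terms=frozenset(sig_terms))


def tag_without_time(prov: NetworkProvenance) -> str:
    return replace(prov, modeling="single").tag()


def _differential_analyses(config, gene_sets, single_tables, single_gsea,
                           out_dir, record, log, add_assignment) -> None:
    if "differential_terms" in config.analyses:
        for family, per_tp in single_gsea.items():
            if len(per_tp) < 2:
                continue
            unique = diff_mod.differential_terms(per_tp)
            for tp, terms in unique.items():
                prov_dict = None
                # reconstruct provenance from one member result
                base = per_tp[tp].provenance
                prov = NetworkProvenance(**{k: base[k] for k in (
                    "dataset", "modeling", "pseudobulk_method", "zero_mode",
                    "gene_selection", "algorithm", "metric")})
                add_assignment(EnrichmentResult(), prov, "differential_terms",
                               terms=frozenset(terms))
    if "differential_centrality" in config.analyses:
        for family, per_tp in single_tables.items():
            if len(per_tp) < 2:
                continue
            try:
                changes = diff_mod.centrality_rank_change(per_tp, metric="degree")
            except ValueError as exc:
                log("differential_centrality_skipped", family=family,
                    reason=str(exc))
                continue
            enr = diff_mod.differential_centrality_gsea(
                changes, gene_sets, n_perm=config.n_perm, seed=config.seed)
            first = next(iter(per_tp.values()))
            prov = replace(first.provenance, modeling="single")
            enr_path = out_dir / f"differential_centrality__{prov.tag()}.tsv"
            enr.write_tsv(enr_path)
            record(enr_path, "enrichment",
                   {**prov.as_dict(), "analysis": "differential_centrality"})
            add_assignment(enr, prov, "differential_centrality",
                           positive_only=True)


def _ig_seeds(study: ExpressionStudy, config: RunConfig,
              n_seeds: int = 30) -> set[str]:
    """Seed genes for IG: the most differential genes across time points."""
    pb = make_pseudobulks(study, method="time", zero_mode="ignore_zeros",
                          seed=config.seed)
    selection = select_genes(pb, "deg", n_seeds)
    return set(selection.genes)
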