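"""Benchmark scenarios with planted ground truth.

These functions define the package's reference study conditions for
validating recovery of planted structure end-to-end: expression studies
with known co-expression modules are generated, pushed through
pseudo-bulking, gene selection, network inference and the downstream
analyses, and the result is scored against the generating truth.  The
scenario parameters were calibrated once by Monte-Carlo before being
frozen (see docs/methods.md for the reasoning behind each choice).
"""

from __future__ import annotations

import warnings

import numpy as np

from .differential import centrality_rank_change, differential_centrality_gsea
from .gene_selection import select_top_variable
from .meta_comparison import (TermAssignment, cluster_similarity_graph,
                              jaccard_distance_matrix,
                              parameter_overrepresentation)
from .network_analysis import detect_communities, node_centralities
from .network_inference import (aracne_network, assemble_time_point_inputs,
                                clr_network, compute_similarity, wgcna_network)
from .pseudobulk import make_pseudobulks
from .synthetic_data import (ExpressionStudy, ModuleSpec, SyntheticConfig,
                             generate_expression_study, generate_gene_sets)

__all__ = [
    "edge_placement_fractions",
    "community_recovery_ari",
    "differential_centrality_recovery",
    "planted_driver_flagged",
    "null_parameter_flag_fraction",
]


def _module_map(study: ExpressionStudy) -> dict[str, int]:
    mod_of: dict[str, int] = {}
    for k, mod in enumerate(study.truth.modules):
        for g in mod.genes:
            mod_of[study.gene_ids[g]] = k
    return mod_of


def _recovery_study(seed: int, module_sizes: tuple[int, ...],
                    module_mean: float = 80.0) -> ExpressionStudy:
    """2000 cells, 1500 genes, 4 time points; balanced always-active
    modules at target correlation 0.9 driven by per-cell latent factors."""
    start = 0
    modules = []
    for size in module_sizes:
        modules.append(ModuleSpec(tuple(range(start, start + size)),
                                  (0, 1, 2, 3), 0.9, down_fraction=0.5,
                                  substates=True))
        start += size
    config = SyntheticConfig(
        n_cells=2000, n_genes=1500, n_timepoints=4, modules=tuple(modules),
        dropout_rate=0.05, seed=seed, activation_strength=0.0,
        timepoint_drift=0.0, module_mean=module_mean)
    return generate_expression_study(config)


def edge_placement_fractions(seed: int) -> dict[str, float]:
    """Fraction of each algorithm's edges inside a planted module.

    Two balanced 60-gene modules at correlation 0.9, 2000 cells, paper-
    default time-sampled pseudo-bulks (10 groups of 100 cells per time
    point), top-120 variable genes, every algorithm at its defaults.
    """
    study = _recovery_study(seed, (60, 60))
    mod_of = _module_map(study)
    pb = make_pseudobulks(study, "time", "ignore_zeros", seed=seed)
    selection = select_top_variable(pb, 120)
    sim_mi = compute_similarity(pb, selection, "mi")
    sim_pe = compute_similarity(pb, selection, "pearson")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        networks = {
            "aracne": aracne_network(sim_mi, pb=pb, seed=seed),
            "clr": clr_network(sim_mi),
            "wgcna": wgcna_network(sim_pe),
        }
    out = {}
    for name, net in networks.items():
        within = sum(
            1 for (a, b) in net.edges
            if a in mod_of and b in mod_of and mod_of[a] == mod_of[b])
        out[name] = within / net.n_edges if net.n_edges else 0.0
    return out


def community_recovery_ari(seed: int) -> float:
    """Adjusted Rand index of Louvain communities vs planted membership.

    Three balanced modules (40 genes each) at correlation 0.9; communities
    are detected on the CLR network over the top-120 variable genes.
    """
    from sklearn.metrics import adjusted_rand_score

    study = _recovery_study(seed, (40, 40, 40))
    mod_of = _module_map(study)
    pb = make_pseudobulks(study, "time", "ignore_zeros", seed=seed)
    selection = select_top_variable(pb, 120)
    net = clr_network(compute_similarity(pb, selection, "mi"))
    partition = detect_communities(net, seed=seed)
    genes = [g for g in selection.genes if g in mod_of]
    truth = [mod_of[g] for g in genes]
    predicted = [partition.membership[g] for g in genes]
    return float(adjusted_rand_score(truth, predicted))


def differential_centrality_recovery(seed: int, n_perm: int = 1000) -> bool:
    """One run of the time-restricted-module recovery scenario.

    Two time points; three always-active reference modules (20/30/40
    genes, giving the degree ranking a stable backbone) plus one 30-gene
    module active only at the second time point.  Single-time-point CLR
    networks are built from 30 sampled groups per time point, degree
    dense-rank changes are enriched, and the run counts as a success when
    the planted module's term lands in the positive significant tail.
    """
    sizes = (20, 30, 40)
    modules = []
    start = 0
    for size in sizes:
        modules.append(ModuleSpec(tuple(range(start, start + size)), (0, 1),
                                  0.9, down_fraction=0.5, substates=True))
        start += size
    modules.append(ModuleSpec(tuple(range(start, start + 30)), (1,), 0.9,
                              down_fraction=0.5, substates=True))
    config = SyntheticConfig(
        n_cells=2000, n_genes=1500, n_timepoints=2, modules=tuple(modules),
        dropout_rate=0.05, seed=seed, activation_strength=0.0,
        timepoint_drift=0.0, module_mean=50.0)
    study = generate_expression_study(config)
    gene_sets = generate_gene_sets(study, n_extra=20, seed=seed)
    pb = make_pseudobulks(study, "time", "ignore_zeros", seed=seed,
                          n_clusters=30)
    selection = select_top_variable(pb, 120)
    tables = {}
    for tp, sub in assemble_time_point_inputs(pb, "single"):
        net = clr_network(compute_similarity(sub, selection, "mi"))
        tables[tp] = node_centralities(net)
    changes = centrality_rank_change(tables, "degree")
    result = differential_centrality_gsea(changes, gene_sets, n_perm=n_perm,
                                          seed=seed)
    table = result.table.set_index("term")
    target = "MODULE_4"  # the time-restricted module
    return bool(target in table.index
                and table.loc[target, "q"] < 0.05
                and table.loc[target, "statistic"] > 0)


_DRIVER_CATEGORIES = {
    "algorithm": ["aracne", "clr", "wgcna"],
    "metric": ["pearson", "spearman", "mi"],
    "pseudobulk_method": ["leiden", "time", "seacell"],
    "gene_selection": ["var500", "sum500", "deg500"],
}
_TERM_UNIVERSE = [f"T{i:03d}" for i in range(200)]


def _synthetic_assignments(rng: np.random.Generator,
                           planted: bool) -> list[TermAssignment]:
    """48 result objects with random parameter annotations.

    When ``planted``, every object with algorithm=aracne shares (up to
    10% per-term noise) one 30-term signature set, so that parameter
    value determines the term set; otherwise all term sets are random.
    """
    signature = set(rng.choice(_TERM_UNIVERSE, 30, replace=False))
    assignments = []
    for i in range(48):
        params = {cat: str(rng.choice(vals))
                  for cat, vals in _DRIVER_CATEGORIES.items()}
        if planted and params["algorithm"] == "aracne":
            terms = {t for t in signature if rng.random() > 0.1}
        else:
            terms = set(rng.choice(_TERM_UNIVERSE, 25, replace=False))
        assignments.append(TermAssignment(f"r{i}", params, frozenset(terms)))
    return assignments


def planted_driver_flagged(seed: int) -> bool:
    """Does parameter over-representation flag the planted driver value?"""
    rng = np.random.default_rng(seed)
    assignments = _synthetic_assignments(rng, planted=True)
    labels = cluster_similarity_graph(jaccard_distance_matrix(assignments),
                                      seed=seed)
    for ce in parameter_overrepresentation(labels, assignments,
                                           categories=list(_DRIVER_CATEGORIES)):
        tab = ce.table
        if len(tab[(tab.category == "algorithm") & (tab.value == "aracne")
                   & tab.significant]):
            return True
    return False


def null_parameter_flag_fraction(seed: int) -> float:
    """Fraction of (category, value, cluster) triples flagged under the null."""
    rng = np.random.default_rng(seed)
    assignments = _synthetic_assignments(rng, planted=False)
    labels = cluster_similarity_graph(jaccard_distance_matrix(assignments),
                                      seed=seed)
    n_sig = n_total = 0
    for ce in parameter_overrepresentation(labels, assignments,
                                           categories=list(_DRIVER_CATEGORIES)):
        n_sig += int(ce.table.significant.sum())
        n_total += len(ce.table)
    return n_sig / n_total if n_total else 0.0
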