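"""Synthetic time-resolved single-cell expression studies with planted structure.

Every downstream stage of the package (pseudo-bulking, gene selection,
network inference, enrichment, meta-comparison) is exercised on data whose
ground truth is known.  The generator plants co-expression modules — groups
of genes driven by a shared per-cell latent factor — that can be restricted
to a subset of time points, on top of independent negative-binomial
background expression with per-cell depth variation and dropout.  The
normalized output (counts per median depth, log1p) mimics the normalized
count matrices distributed by public single-cell expression atlases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ModuleSpec",
    "SyntheticConfig",
    "ExpressionStudy",
    "GeneSetCollection",
    "PPINetwork",
    "generate_expression_study",
    "generate_gene_sets",
    "generate_ppi_network",
]


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    Parameters
    ----------
    genes
        Gene indices (into the study's gene range) that belong to the module.
    active_timepoints
        Time-point indices (0-based) during which the shared latent factor
        drives the module genes.  Outside these time points the genes behave
        like background.
    correlation
        Target within-module Pearson correlation of the normalized
        expression values at the cell level, in (0, 1].
    down_fraction
        Fraction of the module's genes that respond to the module
        activity with a negative loading (program switches them OFF
        while the rest switch ON).  Same-loading pairs correlate
        positively, opposite-loading pairs negatively; a balanced module
        (0.5) leaves the cell's library size nearly unchanged.
    substates
        If true, the per-cell latent is bimodal (two expression
        sub-states at +-1 with spread 0.3) instead of Gaussian: the
        program is ON in one subpopulation of cells and OFF in the
        other, the canonical bimodal structure of single-cell programs.
    """

    genes: tuple[int, ...]
    active_timepoints: tuple[int, ...]
    correlation: float
    down_fraction: float = 0.0
    substates: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.correlation <= 1:
            raise ValueError(f"correlation must be in (0, 1], got {self.correlation}")
        if not 0 <= self.down_fraction < 1:
            raise ValueError("down_fraction must be in [0, 1)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("module gene indices must be unique")


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of a synthetic expression study.

    Defaults describe a desk-scale study: 2000 cells, 1500 genes, three
    time points with equally many cells each.
    """

    n_cells: int = 2000
    n_genes: int = 1500
    n_timepoints: int = 3
    modules: tuple[ModuleSpec, ...] = ()
    dropout_rate: float = 0.0
    depth_dispersion: float = 0.3
    seed: int = 0
    # Negative-binomial shape (Poisson-gamma); smaller = more overdispersed.
    nb_dispersion: float = 10.0
    # Mean log-scale activation of a module while active, and the sd of
    # its per-time-point jitter around that mean: an active program is
    # switched ON (mean shift) with a level that drifts over the course.
    activation_strength: float = 1.0
    timepoint_drift: float = 0.5
    # Geometric-mean base expression of module genes.  Planted programs sit
    # above the background mean (3): co-expression is only estimable for
    # genes detected well enough that aggregation does not quantize them.
    module_mean: float = 10.0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if not 2 <= self.n_timepoints <= 4:
            raise ValueError("n_timepoints must be in [2, 4]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        seen: set[int] = set()
        for mod in self.modules:
            gset = set(mod.genes)
            if seen & gset:
                raise ValueError("module gene sets must be disjoint")
            seen |= gset
            if gset and (min(gset) < 0 or max(gset) >= self.n_genes):
                raise ValueError("module gene index out of gene range")
            for tp in mod.active_timepoints:
                if not 0 <= tp < self.n_timepoints:
                    raise ValueError(f"module active time point {tp} out of range")

    def timepoint_labels(self) -> list[str]:
        return [f"t{i + 1}" for i in range(self.n_timepoints)]


@dataclass
class ExpressionStudy:
    """A cells x genes normalized expression matrix with per-cell time labels."""

    matrix: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    time_labels: np.ndarray  # one categorical label per cell
    truth: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.time_labels = np.asarray(self.time_labels, dtype=object)
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_ids) != n_cells or len(self.time_labels) != n_cells:
            raise ValueError("cell annotation length does not match matrix")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene annotation length does not match matrix")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if np.any(self.matrix < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def timepoints(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.time_labels:
            seen.setdefault(lab)
        return sorted(seen)

    # ------------------------------------------------------------------ io
    def write_mtx(self, directory: str | Path) -> None:
        """Write matrix.mtx + cells.tsv + genes.tsv (+ truth.json if known)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(directory / "matrix.mtx"), sparse.csr_matrix(self.matrix))
        with open(directory / "cells.tsv", "w") as fh:
            fh.write("cell_id\ttime\n")
            for cid, lab in zip(self.cell_ids, self.time_labels):
                fh.write(f"{cid}\t{lab}\n")
        with open(directory / "genes.tsv", "w") as fh:
            fh.write("gene_id\n")
            for gid in self.gene_ids:
                fh.write(f"{gid}\n")
        if self.truth is not None:
            with open(directory / "truth.json", "w") as fh:
                json.dump(_config_to_json(self.truth), fh, indent=1)

    def write_tsv(self, path: str | Path) -> None:
        """Dense TSV alternative: cells x genes with a time column."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("cell_id\ttime\t" + "\t".join(self.gene_ids) + "\n")
            for i, (cid, lab) in enumerate(zip(self.cell_ids, self.time_labels)):
                row = "\t".join(f"{v:.6g}" for v in self.matrix[i])
                fh.write(f"{cid}\t{lab}\t{row}\n")

    @classmethod
    def read_mtx(cls, directory: str | Path) -> "ExpressionStudy":
        directory = Path(directory)
        matrix = np.asarray(spio.mmread(str(directory / "matrix.mtx")).todense())
        cell_ids, labels = [], []
        with open(directory / "cells.tsv") as fh:
            next(fh)
            for line in fh:
                cid, lab = line.rstrip("\n").split("\t")
                cell_ids.append(cid)
                labels.append(lab)
        with open(directory / "genes.tsv") as fh:
            next(fh)
            gene_ids = [line.strip() for line in fh if line.strip()]
        truth = None
        truth_path = directory / "truth.json"
        if truth_path.exists():
            with open(truth_path) as fh:
                truth = _config_from_json(json.load(fh))
        return cls(matrix, cell_ids, gene_ids, np.array(labels, dtype=object), truth)


def _config_to_json(config: SyntheticConfig) -> dict:
    return {
        "n_cells": config.n_cells,
        "n_genes": config.n_genes,
        "n_timepoints": config.n_timepoints,
        "dropout_rate": config.dropout_rate,
        "depth_dispersion": config.depth_dispersion,
        "nb_dispersion": config.nb_dispersion,
        "activation_strength": config.activation_strength,
        "timepoint_drift": config.timepoint_drift,
        "module_mean": config.module_mean,
        "seed": config.seed,
        "modules": [
            {
                "genes": list(m.genes),
                "active_timepoints": list(m.active_timepoints),
                "correlation": m.correlation,
                "down_fraction": m.down_fraction,
                "substates": m.substates,
            }
            for m in config.modules
        ],
    }


def _config_from_json(payload: dict) -> SyntheticConfig:
    modules = tuple(
        ModuleSpec(tuple(m["genes"]), tuple(m["active_timepoints"]),
                   m["correlation"], m.get("down_fraction", 0.0),
                   m.get("substates", False))
        for m in payload.pop("modules", [])
    )
    return SyntheticConfig(modules=modules, **payload)


# --------------------------------------------------------------------------
# Expression study generation
# --------------------------------------------------------------------------

#: Residual log-scale noise of a well-expressed gene after normalization;
#: maps a target within-module correlation onto the latent-factor strength.
#: Fixed once by Monte-Carlo calibration of the generator (docs/methods.md).
_LOG_NOISE_SD = 0.5


def _factor_strength(correlation: float) -> float:
    """Latent-factor log-scale sd needed to reach a target Pearson r.

    With a shared factor of sd `a` and independent residual noise of sd
    `s`, two module genes correlate at roughly a^2 / (a^2 + s^2); invert.
    The count noise floor makes the realized cell-level correlation
    saturate below very high targets (see docs/methods.md).
    """
    if correlation >= 1.0:
        return 6.0  # effectively noise-free on the log scale
    return _LOG_NOISE_SD * float(np.sqrt(correlation / (1.0 - correlation)))


def generate_expression_study(config: SyntheticConfig) -> ExpressionStudy:
    """Draw a normalized expression study from a :class:`SyntheticConfig`.

    Counts are Poisson-gamma (negative binomial).  For each module, cells
    in the module's active time points carry a shared latent activity

    ``a * z_c + m_t``

    on the log-rate scale, where ``z_c`` is a per-cell standard-normal
    latent factor scaled so that two module genes reach roughly the
    target cell-level correlation (mean-normalized, so the factor changes
    correlation but not the time-point mean), and ``m_t`` is the module's
    activity level at time point ``t``, drawn once per module per time
    point around ``activation_strength`` with sd ``timepoint_drift``:
    an active program is switched ON with a level that drifts over the
    differentiation course.  Outside its active time
    points a module gene behaves like background.  Module genes draw
    their base expression around ``module_mean`` instead of the
    background mean.  After dropout, each cell is scaled to the median
    library size and log1p-transformed.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes = config.n_cells, config.n_genes

    # Cells are split evenly over time points, in label order.
    labels_idx = np.repeat(np.arange(config.n_timepoints),
                           -(-n_cells // config.n_timepoints))[:n_cells]
    tp_names = config.timepoint_labels()
    time_labels = np.array([tp_names[i] for i in labels_idx], dtype=object)

    base_mean = rng.lognormal(mean=np.log(3.0), sigma=0.6, size=n_genes)
    depth = rng.lognormal(mean=0.0, sigma=config.depth_dispersion, size=n_cells)

    log_rate = np.log(base_mean)[None, :] + np.log(depth)[:, None]
    for mod in config.modules:
        a = _factor_strength(mod.correlation)
        gene_idx = list(mod.genes)
        mod_base = rng.lognormal(np.log(config.module_mean), 0.3, len(gene_idx))
        log_rate[:, gene_idx] = np.log(mod_base)[None, :] + np.log(depth)[:, None]
        if mod.substates:
            z = rng.choice([-1.0, 1.0], size=n_cells) \
                + 0.3 * rng.standard_normal(n_cells)
        else:
            z = rng.standard_normal(n_cells)
        levels = rng.normal(config.activation_strength, config.timepoint_drift,
                            size=config.n_timepoints)
        active = np.isin(labels_idx, mod.active_timepoints)
        activity = np.where(active, a * z + levels[labels_idx], 0.0)
        n_down = int(round(mod.down_fraction * len(gene_idx)))
        loadings = np.ones(len(gene_idx))
        loadings[:n_down] = -1.0  # first genes (sorted order) switch OFF
        # log E[exp(+-a z)], exact for either latent, so the factor is
        # mean-neutral and only the activation level moves the mean
        if mod.substates:
            log_norm = np.log(np.cosh(a)) + (0.3 * a) ** 2 / 2.0
        else:
            log_norm = a * a / 2.0
        centering = np.where(active, log_norm, 0.0)
        log_rate[:, gene_idx] += (activity[:, None] * loadings[None, :]
                                  - centering[:, None])

    rate = np.exp(log_rate)
    theta = config.nb_dispersion
    gamma_noise = rng.gamma(shape=theta, scale=1.0 / theta, size=rate.shape)
    counts = rng.poisson(rate * gamma_noise).astype(float)

    if config.dropout_rate > 0:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts *= keep

    totals = counts.sum(axis=1)
    med = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    scale = np.divide(med, totals, out=np.zeros_like(totals), where=totals > 0)
    normalized = np.log1p(counts * scale[:, None])

    digits = len(str(max(n_cells - 1, 1)))
    cell_ids = [f"cell{str(i).zfill(digits)}" for i in range(n_cells)]
    gene_ids = [f"G{str(i).zfill(len(str(max(n_genes - 1, 1))))}" for i in range(n_genes)]
    return ExpressionStudy(normalized, cell_ids, gene_ids, time_labels, truth=config)


# --------------------------------------------------------------------------
# Gene sets
# --------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named collection of term id -> (term name, gene-id set), as in a GMT."""

    name: str
    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term, (desc, genes) in self.sets.items():
                fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def generate_gene_sets(study: ExpressionStudy, n_extra: int, seed: int = 0) -> GeneSetCollection:
    """One gene set per planted module plus `n_extra` random decoy sets.

    Module sets carry the exact planted membership, so enrichment of a
    recovered module against this collection has a known best hit.  Decoy
    sets draw 10-200 genes uniformly from the study's gene universe.
    """
    if study.truth is None:
        raise ValueError("study has no generating truth; cannot derive module sets")
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i, mod in enumerate(study.truth.modules):
        members = frozenset(study.gene_ids[g] for g in mod.genes)
        sets[f"MODULE_{i + 1}"] = (f"planted module {i + 1}", members)
    for j in range(n_extra):
        size = int(rng.integers(10, 201))
        size = min(size, study.n_genes)
        picks = rng.choice(study.n_genes, size=size, replace=False)
        members = frozenset(study.gene_ids[g] for g in picks)
        sets[f"RANDOM_{j + 1}"] = (f"random set {j + 1}", members)
    return GeneSetCollection(name="synthetic", sets=sets)


# --------------------------------------------------------------------------
# PPI network
# --------------------------------------------------------------------------


@dataclass
class PPINetwork:
    """Simple undirected protein/gene interaction graph as an edge set."""

    nodes: list[str]
    edges: set[frozenset[str]]
    truth: dict | None = None  # {"paths": [(seedA, intermediate, seedB), ...]}

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("edges must join two distinct nodes")
            if not e <= node_set:
                raise ValueError("edge endpoint outside node set")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.edges):
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PPINetwork":
        edges: set[frozenset[str]] = set()
        nodes: dict[str, None] = {}
        with open(path) as fh:
            header = fh.readline()
            if "\t" in header and not header.lower().startswith("protein"):
                a, b = header.rstrip("\n").split("\t")[:2]
                nodes.setdefault(a), nodes.setdefault(b)
                if a != b:
                    edges.add(frozenset((a, b)))
            for line in fh:
                if not line.strip():
                    continue
                a, b = line.rstrip("\n").split("\t")[:2]
                nodes.setdefault(a), nodes.setdefault(b)
                if a != b:
                    edges.add(frozenset((a, b)))
        return cls(list(nodes), edges)


def generate_ppi_network(
    study: ExpressionStudy,
    planted_paths: int,
    mean_degree: float = 4.0,
    seed: int = 0,
) -> PPINetwork:
    """Random PPI graph over the study's genes with planted length-2 paths.

    Each planted path joins a seed gene from one planted module to a seed
    gene of another (or the same) module through an intermediate gene that
    belongs to no module; the triples are recorded in ``truth["paths"]``.
    """
    if planted_paths < 0:
        raise ValueError("planted_paths must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(study.gene_ids)
    n = len(genes)
    edges: set[frozenset[str]] = set()
    if mean_degree > 0 and n > 1:
        p = min(1.0, mean_degree / (n - 1))
        # vectorized Erdos-Renyi over the upper triangle
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < p
        for i, j in zip(iu[mask], ju[mask]):
            edges.add(frozenset((genes[i], genes[j])))

    paths: list[tuple[str, str, str]] = []
    if planted_paths > 0:
        if study.truth is None or not study.truth.modules:
            raise ValueError("planted paths require a study with planted modules")
        module_genes = [list(m.genes) for m in study.truth.modules]
        in_module = set(g for m in module_genes for g in m)
        free = [i for i in range(n) if i not in in_module]
        if len(free) < planted_paths:
            raise ValueError("not enough non-module genes for planted intermediates")
        intermediates = rng.choice(len(free), size=planted_paths, replace=False)
        for k in range(planted_paths):
            m_a = module_genes[int(rng.integers(len(module_genes)))]
            m_b = module_genes[int(rng.integers(len(module_genes)))]
            sa = genes[m_a[int(rng.integers(len(m_a)))]]
            sb_candidates = [g for g in m_b if genes[g] != sa]
            sb = genes[sb_candidates[int(rng.integers(len(sb_candidates)))]]
            mid = genes[free[int(intermediates[k])]]
            edges.add(frozenset((sa, mid)))
            edges.add(frozenset((mid, sb)))
            # the planted pair must not be short-circuited by a direct edge
            edges.discard(frozenset((sa, sb)))
            paths.append((sa, mid, sb))
    truth = {"paths": paths} if planted_paths > 0 else None
    return PPINetwork(genes, edges, truth=truth)
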