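"""Gene-gene co-expression network (GGCN) inference from pseudo-bulk matrices.

Three classical bulk algorithms are provided, each consuming a pairwise
similarity matrix over the selected genes:

* **ARACNE** — mutual-information network pruned first by a permutation
  null threshold and second by the Data Processing Inequality (DPI): for
  every connected gene triplet, the weakest of the three edges is removed,
  since the inequality I(n1,n3) <= min[I(n1,n2); I(n2,n3)] makes it the
  most likely indirect interaction.
* **CLR** — context likelihood of relatedness: each pair's mutual
  information is z-scored against both genes' background MI distributions
  and the two (non-negative) z-scores are combined quadratically.
* **WGCNA-style** — unsigned soft-threshold adjacency |s|^beta with beta
  chosen for approximate scale-free topology, pruned at a quantile of the
  adjacency distribution.

A consensus network retains edges supported by more than a given fraction
of input networks.  External single-cell-specific estimators (e.g.
cell-type-aware co-expression methods) can be plugged in through the
backend registry without being re-implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Literal

import numpy as np
from scipy import stats

from .pseudobulk import PseudoBulkMatrix

__all__ = [
    "Metric",
    "SimilarityMatrix",
    "NetworkProvenance",
    "CoexpressionNetwork",
    "compute_similarity",
    "assemble_time_point_inputs",
    "aracne_network",
    "clr_network",
    "wgcna_network",
    "consensus_network",
    "infer_network",
    "register_backend",
    "get_backend",
]

Metric = Literal["pearson", "spearman", "mi"]


# --------------------------------------------------------------------------
# Data types
# --------------------------------------------------------------------------


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise gene similarity (correlation or mutual information)."""

    genes: list[str]
    values: np.ndarray
    metric: Metric

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match gene list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if self.metric == "mi" and np.any(self.values[~np.eye(n, dtype=bool)] < -1e-12):
            raise ValueError("mutual information must be non-negative")


@dataclass(frozen=True)
class NetworkProvenance:
    """The full parameter tuple that produced a network."""

    dataset: str = "n/a"
    modeling: str = "combined"  # "combined" or "single:<timepoint>"
    pseudobulk_method: str = "n/a"
    zero_mode: str = "n/a"
    gene_selection: str = "n/a"
    algorithm: str = "n/a"
    metric: str = "n/a"

    def as_dict(self) -> dict[str, str]:
        return {
            "dataset": self.dataset,
            "modeling": self.modeling,
            "pseudobulk_method": self.pseudobulk_method,
            "zero_mode": self.zero_mode,
            "gene_selection": self.gene_selection,
            "algorithm": self.algorithm,
            "metric": self.metric,
        }

    def tag(self) -> str:
        return "__".join(
            v.replace(":", "-").replace("/", "-") for v in self.as_dict().values()
        )


@dataclass
class CoexpressionNetwork:
    """Undirected weighted gene graph plus its creation provenance."""

    genes: list[str]
    edges: dict[tuple[str, str], float]
    provenance: NetworkProvenance = field(default_factory=NetworkProvenance)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        normalized: dict[tuple[str, str], float] = {}
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError("self-loops are not allowed")
            if a not in gene_set or b not in gene_set:
                raise ValueError(f"edge endpoint not in gene list: {(a, b)}")
            if not np.isfinite(w):
                raise ValueError(f"non-finite edge weight on {(a, b)}")
            key = (a, b) if a < b else (b, a)
            if key in normalized and normalized[key] != w:
                raise ValueError(f"duplicate edge with conflicting weight: {key}")
            normalized[key] = float(w)
        self.edges = normalized

    @property
    def n_nodes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) if a < b else (b, a)) in self.edges

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def write_tsv(self, path: str | Path) -> None:
        """3-column edge list (gene_a, gene_b, weight) + provenance sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            for (a, b) in sorted(self.edges):
                fh.write(f"{a}\t{b}\t{self.edges[(a, b)]:.8g}\n")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        with open(sidecar, "w") as fh:
            json.dump({"genes": self.genes, **self.provenance.as_dict()}, fh, indent=1)


# --------------------------------------------------------------------------
# Similarity computation
# --------------------------------------------------------------------------


def _equal_frequency_bins(matrix: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-gene equal-frequency discretization.

    Ties are broken by a per-gene deterministic random order: breaking
    them by sample order instead would impose the same positional
    pattern on every heavily tied gene (pseudo-bulk medians sit on a
    coarse lattice) and fabricate mutual information between unrelated
    genes.
    """
    n_samples = matrix.shape[0]
    order_ranks = np.empty_like(matrix, dtype=int)
    for j in range(matrix.shape[1]):
        jitter = np.random.default_rng(j).random(n_samples)
        order = np.lexsort((jitter, matrix[:, j]))
        ranks = np.empty(n_samples, dtype=int)
        ranks[order] = np.arange(n_samples)
        order_ranks[:, j] = ranks
    return (order_ranks * n_bins) // n_samples


def _mi_from_bins(bins: np.ndarray, n_bins: int, block: int = 128) -> np.ndarray:
    """Pairwise plug-in mutual information (log2) from discretized columns."""
    n_samples, n_genes = bins.shape
    # one-hot indicators: (genes * bins, samples)
    ind = np.zeros((n_genes, n_bins, n_samples))
    for b in range(n_bins):
        ind[:, b, :] = (bins.T == b)
    flat = ind.reshape(n_genes * n_bins, n_samples)
    marg = flat.sum(axis=1).reshape(n_genes, n_bins)  # per-gene bin counts

    mi = np.zeros((n_genes, n_genes))
    for start in range(0, n_genes, block):
        stop = min(start + block, n_genes)
        chunk = flat[start * n_bins: stop * n_bins]          # (cb, samples)
        joint = chunk @ flat.T                                # (cb, genes*bins)
        joint = joint.reshape(stop - start, n_bins, n_genes, n_bins)
        # MI_ij = sum_{b1,b2} (c/n) log2(c*n / (m_i[b1] * m_j[b2]))
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = marg[start:stop, :, None, None] * marg[None, None, :, :]
            # denom shape: (chunk, bins, genes, bins)
            ratio = joint * n_samples / denom
            terms = np.where(joint > 0, joint / n_samples * np.log2(ratio), 0.0)
        mi[start:stop] = terms.sum(axis=(1, 3))
    mi = (mi + mi.T) / 2.0  # exact symmetry despite float summation order
    np.fill_diagonal(mi, 0.0)
    return np.maximum(mi, 0.0)


def compute_similarity(
    pb: PseudoBulkMatrix,
    genes: Iterable[str] | None = None,
    metric: Metric = "pearson",
    n_bins: int | None = None,
) -> SimilarityMatrix:
    """Pairwise similarity over the selected genes.

    Pearson/Spearman correlations are set to 0 for pairs involving a
    constant gene.  Mutual information uses equal-frequency binning with
    ``B = max(2, floor(sqrt(n_samples)))`` bins by default and the plug-in
    estimate in bits.
    """
    from .gene_selection import GeneSelection

    if isinstance(genes, GeneSelection):
        gene_list = list(genes.genes)
    elif genes is None:
        gene_list = list(pb.gene_ids)
    else:
        gene_list = list(genes)
    data = pb.gene_matrix(gene_list)
    n_samples = data.shape[0]
    if n_samples < 3:
        raise ValueError("need at least 3 pseudobulks for similarity estimation")

    if metric in ("pearson", "spearman"):
        values = data if metric == "pearson" else stats.rankdata(data, axis=0)
        sd = values.std(axis=0)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant gene(s); their correlations set to 0",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(values.T)
        corr = np.nan_to_num(corr, nan=0.0)
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
        np.fill_diagonal(corr, 1.0)
        corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
        return SimilarityMatrix(gene_list, corr, metric)

    if metric == "mi":
        if n_bins is None:
            n_bins = max(2, int(np.floor(np.sqrt(n_samples))))
        bins = _equal_frequency_bins(data, n_bins)
        return SimilarityMatrix(gene_list, _mi_from_bins(bins, n_bins), "mi")

    raise ValueError(f"unknown metric {metric!r}")


def assemble_time_point_inputs(
    pb: PseudoBulkMatrix,
    modeling: Literal["combined", "single"],
    min_pseudobulks: int = 3,
) -> list[tuple[str, PseudoBulkMatrix]]:
    """Split a pseudo-bulk matrix into network-inference inputs.

    ``combined`` yields a single entry holding all pseudo-bulks;
    ``single`` yields one entry per time label.  Labels with fewer than
    ``min_pseudobulks`` pseudo-bulks are skipped with a warning.
    """
    if modeling == "combined":
        return [("combined", pb)]
    if modeling != "single":
        raise ValueError(f"unknown modeling {modeling!r}")
    out: list[tuple[str, PseudoBulkMatrix]] = []
    for tp in pb.timepoints():
        mask = pb.time_labels == tp
        if mask.sum() < min_pseudobulks:
            warnings.warn(
                f"time point {tp!r} has {int(mask.sum())} pseudobulks "
                f"(< {min_pseudobulks}); skipped", stacklevel=2)
            continue
        sub = PseudoBulkMatrix(
            pb.matrix[mask],
            [pid for pid, m in zip(pb.pseudobulk_ids, mask) if m],
            list(pb.gene_ids),
            pb.time_labels[mask],
            method=pb.method,
            zero_mode=pb.zero_mode,
        )
        out.append((tp, sub))
    return out


# --------------------------------------------------------------------------
# ARACNE
# --------------------------------------------------------------------------


def _binned_mi_pair(x_bins: np.ndarray, y_bins: np.ndarray, n_bins: int) -> float:
    n = x_bins.size
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (x_bins, y_bins), 1.0)
    mx, my = joint.sum(axis=1), joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint * n / np.outer(mx, my)
        terms = np.where(joint > 0, joint / n * np.log2(ratio), 0.0)
    return float(terms.sum())


def mi_permutation_threshold(
    pb: PseudoBulkMatrix,
    genes: list[str],
    alpha: float = 0.05,
    n_null: int = 100,
    n_bins: int | None = None,
    seed: int = 0,
) -> float:
    """(1 - alpha) quantile of a pooled permutation-null MI distribution.

    Each draw permutes the sample labels of one randomly chosen gene and
    measures its MI against another randomly chosen gene, destroying any
    dependence while preserving the marginals.
    """
    rng = np.random.default_rng(seed)
    data = pb.gene_matrix(genes)
    n_samples = data.shape[0]
    if n_bins is None:
        n_bins = max(2, int(np.floor(np.sqrt(n_samples))))
    bins = _equal_frequency_bins(data, n_bins)
    null = np.empty(n_null)
    n_genes = len(genes)
    for t in range(n_null):
        i, j = rng.choice(n_genes, size=2, replace=False)
        perm = rng.permutation(n_samples)
        null[t] = _binned_mi_pair(bins[perm, i], bins[:, j], n_bins)
    return float(np.quantile(null, 1.0 - alpha))


def dpi_prune(
    edges: dict[tuple[str, str], float],
    genes: list[str],
    tolerance: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Data Processing Inequality pruning of an MI edge set.

    For every triplet forming a triangle in the *input* edge set, the
    weakest edge is marked for removal when its weight is below
    ``min(other two) * (1 - tolerance)``.  Marking against the pre-prune
    edge set makes the result independent of scan order and idempotent.
    """
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    adj = np.zeros((n, n))
    present = np.zeros((n, n), dtype=bool)
    for (a, b), w in edges.items():
        i, j = index[a], index[b]
        adj[i, j] = adj[j, i] = w
        present[i, j] = present[j, i] = True

    to_remove: set[tuple[str, str]] = set()
    for (a, b), w_ab in edges.items():
        i, j = index[a], index[b]
        common = np.flatnonzero(present[i] & present[j])
        if common.size == 0:
            continue
        others = np.minimum(adj[i, common], adj[j, common])
        if np.any(w_ab < others * (1.0 - tolerance)):
            to_remove.add((a, b))
    return {e: w for e, w in edges.items() if e not in to_remove}


def aracne_network(
    sim: SimilarityMatrix,
    pb: PseudoBulkMatrix | None = None,
    alpha: float = 0.05,
    dpi_tolerance: float = 0.0,
    n_null: int = 100,
    seed: int = 0,
    threshold: float | None = None,
    provenance: NetworkProvenance | None = None,
) -> CoexpressionNetwork:
    """MI network with permutation-null thresholding and DPI pruning.

    Either supply the pseudo-bulk matrix (to estimate the null threshold
    by permutation) or pass an explicit ``threshold``.
    """
    if sim.metric != "mi":
        raise ValueError("ARACNE requires a mutual-information similarity matrix")
    if threshold is None:
        if pb is None:
            raise ValueError("need the pseudo-bulk matrix or an explicit threshold")
        threshold = mi_permutation_threshold(
            pb, sim.genes, alpha=alpha, n_null=n_null, seed=seed)

    n = len(sim.genes)
    iu, ju = np.triu_indices(n, k=1)
    keep = sim.values[iu, ju] > threshold
    edges = {
        (min(sim.genes[i], sim.genes[j]), max(sim.genes[i], sim.genes[j])):
        float(sim.values[i, j])
        for i, j in zip(iu[keep], ju[keep])
    }
    edges = dpi_prune(edges, sim.genes, tolerance=dpi_tolerance)
    prov = replace(provenance or NetworkProvenance(),
                   algorithm="aracne", metric=sim.metric)
    return CoexpressionNetwork(list(sim.genes), edges, prov)


# --------------------------------------------------------------------------
# CLR
# --------------------------------------------------------------------------


def clr_scores(values: np.ndarray) -> np.ndarray:
    """Background-corrected CLR scores from a symmetric MI matrix.

    z_i(j) = (I_ij - mean_i) / sd_i over row i excluding the diagonal;
    c_ij = sqrt(max(0, z_i(j))^2 + max(0, z_j(i))^2).  Genes with zero
    background sd contribute z = 0.
    """
    n = values.shape[0]
    off = ~np.eye(n, dtype=bool)
    row_mean = np.array([values[i, off[i]].mean() for i in range(n)])
    row_sd = np.array([values[i, off[i]].std() for i in range(n)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (values - row_mean[:, None]) / row_sd[:, None]
    z[row_sd == 0, :] = 0.0
    z = np.maximum(z, 0.0)
    scores = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(scores, 0.0)
    return scores


def clr_network(
    sim: SimilarityMatrix,
    z_cutoff: float = 2.0,
    provenance: NetworkProvenance | None = None,
) -> CoexpressionNetwork:
    """Context-likelihood-of-relatedness network at a combined z cutoff."""
    if sim.metric != "mi":
        raise ValueError("CLR requires a mutual-information similarity matrix")
    if len(sim.genes) < 3:
        raise ValueError("CLR needs at least 3 genes for a background")
    scores = clr_scores(sim.values)
    n = len(sim.genes)
    iu, ju = np.triu_indices(n, k=1)
    keep = scores[iu, ju] >= z_cutoff
    edges = {
        (min(sim.genes[i], sim.genes[j]), max(sim.genes[i], sim.genes[j])):
        float(scores[i, j])
        for i, j in zip(iu[keep], ju[keep])
    }
    prov = replace(provenance or NetworkProvenance(),
                   algorithm="clr", metric=sim.metric)
    return CoexpressionNetwork(list(sim.genes), edges, prov)


# --------------------------------------------------------------------------
# WGCNA-style soft thresholding
# --------------------------------------------------------------------------


def scale_free_fit(adjacency: np.ndarray, n_degree_bins: int = 10) -> float:
    """R^2 of the log-frequency vs log-connectivity regression.

    Connectivity k_i is the row sum of the (off-diagonal) adjacency;
    the k distribution is binned into ``n_degree_bins`` bins and the fit
    of log10(freq) against log10(mean k) per occupied bin is returned.
    """
    adj = adjacency.copy()
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_degree_bins + 1)
    which = np.digitize(k, edges) - 1
    log_k, log_f = [], []
    for b in range(n_degree_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(members.size / k.size))
    if len(log_k) < 3:
        return 0.0
    slope, intercept, r, _, _ = stats.linregress(log_k, log_f)
    return float(r ** 2)


def pick_soft_threshold(
    values: np.ndarray,
    powers: Iterable[int] = range(1, 21),
    r2_target: float = 0.8,
    default: int = 6,
) -> int:
    """Smallest power with scale-free fit R^2 >= target, else the default."""
    for beta in powers:
        if scale_free_fit(np.abs(values) ** beta) >= r2_target:
            return int(beta)
    return int(default)


def wgcna_network(
    sim: SimilarityMatrix,
    beta: int | Literal["auto"] = "auto",
    edge_quantile: float = 0.95,
    provenance: NetworkProvenance | None = None,
) -> CoexpressionNetwork:
    """Unsigned soft-threshold adjacency pruned at an adjacency quantile.

    a_ij = |s_ij|^beta, with MI similarities first rescaled to [0, 1] by
    their maximum.  Edges strictly above the ``edge_quantile`` of the
    off-diagonal adjacency values are kept with weight a_ij.
    """
    if not 0 <= edge_quantile < 1:
        raise ValueError("edge_quantile must be in [0, 1)")
    values = np.abs(sim.values.copy())
    np.fill_diagonal(values, 0.0)
    if sim.metric == "mi":
        vmax = values.max()
        if vmax > 0:
            values = values / vmax
    if values.max() == 0:
        warnings.warn("all similarities are 0; returning an empty network",
                      stacklevel=2)
        prov = replace(provenance or NetworkProvenance(),
                       algorithm="wgcna", metric=sim.metric)
        return CoexpressionNetwork(list(sim.genes), {}, prov)

    if beta == "auto":
        beta = pick_soft_threshold(values)
    adjacency = values ** beta
    n = len(sim.genes)
    iu, ju = np.triu_indices(n, k=1)
    upper = adjacency[iu, ju]
    # quantile 0 means "keep every nonzero adjacency"
    cutoff = (np.quantile(adjacency[~np.eye(n, dtype=bool)], edge_quantile)
              if edge_quantile > 0 else 0.0)
    keep = upper > cutoff
    edges = {
        (min(sim.genes[i], sim.genes[j]), max(sim.genes[i], sim.genes[j])):
        float(adjacency[i, j])
        for i, j in zip(iu[keep], ju[keep])
    }
    prov = replace(provenance or NetworkProvenance(),
                   algorithm="wgcna", metric=sim.metric)
    return CoexpressionNetwork(list(sim.genes), edges, prov)


# --------------------------------------------------------------------------
# Consensus and backends
# --------------------------------------------------------------------------


def consensus_network(
    networks: list[CoexpressionNetwork],
    min_fraction: float = 0.5,
    provenance: NetworkProvenance | None = None,
) -> CoexpressionNetwork:
    """Edges present in more than ``min_fraction`` of the input networks.

    Edge weight is the mean weight over the networks containing the edge.
    All inputs must share the same gene universe.
    """
    if len(networks) < 2:
        raise ValueError("consensus needs at least 2 networks")
    universe = set(networks[0].genes)
    for net in networks[1:]:
        if set(net.genes) != universe:
            raise ValueError("consensus inputs must share the same gene universe")
    counts: dict[tuple[str, str], list[float]] = {}
    for net in networks:
        for e, w in net.edges.items():
            counts.setdefault(e, []).append(w)
    m = len(networks)
    edges = {
        e: float(np.mean(ws)) for e, ws in counts.items() if len(ws) / m > min_fraction
    }
    base = provenance or networks[0].provenance
    prov = replace(base, algorithm="consensus", metric="n/a")
    return CoexpressionNetwork(list(networks[0].genes), edges, prov)


#: Pluggable backends for external co-expression estimators.  A backend is
#: a callable (data, **kwargs) -> CoexpressionNetwork, where data is an
#: ExpressionStudy (non-pseudo-bulk mode) or a PseudoBulkMatrix.
_BACKENDS: dict[str, Callable[..., CoexpressionNetwork]] = {}


def register_backend(name: str, fn: Callable[..., CoexpressionNetwork]) -> None:
    _BACKENDS[name] = fn


def get_backend(name: str) -> Callable[..., CoexpressionNetwork]:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"no backend {name!r} registered; available: {sorted(_BACKENDS)}"
        ) from None


def infer_network(
    pb: PseudoBulkMatrix,
    genes,
    algorithm: str,
    metric: Metric = "pearson",
    seed: int = 0,
    provenance: NetworkProvenance | None = None,
    **kwargs,
) -> CoexpressionNetwork:
    """Front end: similarity + one inference algorithm in one call."""
    if algorithm in ("aracne", "clr") and metric != "mi":
        raise ValueError(f"{algorithm} requires metric='mi'")
    sim = compute_similarity(pb, genes, metric=metric)
    if algorithm == "aracne":
        return aracne_network(sim, pb=pb, seed=seed, provenance=provenance, **kwargs)
    if algorithm == "clr":
        return clr_network(sim, provenance=provenance, **kwargs)
    if algorithm == "wgcna":
        return wgcna_network(sim, provenance=provenance, **kwargs)
    if algorithm in _BACKENDS:
        return _BACKENDS[algorithm](pb, genes=genes, metric=metric, seed=seed, **kwargs)
    raise ValueError(f"unknown algorithm {algorithm!r}")
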