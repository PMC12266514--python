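"""Pseudo-bulk creation: collapse single cells into bulk-like profiles.

Three grouping methods are supported, mirroring common practice for making
single-cell data palatable to bulk network-inference algorithms:

* ``leiden`` — graph-based clustering of cells (PCA -> kNN graph -> Leiden
  modularity optimization); each cluster becomes one pseudo-bulk labeled by
  its majority time point.
* ``time`` — per time point, a fixed number of random cell groups (cells
  may appear in several groups); each group becomes one pseudo-bulk
  carrying that time point's label.
* ``seacell`` — metacell-style aggregation: k-means in PCA space with one
  center per metacell, aggregated by per-gene mean.

For ``leiden`` and ``time`` groups, profiles are collapsed by the per-gene
median, either ignoring zeros (dropout treated as missing) or keeping them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .synthetic_data import ExpressionStudy

__all__ = [
    "CellAssignment",
    "PseudoBulkMatrix",
    "pseudobulk_by_clustering",
    "pseudobulk_by_time_sampling",
    "pseudobulk_metacell",
    "collapse_median",
    "make_pseudobulks",
]

ZeroMode = Literal["ignore_zeros", "with_zeros", "n/a"]


@dataclass
class CellAssignment:
    """Cell-group assignment: group id -> member cell indices, with labels.

    Groups may overlap (time sampling) and need not cover all cells.
    """

    groups: dict[str, np.ndarray]
    labels: dict[str, str]
    method: str

    def __post_init__(self) -> None:
        for gid in self.groups:
            if gid not in self.labels:
                raise ValueError(f"group {gid!r} has no time label")
            if len(self.groups[gid]) == 0:
                raise ValueError(f"group {gid!r} is empty")


@dataclass
class PseudoBulkMatrix:
    """pseudobulks x genes summarized expression with creation provenance."""

    matrix: np.ndarray
    pseudobulk_ids: list[str]
    gene_ids: list[str]
    time_labels: np.ndarray
    method: Literal["leiden", "time", "seacell", "none"]
    zero_mode: ZeroMode

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.time_labels = np.asarray(self.time_labels, dtype=object)
        n, g = self.matrix.shape
        if len(self.pseudobulk_ids) != n or len(self.time_labels) != n:
            raise ValueError("pseudobulk annotations do not match matrix")
        if len(self.gene_ids) != g:
            raise ValueError("gene annotations do not match matrix")

    @property
    def n_pseudobulks(self) -> int:
        return self.matrix.shape[0]

    def timepoints(self) -> list[str]:
        return sorted(set(self.time_labels))

    def gene_matrix(self, genes: Sequence[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in genes]
        return self.matrix[:, cols]

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("pseudobulk_id\ttime\t" + "\t".join(self.gene_ids) + "\n")
            for i, (pid, lab) in enumerate(zip(self.pseudobulk_ids, self.time_labels)):
                row = "\t".join(f"{v:.6g}" for v in self.matrix[i])
                fh.write(f"{pid}\t{lab}\t{row}\n")

    @classmethod
    def read_tsv(cls, path: str | Path,
                 method: str = "none", zero_mode: ZeroMode = "n/a") -> "PseudoBulkMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            gene_ids = header[2:]
            ids, labels, rows = [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                labels.append(parts[1])
                rows.append([float(x) for x in parts[2:]])
        return cls(np.array(rows), ids, gene_ids,
                   np.array(labels, dtype=object), method, zero_mode)  # type: ignore[arg-type]


def _majority_label(labels: Sequence[str]) -> str:
    """Most frequent label; ties broken by earliest label in sorted order."""
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    return min(lab for lab, c in counts.items() if c == best)


def _pca(matrix: np.ndarray, n_components: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    n_comp = min(n_components, matrix.shape[0] - 1, matrix.shape[1])
    n_comp = max(n_comp, 1)
    return PCA(n_components=n_comp, svd_solver="randomized",
               random_state=seed).fit_transform(matrix)


def pseudobulk_by_clustering(
    study: ExpressionStudy,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 30,
    n_neighbors: int = 15,
) -> CellAssignment:
    """Leiden clustering of cells on a kNN graph over principal components.

    Each cluster is labeled by the most frequent time point among its
    cells.  Deterministic given ``seed``.
    """
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    if study.n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    if study.n_cells <= n_neighbors:
        raise ValueError(
            f"n_neighbors={n_neighbors} requires more than {n_neighbors} cells")

    pcs = _pca(study.matrix, n_pcs, seed)
    knn = kneighbors_graph(pcs, n_neighbors=n_neighbors, mode="connectivity")
    knn = knn.maximum(knn.T).tocoo()  # symmetrize
    edges = [(int(i), int(j)) for i, j in zip(knn.row, knn.col) if i < j]
    graph = igraph.Graph(n=study.n_cells, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    groups: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for k, members in enumerate(part):
        gid = f"leiden{k}"
        idx = np.asarray(sorted(members), dtype=int)
        groups[gid] = idx
        labels[gid] = _majority_label([study.time_labels[i] for i in idx])
    return CellAssignment(groups, labels, method="leiden")


def pseudobulk_by_time_sampling(
    study: ExpressionStudy,
    n_clusters: int = 10,
    cluster_size: int = 100,
    seed: int = 0,
) -> CellAssignment:
    """Random cell groups per time point.

    For each time point, ``n_clusters`` groups of ``cluster_size`` cells are
    drawn; cells may belong to several groups.  Within one group, cells are
    drawn without replacement when the time point holds at least
    ``cluster_size`` cells, otherwise with replacement.  The RNG stream is
    split per time point so adding a time point does not perturb the others.
    """
    if n_clusters <= 0 or cluster_size <= 0:
        raise ValueError("n_clusters and cluster_size must be positive")
    groups: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    timepoints = study.timepoints()
    for t_idx, tp in enumerate(timepoints):
        cells = np.flatnonzero(study.time_labels == tp)
        if cells.size == 0:
            raise ValueError(f"time point {tp!r} has no cells")
        rng = np.random.default_rng([seed, t_idx])
        replace = cells.size < cluster_size
        for k in range(n_clusters):
            pick = rng.choice(cells, size=cluster_size, replace=replace)
            gid = f"time_{tp}_{k}"
            groups[gid] = np.sort(pick)
            labels[gid] = tp
    return CellAssignment(groups, labels, method="time")


def collapse_median(
    study: ExpressionStudy,
    assignment: CellAssignment,
    zero_mode: ZeroMode = "ignore_zeros",
) -> PseudoBulkMatrix:
    """Per-pseudobulk per-gene median over member cells.

    ``ignore_zeros`` drops zero entries before taking the median and
    returns 0 when a gene is zero in every member cell; ``with_zeros``
    keeps them.  Networks built from ``with_zeros`` pseudo-bulks are
    conventionally tagged "w0".
    """
    if zero_mode not in ("ignore_zeros", "with_zeros"):
        raise ValueError(f"invalid zero_mode {zero_mode!r}")
    gids = sorted(assignment.groups)
    out = np.zeros((len(gids), study.n_genes))
    for r, gid in enumerate(gids):
        sub = study.matrix[assignment.groups[gid], :]
        if zero_mode == "with_zeros":
            out[r] = np.median(sub, axis=0)
        else:
            masked = np.where(sub == 0, np.nan, sub)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
                med = np.nanmedian(masked, axis=0)
            out[r] = np.nan_to_num(med, nan=0.0)
    labels = np.array([assignment.labels[g] for g in gids], dtype=object)
    return PseudoBulkMatrix(out, gids, list(study.gene_ids), labels,
                            method=assignment.method,  # type: ignore[arg-type]
                            zero_mode=zero_mode)


def pseudobulk_metacell(
    study: ExpressionStudy,
    n_metacells: int,
    seed: int = 0,
    n_pcs: int = 30,
) -> PseudoBulkMatrix:
    """Metacell-style aggregation: k-means in PCA space, per-gene mean.

    This is a centroid-based stand-in for archetypal metacell algorithms:
    cells are grouped into ``n_metacells`` compact neighborhoods and each
    group's mean expression profile is returned, labeled by its majority
    time point.  Zero handling does not apply (``zero_mode = "n/a"``).
    """
    from sklearn.cluster import KMeans

    if n_metacells <= 0:
        raise ValueError("n_metacells must be positive")
    if n_metacells >= study.n_cells:
        raise ValueError("n_metacells must be smaller than the number of cells")
    pcs = _pca(study.matrix, n_pcs, seed)
    km = KMeans(n_clusters=n_metacells, n_init=10, random_state=seed).fit(pcs)
    rows, ids, labels = [], [], []
    for k in range(n_metacells):
        members = np.flatnonzero(km.labels_ == k)
        if members.size == 0:
            continue
        rows.append(study.matrix[members].mean(axis=0))
        ids.append(f"seacell{k}")
        labels.append(_majority_label([study.time_labels[i] for i in members]))
    return PseudoBulkMatrix(np.array(rows), ids, list(study.gene_ids),
                            np.array(labels, dtype=object),
                            method="seacell", zero_mode="n/a")


def make_pseudobulks(
    study: ExpressionStudy,
    method: Literal["leiden", "time", "seacell"],
    zero_mode: ZeroMode = "ignore_zeros",
    seed: int = 0,
    **kwargs,
) -> PseudoBulkMatrix:
    """One-call front end dispatching to the three creation methods."""
    if method == "leiden":
        assignment = pseudobulk_by_clustering(study, seed=seed, **kwargs)
        return collapse_median(study, assignment, zero_mode)
    if method == "time":
        assignment = pseudobulk_by_time_sampling(study, seed=seed, **kwargs)
        return collapse_median(study, assignment, zero_mode)
    if method == "seacell":
        n_metacells = kwargs.pop("n_metacells", max(2, study.n_cells // 75))
        return pseudobulk_metacell(study, n_metacells, seed=seed, **kwargs)
    raise ValueError(f"unknown pseudobulk method {method!r}")
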