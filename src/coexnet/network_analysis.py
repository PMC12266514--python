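"""Topological analysis of co-expression networks.

Centralities (degree, betweenness, closeness) are computed on the
unweighted topology so that networks whose edge-weight scales differ
(correlation vs mutual information vs z-scores) remain comparable; edge
weights enter only community detection.  Size metrics follow the standard
graph definitions: density d = 2m / n(n-1), transitivity
T = 3 * #triangles / #triads, and the average local clustering
coefficient (nodes of degree < 2 contribute 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network_inference import CoexpressionNetwork, NetworkProvenance

__all__ = [
    "CentralityTable",
    "NetworkSizeMetrics",
    "CommunityPartition",
    "node_centralities",
    "network_size_metrics",
    "detect_communities",
    "dense_rank_descending",
]

CENTRALITY_METRICS = ("degree", "betweenness", "closeness")


def dense_rank_descending(values: np.ndarray) -> np.ndarray:
    """Dense ranks, rank 1 for the largest value; ties share a rank."""
    return stats.rankdata(-np.asarray(values, dtype=float), method="dense")


@dataclass
class CentralityTable:
    """Per-gene centralities and their dense ranks for one network."""

    provenance: NetworkProvenance
    table: pd.DataFrame  # index: gene id; columns: metric and metric_rank

    def ranking(self, metric: str) -> pd.Series:
        """Centrality values (descending-rankable scores) for one metric."""
        if metric not in CENTRALITY_METRICS:
            raise ValueError(f"unknown centrality metric {metric!r}")
        return self.table[metric]

    def ranks(self, metric: str) -> pd.Series:
        return self.table[f"{metric}_rank"]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


@dataclass
class NetworkSizeMetrics:
    n_nodes: int
    n_edges: int
    density: float
    average_clustering: float
    transitivity: float


@dataclass
class CommunityPartition:
    """gene -> community id for one network."""

    provenance: NetworkProvenance
    membership: dict[str, int]
    resolution: float
    seed: int

    def communities(self, min_size: int = 1) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for gene, cid in self.membership.items():
            out.setdefault(cid, set()).add(gene)
        return {cid: genes for cid, genes in out.items() if len(genes) >= min_size}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tcommunity\n")
            for gene in sorted(self.membership):
                fh.write(f"{gene}\t{self.membership[gene]}\n")


def node_centralities(net: CoexpressionNetwork) -> CentralityTable:
    """Degree, betweenness and closeness centrality with dense ranks.

    Betweenness is normalized by the number of node pairs; closeness uses
    the improved formula that scales by the reachable component's size,
    so both lie in [0, 1] for disconnected graphs as well.
    """
    if net.n_nodes < 2:
        raise ValueError("centralities need at least 2 nodes")
    g = net.to_networkx()
    if net.n_edges == 0:
        deg = {v: 0.0 for v in g}
        bet = dict(deg)
        clo = dict(deg)
    else:
        deg = dict(g.degree())
        bet = nx.betweenness_centrality(g, normalized=True)
        clo = nx.closeness_centrality(g, wf_improved=True)
    genes = list(net.genes)
    table = pd.DataFrame(
        {
            "degree": [float(deg[v]) for v in genes],
            "betweenness": [bet[v] for v in genes],
            "closeness": [clo[v] for v in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    for metric in CENTRALITY_METRICS:
        table[f"{metric}_rank"] = dense_rank_descending(table[metric].to_numpy())
    return CentralityTable(net.provenance, table)


def network_size_metrics(net: CoexpressionNetwork) -> NetworkSizeMetrics:
    """Density, average clustering coefficient and transitivity."""
    if net.n_nodes < 2:
        raise ValueError("size metrics need at least 2 nodes")
    g = net.to_networkx()
    return NetworkSizeMetrics(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        density=nx.density(g),
        average_clustering=nx.average_clustering(g),
        transitivity=nx.transitivity(g),
    )


def detect_communities(
    net: CoexpressionNetwork,
    resolution: float = 1.0,
    seed: int = 0,
) -> CommunityPartition:
    """Weighted Louvain modularity communities; deterministic given seed."""
    g = net.to_networkx()
    if net.n_edges == 0:
        warnings.warn("edgeless network: every node is its own community",
                      stacklevel=2)
        membership = {v: i for i, v in enumerate(net.genes)}
        return CommunityPartition(net.provenance, membership, resolution, seed)
    parts = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed)
    # stable community ids: order by sorted first member
    parts = sorted(parts, key=lambda s: min(s))
    membership: dict[str, int] = {}
    for cid, members in enumerate(parts):
        for v in members:
            membership[v] = cid
    return CommunityPartition(net.provenance, membership, resolution, seed)
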