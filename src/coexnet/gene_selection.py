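"""Gene-universe reduction applied after pseudo-bulk creation.

Three strategies rank genes on the pseudo-bulk matrix:

* ``var`` — top-k most variable genes across all pseudo-bulks.
* ``sum`` — union over time points of each time point's top-k genes by
  summed expression (the union may exceed k).
* ``deg`` — most differentially expressed genes: for every pair of
  pseudo-bulk groups with different time labels, a two-sided Wilcoxon
  rank-sum test per gene, Benjamini-Hochberg adjusted within the pair;
  genes are ranked by the sum of adjusted p-values over all pairs,
  ascending, so consistently differential genes come first.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pseudobulk import PseudoBulkMatrix

__all__ = [
    "GeneSelection",
    "select_top_variable",
    "select_top_expressed_union",
    "select_top_differential",
    "select_genes",
]

Strategy = Literal["var", "sum", "deg"]


@dataclass
class GeneSelection:
    """An ordered list of selected gene ids with its creating strategy."""

    strategy: Strategy
    k: int
    genes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("selected genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(g + "\n")


def _rank_select(scores: dict[str, float], k: int, largest: bool) -> list[str]:
    # Sort by score then gene id for a deterministic tie-break.
    sign = -1.0 if largest else 1.0
    ordered = sorted(scores, key=lambda g: (sign * scores[g], g))
    return ordered[:k]


def select_top_variable(pb: PseudoBulkMatrix, k: int) -> GeneSelection:
    """Top-k genes by sample variance across pseudo-bulks (ddof=1)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if pb.n_pseudobulks < 2:
        raise ValueError("need at least 2 pseudobulks to compute variance")
    variances = pb.matrix.var(axis=0, ddof=1)
    scores = dict(zip(pb.gene_ids, variances))
    return GeneSelection("var", k, _rank_select(scores, k, largest=True))


def select_top_expressed_union(pb: PseudoBulkMatrix, k: int) -> GeneSelection:
    """Union over time points of the per-time-point top-k by summed expression."""
    if k <= 0:
        raise ValueError("k must be positive")
    union: set[str] = set()
    for tp in pb.timepoints():
        rows = pb.matrix[pb.time_labels == tp]
        sums = rows.sum(axis=0)
        scores = dict(zip(pb.gene_ids, sums))
        union |= set(_rank_select(scores, k, largest=True))
    genes = sorted(union)
    return GeneSelection("sum", k, genes)


def select_top_differential(pb: PseudoBulkMatrix, k: int) -> GeneSelection:
    """Top-k most differentially expressed genes across time points.

    Pairs of time-point groups are compared with a two-sided Wilcoxon
    rank-sum test per gene; p-values are BH-adjusted within each pair and
    summed per gene over all pairs.  Smaller sums rank first.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    timepoints = pb.timepoints()
    if len(timepoints) < 2:
        raise ValueError("need at least 2 distinct time labels")
    groups: dict[str, np.ndarray] = {}
    for tp in timepoints:
        rows = pb.matrix[pb.time_labels == tp]
        if rows.shape[0] < 2:
            raise ValueError(f"time label {tp!r} has fewer than 2 pseudobulks")
        groups[tp] = rows

    sums = np.zeros(len(pb.gene_ids))
    for ta, tb in combinations(timepoints, 2):
        stat_res = stats.ranksums(groups[ta], groups[tb], axis=0)
        pvals = np.nan_to_num(stat_res.pvalue, nan=1.0)
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        sums += adjusted
    scores = dict(zip(pb.gene_ids, sums))
    return GeneSelection("deg", k, _rank_select(scores, k, largest=False))


def select_genes(pb: PseudoBulkMatrix, strategy: Strategy, k: int) -> GeneSelection:
    """Dispatch to one of the three selection strategies."""
    if strategy == "var":
        return select_top_variable(pb, k)
    if strategy == "sum":
        return select_top_expressed_union(pb, k)
    if strategy == "deg":
        return select_top_differential(pb, k)
    raise ValueError(f"unknown selection strategy {strategy!r}")
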