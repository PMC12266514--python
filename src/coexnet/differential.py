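"""Differential comparison of single-time-point networks.

Two strategies compare networks built per time point under the same
creation strategy:

* differential term analysis — for each time point, the significant terms
  not significant at any other time point;
* differential centrality analysis — genes are ranked by the mean absolute
  change of their centrality dense rank across all unordered time-point
  pairs, and that ranking is enriched with preranked GSEA; the positive
  tail marks terms whose genes change network position over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, RankedGeneList, preranked_gsea
from .network_analysis import CentralityTable
from .synthetic_data import GeneSetCollection

__all__ = [
    "RankChangeTable",
    "differential_terms",
    "centrality_rank_change",
    "differential_centrality_gsea",
]


@dataclass
class RankChangeTable:
    """gene -> mean absolute dense-rank change for one centrality metric."""

    metric: str
    changes: pd.Series  # index: gene id

    def ranking(self) -> RankedGeneList:
        return RankedGeneList(list(self.changes.index), self.changes.to_numpy())


def differential_terms(
    results: Mapping[str, EnrichmentResult],
    positive_only: bool = False,
) -> dict[str, set[str]]:
    """Per time point, significant terms unique to that time point."""
    if len(results) < 2:
        raise ValueError("differential terms need at least 2 time points")
    sig = {tp: res.significant_terms(positive_only=positive_only)
           for tp, res in results.items()}
    out: dict[str, set[str]] = {}
    for tp, terms in sig.items():
        others: set[str] = set()
        for other_tp, other_terms in sig.items():
            if other_tp != tp:
                others |= other_terms
        out[tp] = terms - others
    return out


def centrality_rank_change(
    tables: Mapping[str, CentralityTable],
    metric: str = "degree",
    min_shared: int = 5,
) -> RankChangeTable:
    """Mean absolute dense-rank change per gene across time-point pairs.

    Only genes present in every compared network are retained; ranks are
    recomputed on that shared gene set so that set differences between
    networks do not leak into the change scores.
    """
    if len(tables) < 2:
        raise ValueError("rank change needs at least 2 time points")
    timepoints = sorted(tables)
    shared = set(tables[timepoints[0]].table.index)
    for tp in timepoints[1:]:
        shared &= set(tables[tp].table.index)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared across time points (< {min_shared})")
    genes = sorted(shared)
    from .network_analysis import dense_rank_descending

    ranks = {
        tp: dense_rank_descending(
            tables[tp].ranking(metric).loc[genes].to_numpy())
        for tp in timepoints
    }
    total = np.zeros(len(genes))
    n_pairs = 0
    for ta, tb in combinations(timepoints, 2):
        total += np.abs(ranks[ta].astype(float) - ranks[tb].astype(float))
        n_pairs += 1
    changes = pd.Series(total / n_pairs, index=pd.Index(genes, name="gene"))
    return RankChangeTable(metric=metric, changes=changes)


def differential_centrality_gsea(
    changes: RankChangeTable,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA on the mean rank-change scores.

    Terms in the positive-ES significant tail are the "differentially
    central" terms: their genes move in the centrality ranking between
    time points more than expected.
    """
    if np.all(changes.changes.to_numpy() == 0):
        warnings.warn("all rank changes are 0; degenerate ranking", stacklevel=2)
    result = preranked_gsea(changes.ranking(), sets, n_perm=n_perm, seed=seed)
    result.provenance = {"analysis": "differential_centrality",
                         "metric": changes.metric}
    return result
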