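"""Functional enrichment: preranked GSEA and hypergeometric over-representation.

Both strategies link gene-level results to flat term collections (GMT
files, e.g. Reactome pathways or GO biological processes):

* :func:`preranked_gsea` — weighted Kolmogorov-Smirnov enrichment score
  (weight exponent 1 on the absolute ranking score) with a permutation
  p-value from gene-label shuffles.
* :func:`hypergeometric_ora` — upper-tail hypergeometric test of overlap
  between a hit set and each term's gene set within a background universe.

Significance is called at Benjamini-Hochberg q < 0.05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import GeneSetCollection

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "read_gmt",
    "bh_adjust",
    "preranked_gsea",
    "hypergeometric_ora",
]

SIGNIFICANCE_Q = 0.05
MIN_OVERLAP = 3


@dataclass
class RankedGeneList:
    """Genes ordered by a score, descending; ties broken by gene id."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        order = sorted(range(len(self.genes)),
                       key=lambda i: (-self.scores[i], self.genes[i]))
        self.genes = [self.genes[i] for i in order]
        self.scores = self.scores[order]

    @classmethod
    def from_mapping(cls, scores: Mapping[str, float]) -> "RankedGeneList":
        genes = list(scores)
        return cls(genes, np.array([scores[g] for g in genes]))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Per-term statistic / p / q for one (network, strategy) combination."""

    provenance: dict = field(default_factory=dict)
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["term", "statistic", "p", "q", "significant"]))

    def significant_terms(self, positive_only: bool = False) -> set[str]:
        tab = self.table
        mask = tab["significant"].astype(bool)
        if positive_only:
            mask &= tab["statistic"] > 0
        return set(tab.loc[mask, "term"])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.table)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: term id, description, then member genes, tab-separated."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (term, description, genes...)")
            term, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            sets[term] = (desc, genes)
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(name=name or path.stem, sets=sets)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# Preranked GSEA
# --------------------------------------------------------------------------


def _es_at_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Signed enrichment score for each row of hit positions.

    ``positions`` is (n_rows, k) of 0-based positions in the ranked list
    (need not be sorted); ``weights`` is the per-position weight vector
    |score|^1.  The running-sum extremum with the larger magnitude is
    returned (positive on ties).
    """
    positions = np.sort(positions, axis=1)
    n_rows, k = positions.shape
    if k >= n:
        raise ValueError("gene set cannot cover the whole ranking")
    wv = weights[positions]                              # (rows, k)
    wsum = wv.sum(axis=1, keepdims=True)
    # all-zero weight rows fall back to the unweighted KS statistic
    zero = (wsum == 0).ravel()
    if zero.any():
        wv = wv.copy()
        wv[zero] = 1.0
        wsum = wv.sum(axis=1, keepdims=True)
    hit_cum = np.cumsum(wv, axis=1) / wsum
    idx = np.arange(1, k + 1)
    miss_unit = 1.0 / (n - k)
    peak = hit_cum - (positions + 1 - idx) * miss_unit
    hit_prev = np.concatenate(
        [np.zeros((n_rows, 1)), hit_cum[:, :-1]], axis=1)
    valley = hit_prev - (positions - (idx - 1)) * miss_unit
    best_peak = peak.max(axis=1)
    worst_valley = np.minimum(valley.min(axis=1), 0.0)
    return np.where(best_peak >= -worst_valley, best_peak, worst_valley)


def enrichment_score(ranking: RankedGeneList, gene_set: Iterable[str]) -> float:
    """Weighted KS enrichment score of one gene set against one ranking."""
    pos_index = {g: i for i, g in enumerate(ranking.genes)}
    positions = np.array(sorted(pos_index[g] for g in gene_set if g in pos_index))
    if positions.size == 0:
        raise ValueError("gene set does not overlap the ranking")
    weights = np.abs(ranking.scores)
    return float(_es_at_positions(positions[None, :], weights, len(ranking))[0])


def preranked_gsea(
    ranking: RankedGeneList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = MIN_OVERLAP,
) -> EnrichmentResult:
    """Preranked gene-set enrichment analysis.

    Terms are intersected with the ranking universe; sets overlapping in
    fewer than ``min_overlap`` genes are skipped.  The permutation
    p-value is two-sided on |ES| over ``n_perm`` gene-label shuffles
    (equivalently: random position sets of the same size), with the +1
    correction.  q-values are BH across the tested terms.
    """
    if len(ranking) < 10:
        raise ValueError("ranking must cover at least 10 genes")
    universe = set(ranking.genes)
    weights = np.abs(ranking.scores)
    n = len(ranking)
    pos_index = {g: i for i, g in enumerate(ranking.genes)}

    tested: list[tuple[str, np.ndarray]] = []
    for term in sorted(sets.sets):
        overlap = sets.genes(term) & universe
        if len(overlap) < min_overlap:
            continue
        tested.append((term, np.array(sorted(pos_index[g] for g in overlap))))
    if not tested:
        warnings.warn("no gene set overlaps the ranking; empty result",
                      stacklevel=2)
        return EnrichmentResult()

    rng = np.random.default_rng(seed)
    # share permutation draws between sets of equal size
    null_by_size: dict[int, np.ndarray] = {}
    rows = []
    for term, positions in tested:
        k = positions.size
        if k not in null_by_size:
            perm_pos = np.argsort(
                rng.random((n_perm, n)), axis=1)[:, :k]
            null_by_size[k] = np.abs(_es_at_positions(perm_pos, weights, n))
        es = float(_es_at_positions(positions[None, :], weights, n)[0])
        null_abs = null_by_size[k]
        p = (1.0 + np.sum(null_abs >= abs(es))) / (n_perm + 1.0)
        rows.append((term, es, p))

    table = pd.DataFrame(rows, columns=["term", "statistic", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < SIGNIFICANCE_Q
    return EnrichmentResult(table=table)


# --------------------------------------------------------------------------
# Hypergeometric over-representation
# --------------------------------------------------------------------------


def hypergeometric_ora(
    hits: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of each term against a hit set.

    For a term with K genes in the background of size N and n hits,
    p = P[X >= k] with k the observed overlap and
    X ~ Hypergeometric(N, K, n).  The statistic column reports the
    overlap k.  Terms with no background genes are skipped.
    """
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    n_bg = len(background)
    n_hits = len(hits)
    rows = []
    for term in sorted(sets.sets):
        term_bg = sets.genes(term) & background
        big_k = len(term_bg)
        if big_k == 0:
            continue
        k = len(hits & term_bg)
        if n_hits == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_hits))
        rows.append((term, float(k), min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "statistic", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < SIGNIFICANCE_Q
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return EnrichmentResult(table=table)
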