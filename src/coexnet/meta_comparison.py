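"""Meta-comparison of enrichment results across network creation strategies.

Each analyzed (network, strategy) combination yields a set of significant
terms — a :class:`TermAssignment`.  The evaluation layer asks which
creation parameters drive the downstream interpretation:

1. pairwise Jaccard distances between term sets;
2. Louvain clustering of the similarity (1 - distance) graph;
3. per cluster, a hypergeometric test of whether any parameter value
   (algorithm, metric, pseudo-bulk method, ...) is over-represented —
   a parameter concentrating in a cluster of similar interpretations is
   one that shapes them;
4. a literature score: within one result object, significant terms
   should be better supported (higher literature co-mention counts,
   injected from a table) than non-significant ones, tested with a
   one-sided Welch t-test on log10(count + 1).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import SIGNIFICANCE_Q, bh_adjust

__all__ = [
    "TermAssignment",
    "ClusterEnrichment",
    "LiteratureScore",
    "jaccard_distance_matrix",
    "cluster_similarity_graph",
    "parameter_overrepresentation",
    "literature_score_test",
    "cluster_literature_scores",
]

logger = logging.getLogger(__name__)

PARAMETER_CATEGORIES = (
    "dataset",
    "modeling",
    "pseudobulk_method",
    "zero_mode",
    "gene_selection",
    "algorithm",
    "metric",
    "analysis",
)


@dataclass
class TermAssignment:
    """Significant term set of one result object plus its parameter tuple."""

    result_id: str
    parameters: dict[str, str]
    terms: frozenset[str]

    def __post_init__(self) -> None:
        # complete the annotation; inapplicable categories read "n/a"
        self.parameters = {
            cat: self.parameters.get(cat, "n/a") for cat in PARAMETER_CATEGORIES
        }
        self.terms = frozenset(self.terms)

    def to_json(self) -> str:
        return json.dumps({
            "result_id": self.result_id,
            "parameters": self.parameters,
            "terms": sorted(self.terms),
        })

    @classmethod
    def from_json(cls, line: str) -> "TermAssignment":
        payload = json.loads(line)
        return cls(payload["result_id"], payload["parameters"],
                   frozenset(payload["terms"]))


def write_assignments(assignments: Sequence[TermAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in assignments:
            fh.write(a.to_json() + "\n")


def read_assignments(path: str | Path) -> list[TermAssignment]:
    with open(path) as fh:
        return [TermAssignment.from_json(line) for line in fh if line.strip()]


def jaccard_distance_matrix(assignments: Sequence[TermAssignment]) -> np.ndarray:
    """D_ij = 1 - |S_i & S_j| / |S_i | S_j|; two empty sets are distance 0."""
    if len(assignments) < 2:
        raise ValueError("need at least 2 assignments")
    n = len(assignments)
    dist = np.zeros((n, n))
    empty_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = assignments[i].terms, assignments[j].terms
            union = len(si | sj)
            if union == 0:
                d = 0.0
                empty_pairs += 1
            else:
                d = 1.0 - len(si & sj) / union
            dist[i, j] = dist[j, i] = d
    if empty_pairs:
        logger.info("%d assignment pairs with both term sets empty "
                    "(distance 0 by convention)", empty_pairs)
    return dist


def cluster_similarity_graph(
    distance: np.ndarray,
    resolution: float = 1.0,
    seed: int = 0,
    weight_floor: float = 0.05,
) -> np.ndarray:
    """Louvain cluster labels on the similarity (1 - distance) graph.

    Edges with similarity below ``weight_floor`` are pruned so Louvain
    does not operate on a fully dense near-zero graph.  Deterministic
    given ``seed``.
    """
    distance = np.asarray(distance, dtype=float)
    if distance.ndim != 2 or distance.shape[0] != distance.shape[1]:
        raise ValueError("distance must be a square matrix")
    if not np.allclose(distance, distance.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(distance), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = distance.shape[0]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    sim = 1.0 - distance
    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= weight_floor:
                graph.add_edge(i, j, weight=float(sim[i, j]))
    parts = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed)
    parts = sorted(parts, key=min)
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(parts):
        for v in members:
            labels[v] = cid
    return labels


@dataclass
class ClusterEnrichment:
    """Hypergeometric parameter enrichment for one cluster."""

    cluster_id: int
    table: pd.DataFrame  # columns: category, value, k, K, n, N, p, q


def parameter_overrepresentation(
    labels: np.ndarray,
    assignments: Sequence[TermAssignment],
    categories: Sequence[str] = PARAMETER_CATEGORIES,
) -> list[ClusterEnrichment]:
    """Per cluster and (category, value): upper-tail hypergeometric test.

    N = all result objects, K = objects carrying the value, n = cluster
    size, k = objects in the cluster carrying the value.  q-values are BH
    within each category across clusters and values; significance at
    q < 0.05.  Categories with a single observed value are skipped.
    """
    labels = np.asarray(labels)
    if labels.size != len(assignments):
        raise ValueError("labels must cover all assignments")
    n_total = len(assignments)
    cluster_ids = sorted(set(labels.tolist()))

    rows = []  # (cluster, category, value, k, K, n, N, p)
    for cat in categories:
        values = [a.parameters.get(cat, "n/a") for a in assignments]
        distinct = sorted(set(values))
        if len(distinct) < 2:
            logger.info("category %r has a single value; skipped", cat)
            continue
        for cid in cluster_ids:
            in_cluster = labels == cid
            n_cluster = int(in_cluster.sum())
            for val in distinct:
                has_val = np.array([v == val for v in values])
                big_k = int(has_val.sum())
                k = int((has_val & in_cluster).sum())
                p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_cluster))
                rows.append((cid, cat, val, k, big_k, n_cluster, n_total,
                             min(p, 1.0)))

    frame = pd.DataFrame(
        rows, columns=["cluster", "category", "value", "k", "K", "n", "N", "p"])
    frame["q"] = np.nan
    for cat in frame["category"].unique():
        mask = frame["category"] == cat
        frame.loc[mask, "q"] = bh_adjust(frame.loc[mask, "p"].to_numpy())
    frame["significant"] = frame["q"] < SIGNIFICANCE_Q

    out = []
    for cid in cluster_ids:
        sub = frame[frame["cluster"] == cid].drop(columns="cluster")
        out.append(ClusterEnrichment(cluster_id=int(cid),
                                     table=sub.reset_index(drop=True)))
    return out


@dataclass
class LiteratureScore:
    """Welch t-test of literature counts: significant vs non-significant terms."""

    result_id: str
    t: float
    p: float
    testable: bool = True
    n_significant: int = 0
    n_other: int = 0


def literature_score_test(
    assignment: TermAssignment,
    all_terms: set[str],
    counts: Mapping[str, float],
    min_group: int = 3,
) -> LiteratureScore:
    """One-sided Welch t-test on log10(count + 1), significant > others.

    ``counts`` maps term id to a literature co-mention count (injected
    from a file; no live queries).  Terms without a count are dropped.
    A result with fewer than ``min_group`` counted terms on either side,
    or with zero variance overall, is flagged untestable.
    """
    sig = sorted(t for t in assignment.terms if t in counts)
    other = sorted(t for t in (all_terms - assignment.terms) if t in counts)
    if len(sig) < min_group or len(other) < min_group:
        return LiteratureScore(assignment.result_id, np.nan, np.nan,
                               testable=False,
                               n_significant=len(sig), n_other=len(other))
    x = np.log10(np.array([counts[t] for t in sig], dtype=float) + 1.0)
    y = np.log10(np.array([counts[t] for t in other], dtype=float) + 1.0)
    if np.ptp(np.concatenate([x, y])) == 0:
        return LiteratureScore(assignment.result_id, np.nan, np.nan,
                               testable=False,
                               n_significant=len(sig), n_other=len(other))
    t_stat, p = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    return LiteratureScore(assignment.result_id, float(t_stat), float(p),
                           n_significant=len(sig), n_other=len(other))


def cluster_literature_scores(
    scores: Sequence[LiteratureScore],
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Cluster result objects by their (t, p) literature scores.

    Euclidean distances between standardized (t, p) vectors are rescaled
    to [0, 1] and clustered like the term-set similarity graph.  Returns
    the labels and the id of the "expected" cluster — the one with the
    largest mean t statistic, i.e. whose results agree best with the
    literature.  Untestable scores must be filtered out beforehand.
    """
    usable = [s for s in scores if s.testable]
    if len(usable) != len(scores):
        raise ValueError("filter untestable scores before clustering")
    if len(scores) < 2:
        raise ValueError("need at least 2 scores")
    feats = np.array([[s.t, s.p] for s in scores])
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd
    diff = feats[:, None, :] - feats[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    if dist.max() > 0:
        dist = dist / dist.max()
    labels = cluster_similarity_graph(dist, resolution=resolution, seed=seed)
    mean_t = {}
    for cid in set(labels.tolist()):
        mean_t[cid] = float(np.mean([scores[i].t for i in np.flatnonzero(labels == cid)]))
    expected = max(sorted(mean_t), key=lambda c: mean_t[c])
    return labels, int(expected)


def read_literature_counts(path: str | Path) -> dict[str, float]:
    """Two-column TSV (term id, count), optional header."""
    counts: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            term, value = line.rstrip("\n").split("\t")[:2]
            try:
                counts[term] = float(value)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise
    return counts
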