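"""Intermediate-gene (IG) analysis on a prior protein-protein interaction
network.

Given a set of seed genes (typically the differential genes of a
condition), all shortest paths between every pair of seeds are enumerated
on the PPI graph; the non-seed genes lying in the interior of any of a
pair's shortest paths are the intermediate genes.  Each intermediate is
counted once per seed pair (however many of the pair's shortest paths it
sits on), and the resulting gene set is enriched against a term
collection by over-representation, with the PPI gene universe as
background.  Unlike co-expression networks the PPI graph is dataset
independent, so the (expensive) path enumeration can be reused across
studies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .enrichment import EnrichmentResult, hypergeometric_ora
from .synthetic_data import GeneSetCollection, PPINetwork

__all__ = [
    "IntermediateGeneResult",
    "shortest_path_intermediates",
    "ig_enrich",
]

logger = logging.getLogger(__name__)


@dataclass
class IntermediateGeneResult:
    """Intermediate genes with their seed-pair frequencies."""

    seeds: frozenset[str]
    frequencies: dict[str, int] = field(default_factory=dict)
    skipped_pairs: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.frequencies) & set(self.seeds)
        if overlap:
            raise ValueError(f"intermediates may not be seeds: {sorted(overlap)}")
        if any(f < 1 for f in self.frequencies.values()):
            raise ValueError("frequencies must be >= 1")

    def intermediates(self, min_frequency: int = 1) -> set[str]:
        return {g for g, f in self.frequencies.items() if f >= min_frequency}


def shortest_path_intermediates(
    ppi: PPINetwork,
    seeds: set[str],
    max_len: int = 3,
) -> IntermediateGeneResult:
    """Interior genes of all shortest paths between seed pairs.

    Only pairs at shortest-path distance <= ``max_len`` contribute; pairs
    in different components (or farther apart) are skipped and counted.
    A non-seed gene is counted once per pair in which it appears on any
    of the pair's shortest paths.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    graph = ppi.to_networkx()
    mapped = sorted(s for s in seeds if s in graph)
    if len(mapped) < 2:
        raise ValueError(
            f"only {len(mapped)} seed(s) map to the PPI; need at least 2")
    dropped = seeds - set(mapped)
    if dropped:
        logger.info("seeds not in PPI dropped: %s", sorted(dropped))

    frequencies: dict[str, int] = {}
    skipped = 0
    seed_set = set(mapped)
    # single-source BFS trees are reused across that seed's pairs
    for sa, sb in combinations(mapped, 2):
        try:
            distance = nx.shortest_path_length(graph, sa, sb)
        except nx.NetworkXNoPath:
            skipped += 1
            logger.info("seed pair (%s, %s) disconnected; skipped", sa, sb)
            continue
        if distance > max_len:
            skipped += 1
            continue
        if distance < 2:
            continue  # adjacent seeds have no interior nodes
        interior: set[str] = set()
        for path in nx.all_shortest_paths(graph, sa, sb):
            interior.update(path[1:-1])
        for gene in interior - seed_set:
            frequencies[gene] = frequencies.get(gene, 0) + 1
    return IntermediateGeneResult(frozenset(mapped), frequencies, skipped)


def ig_enrich(
    result: IntermediateGeneResult,
    background: set[str],
    sets: GeneSetCollection,
    min_frequency: int = 1,
) -> EnrichmentResult:
    """ORA of the (frequency-filtered) intermediate set vs the PPI universe."""
    intermediates = result.intermediates(min_frequency)
    if not intermediates:
        warnings.warn("no intermediate genes pass the frequency filter; "
                      "empty enrichment", stacklevel=2)
        return EnrichmentResult(provenance={"analysis": "ig"})
    enrich = hypergeometric_ora(intermediates & background, background, sets)
    enrich.provenance = {"analysis": "ig", "min_frequency": min_frequency}
    return enrich
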