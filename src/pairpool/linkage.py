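"""Cross-reaction genotype matching: find clusters shared between reactions.

The matched skin/PBMC pair of a donor shows up as two genotype clusters in
two different reactions with (near-)identical consensus genotypes.  The
concordance score between two clusters is the fraction of identical
discretized calls over loci where both clusters made a confident call; a
pair with too few co-called loci yields a no-call rather than a low score.
Edges at or above the match threshold form an undirected graph whose
connected components are the putative same-donor equivalence classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["MatchGraph", "genotype_concordance", "match_shared_clusters"]

Node = tuple[str, int]  # (reaction_id, cluster_id)


@dataclass
class MatchGraph:
    """Cross-reaction genotype-concordance matches.

    ``comparable`` lists reaction pairs whose shared confidently-called locus
    sets were large enough to compare every cluster pair; only for those
    pairs is the *absence* of a match evidence that donors differ.
    """

    graph: nx.Graph
    components: list[set[Node]]
    conflicts: list[Node]
    comparable: set[frozenset[str]]
    edges: pd.DataFrame  # reaction_a cluster_a reaction_b cluster_b score n_shared borderline

    def component_of(self) -> dict[Node, int]:
        out: dict[Node, int] = {}
        for i, comp in enumerate(self.components):
            for node in comp:
                out[node] = i
        return out


def genotype_concordance(g_a: np.ndarray, g_b: np.ndarray,
                         min_shared_loci: int = 20,
                         ) -> tuple[float | None, int]:
    """Fraction of identical calls over co-called loci.

    Vectors must be indexed on a common locus set; NaN marks a no-call.
    Returns ``(None, n_shared)`` — a no-call signal, distinct from a low
    score — when fewer than ``min_shared_loci`` loci are co-called.
    """
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    if g_a.shape != g_b.shape:
        raise ValidationError("call vectors must share a common locus index")
    both = ~np.isnan(g_a) & ~np.isnan(g_b)
    n_shared = int(both.sum())
    if n_shared < min_shared_loci:
        return None, n_shared
    score = float(np.mean(g_a[both] == g_b[both]))
    return score, n_shared


def match_shared_clusters(cluster_genotypes: dict[str, tuple[list[str], np.ndarray]],
                          tau_match: float = 0.9,
                          min_shared_loci: int = 20,
                          borderline_band: float = 0.02) -> MatchGraph:
    """Build the cross-reaction match graph from per-reaction consensus calls.

    ``cluster_genotypes`` maps reaction_id -> (locus_keys, calls) where
    ``calls`` is (n_loci, K) with NaN no-calls.  An edge joins every
    cross-reaction cluster pair with concordance >= ``tau_match``; scores
    within ``borderline_band`` above the threshold are flagged borderline.
    A node matching two or more clusters within one other reaction is listed
    as a conflict (and never silently resolved).
    """
    if len(cluster_genotypes) < 2:
        raise ValidationError("need at least 2 reactions to match")
    rxns = sorted(cluster_genotypes)
    common = set(cluster_genotypes[rxns[0]][0])
    for r in rxns[1:]:
        common &= set(cluster_genotypes[r][0])
    if not common:
        raise ValidationError("empty locus intersection across all reactions")

    graph = nx.Graph()
    for r in rxns:
        loci, calls = cluster_genotypes[r]
        for k in range(calls.shape[1]):
            graph.add_node((r, k))

    rows = []
    comparable: set[frozenset[str]] = set()
    for ra, rb in combinations(rxns, 2):
        loci_a, calls_a = cluster_genotypes[ra]
        loci_b, calls_b = cluster_genotypes[rb]
        shared = sorted(set(loci_a) & set(loci_b))
        ia = [loci_a.index(l) for l in shared]
        ib = [loci_b.index(l) for l in shared]
        pair_ok = bool(shared)
        for ka in range(calls_a.shape[1]):
            for kb in range(calls_b.shape[1]):
                score, n_shared = genotype_concordance(
                    calls_a[ia, ka], calls_b[ib, kb], min_shared_loci)
                if score is None:
                    pair_ok = False
                    continue
                if score >= tau_match:
                    borderline = score < tau_match + borderline_band
                    graph.add_edge((ra, ka), (rb, kb), score=score,
                                   n_shared=n_shared, borderline=borderline)
                    rows.append((ra, ka, rb, kb, score, n_shared, borderline))
        if pair_ok:
            comparable.add(frozenset((ra, rb)))

    conflicts: list[Node] = []
    for node in graph.nodes:
        partners_by_rxn: dict[str, int] = {}
        for nb in graph.neighbors(node):
            partners_by_rxn[nb[0]] = partners_by_rxn.get(nb[0], 0) + 1
        if any(c >= 2 for c in partners_by_rxn.values()):
            conflicts.append(node)

    components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: sorted(c)[0])
    edges = pd.DataFrame(
        rows, columns=["reaction_a", "cluster_a", "reaction_b", "cluster_b",
                       "score", "n_shared", "borderline"])
    return MatchGraph(graph, components, sorted(conflicts), comparable, edges)
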