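"""Confidence-thresholded protein-interaction graph and MCC hub ranking.

The graph keeps every queried gene as a node whether or not it gains an
edge — sparse discovery-scale gene lists are mostly isolated nodes, and the
node count is a reported quantity.  Hubs are ranked by maximal clique
centrality: ``MCC(v) = Σ (|C| − 1)!`` over the maximal cliques ``C``
containing ``v``, with an isolated node scoring 1 (the singleton clique
contributes ``0! = 1``).  Maximal cliques come from the pivoting
Bron–Kerbosch enumeration in networkx.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import UsageError
from .types import EdgeList


@dataclass
class PPIGraph:
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class HubScore:
    """Per-gene MCC values plus degrees (used for deterministic tie-breaks)."""

    scores: dict[str, int]
    degrees: dict[str, int]

    def ranking(self) -> list[str]:
        return sorted(
            self.scores, key=lambda g: (-self.scores[g], -self.degrees[g], g)
        )


def build_graph(genes: Iterable[str], edges: EdgeList, threshold: float) -> PPIGraph:
    """Undirected graph over the queried genes, keeping edges with
    score >= threshold.  Edges naming genes outside the query set are
    dropped with a warning."""
    if not (0.0 <= threshold <= 1.0):
        raise UsageError(f"threshold {threshold} outside [0, 1]")
    g = nx.Graph()
    genes = set(genes)
    g.add_nodes_from(genes)
    for a, b, score in edges:
        if a not in genes or b not in genes:
            warnings.warn(f"edge {a}–{b} references a gene outside the query set; dropped")
            continue
        if score >= threshold:
            g.add_edge(a, b, score=score)
    return PPIGraph(graph=g, threshold=threshold)


def average_degree(g: PPIGraph) -> float:
    """Mean node degree, 2·|E| / |N|."""
    if g.n_nodes == 0:
        raise UsageError("average degree of an empty graph is undefined")
    return 2.0 * g.n_edges / g.n_nodes


def maximal_cliques(g: PPIGraph) -> list[frozenset[str]]:
    """All inclusion-maximal cliques; isolated nodes appear as singletons."""
    return [frozenset(c) for c in nx.find_cliques(g.graph)]


def mcc_scores(g: PPIGraph) -> HubScore:
    scores = {v: 0 for v in g.graph.nodes}
    for clique in maximal_cliques(g):
        weight = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += weight
    degrees = dict(g.graph.degree())
    return HubScore(scores=scores, degrees=degrees)


def top_hubs(scores: HubScore, k: int) -> list[str]:
    """Top-k genes by (MCC desc, degree desc, symbol asc)."""
    if k < 1:
        raise UsageError("k must be >= 1")
    return scores.ranking()[:k]


def graph_summary(g: PPIGraph) -> pd.DataFrame:
    hub = mcc_scores(g)
    return pd.DataFrame(
        [
            {"gene": v, "degree": hub.degrees[v], "mcc": hub.scores[v]}
            for v in hub.ranking()
        ],
        columns=["gene", "degree", "mcc"],
    )
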