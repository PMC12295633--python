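"""Scored protein-protein interaction graphs and degree-based hub ranking.

The PPI graph is an undirected simple ``networkx.Graph`` whose edges carry
a ``score`` attribute (STRING-style combined score, 0-1000).  Hubs are
read off exactly the way the source analysis reads its network figures:
the number of edges incident to a protein is its interaction frequency,
and the highest-degree proteins are the predicted central effectors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HubRanking:
    """Degree-sorted protein list plus the selected hub set."""

    ranked: tuple[tuple[str, int], ...]  # (protein, degree), non-increasing
    hub_set: frozenset[str]


def build_ppi_graph(
    edges: Iterable[tuple[str, str, float]], score_min: float = 0
) -> nx.Graph:
    """Assemble an undirected simple graph from scored protein pairs.

    Self-loops are dropped; duplicate A-B / B-A rows merge keeping the
    maximum score; edges scoring below ``score_min`` are excluded.
    """
    g = nx.Graph()
    n_rows = n_self = n_low = 0
    for a, b, score in edges:
        n_rows += 1
        a, b = a.strip(), b.strip()
        if a == b:
            n_self += 1
            continue
        if score < score_min:
            n_low += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    logger.info(
        "PPI graph: %d rows in, %d self-loops dropped, %d below score_min=%s, "
        "%d nodes, %d edges",
        n_rows, n_self, n_low, score_min, g.number_of_nodes(),
        g.number_of_edges(),
    )
    if n_rows and g.number_of_edges() == 0:
        logger.warning("all %d edge rows filtered out; graph is empty", n_rows)
    return g


def degree_rank(graph: nx.Graph, top_k: int = 10) -> HubRanking:
    """Rank proteins by degree, descending, ties lexicographic.

    The hub set is the top ``top_k`` proteins with the full tie group at
    the boundary included, so the selection never splits proteins of equal
    degree.  An empty graph yields an empty ranking.
    """
    ranked = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    if not ranked or top_k <= 0:
        return HubRanking(ranked=tuple(ranked), hub_set=frozenset())
    cutoff_idx = min(top_k, len(ranked)) - 1
    cutoff_degree = ranked[cutoff_idx][1]
    hubs = frozenset(p for p, d in ranked if d >= cutoff_degree)
    return HubRanking(ranked=tuple(ranked), hub_set=hubs)


def subgraph_for(
    proteins: Iterable[str], graph: nx.Graph
) -> tuple[nx.Graph, frozenset[str]]:
    """Induced subgraph on the given proteins; absent proteins reported.

    Returns the subgraph (a copy) and the set of requested proteins not
    present in the graph.
    """
    wanted = set(proteins)
    present = wanted & set(graph.nodes)
    absent = frozenset(wanted - present)
    sub = graph.subgraph(present).copy()
    if absent:
        logger.info("%d of %d requested proteins absent from the PPI graph",
                    len(absent), len(wanted))
    return sub, absent
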