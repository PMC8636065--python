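"""Thresholded Pearson co-expression network and hub statistics.

Given a gene list, every pair of genes is correlated across strains and an
edge is kept when |r| strictly exceeds the threshold (default 0.3, the
moderate-correlation convention).  Edges carry the signed r.  Per node:

* degree (connectivity),
* connection weight — the sum of |r| over incident edges (the absolute
  convention; signed sums are reported alongside),
* average connection weight = weight / degree.

The hub is the node maximizing degree, ties broken by absolute connection
weight, then lexicographically by gene id.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["build_network", "node_stats", "identify_hub"]


def build_network(
    expression: ExpressionMatrix,
    genes: list[str] | None = None,
    threshold: float = 0.3,
) -> nx.Graph:
    """All-pairs Pearson graph over ``genes`` with |r| > threshold edges.

    Every listed gene becomes a node even if isolated.  The threshold is
    strict: a pair at exactly |r| = threshold is not connected.
    """
    if genes is not None:
        expression = expression.restrict(genes=genes)
    ids = expression.gene_ids
    if len(ids) < 3:
        raise ValueError("need at least 3 genes to build a network")
    if expression.n_strains < 6:
        raise ValueError("need at least 6 strains to build a network")
    corr = np.corrcoef(expression.values)
    graph = nx.Graph(threshold=float(threshold))
    graph.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = float(corr[i, j])
            if abs(r) > threshold:
                graph.add_edge(ids[i], ids[j], r=r)
    return graph


def node_stats(graph: nx.Graph) -> pd.DataFrame:
    """Degree and connection-weight statistics per node.

    Columns: gene, degree, weight_abs (sum |r|), weight_signed (sum r),
    weight_avg (weight_abs / degree, 0 for isolated nodes).  Sorted by
    (degree, weight_abs) descending with gene id as the final tie-break, so
    the first row is the hub.
    """
    rows = []
    for node in graph.nodes:
        rs = [graph.edges[node, nbr]["r"] for nbr in graph.neighbors(node)]
        degree = len(rs)
        weight_abs = float(np.sum(np.abs(rs))) if rs else 0.0
        rows.append(
            {
                "gene": node,
                "degree": degree,
                "weight_abs": weight_abs,
                "weight_signed": float(np.sum(rs)) if rs else 0.0,
                "weight_avg": weight_abs / degree if degree else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["degree", "weight_abs", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return table


def identify_hub(stats: pd.DataFrame) -> tuple[str, pd.DataFrame]:
    """Hub gene (max degree, tie-broken by weight_abs, then gene id) and the
    full ranking."""
    if len(stats) == 0:
        raise ValueError("empty node statistics")
    ranking = stats.sort_values(
        ["degree", "weight_abs", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return str(ranking.iloc[0]["gene"]), ranking
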