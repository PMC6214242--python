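"""Node-level complex-network indices for undirected site graphs.

Five local indices feed the cross-graph correlation analysis: node degree,
betweenness and closeness centrality, the clustering coefficient, and the
topological coefficient.  Conventions (which matter because the graphs here
are typically disconnected):

* **closeness** is component-local: 1 / (mean shortest-path length from the
  node to the nodes it can reach); isolated nodes score 0.  No penalty is
  applied for unreachable nodes, so every node gets a finite value and
  within-graph rank order — the quantity the correlation analysis uses —
  is well defined.
* **betweenness** is the shortest-path pair-dependency sum normalized by
  (N−1)(N−2)/2 over the full node count, including other components;
  unreachable pairs contribute 0.
* **clustering** of a node with degree k ≥ 2 is 2·e/(k(k−1)) with e the
  edge count among its neighbours, else 0.
* the **topological coefficient** of node v averages, over the nodes m
  that share at least one neighbour with v, the shared-neighbour count
  J(v, m) — plus 1 when (v, m) is itself an edge — and divides by the
  degree of v; nodes with no neighbour-sharing partner (or degree 0)
  score 0.  This is the shared-neighbour index reported by common
  network-analysis suites; it is near 1 for nodes whose neighbourhoods
  are redundant with their partners' and small for hub-like nodes.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = ["compute_indices", "topological_coefficient"]

INDEX_NAMES = ("degree", "betweenness", "closeness", "clustering", "topological")


def topological_coefficient(g: nx.Graph) -> dict:
    """Topological coefficient per node of an undirected simple graph."""
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    out = {}
    for v in g.nodes:
        k = len(adj[v])
        if k == 0:
            out[v] = 0.0
            continue
        scores = []
        for m in g.nodes:
            if m == v:
                continue
            shared = len(adj[v] & adj[m])
            if shared == 0:
                continue
            scores.append(shared + (1 if m in adj[v] else 0))
        out[v] = (sum(scores) / len(scores)) / k if scores else 0.0
    return out


def compute_indices(graph) -> pd.DataFrame:
    """All five node indices of an :class:`~sitegraphs.graphs.EcoGraph`.

    Returns a DataFrame indexed by node id with columns ``degree``,
    ``betweenness``, ``closeness``, ``clustering``, ``topological``.
    An empty graph yields an empty table.
    """
    g = graph.to_networkx() if hasattr(graph, "to_networkx") else nx.Graph(graph)
    nodes = list(g.nodes)
    if not nodes:
        return pd.DataFrame(columns=list(INDEX_NAMES))
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    clustering = nx.clustering(g)
    topological = topological_coefficient(g)
    return pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "clustering": [clustering[v] for v in nodes],
            "topological": [topological[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
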