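"""Graph and nodal properties of thresholded connectivity graphs.

The discriminability machinery evaluates one scalar *property* per
(condition, subject) connectivity slice.  For a multi-ROI candidate network
the property is computed on the subgraph **induced** by the candidate's ROI
set, so a candidate's score does not depend on non-member ROIs; for a single
ROI the nodal property is computed within the **full** combined-network
graph, the only reading under which a lone node has a meaningful degree.
Both scopes are exposed.

Available metrics: degree centrality (default), clustering coefficient and
global efficiency, all on unweighted graphs.  Degree quantities are plain
numpy; clustering and efficiency delegate to networkx on the induced
subgraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .connectivity import ConditionStack

__all__ = [
    "METRICS",
    "BinaryGraph",
    "threshold_graph",
    "nodal_degree_centrality",
    "subset_mean_degree_centrality",
    "clustering_coefficient",
    "global_efficiency",
    "subset_property",
    "nodal_property",
]

METRICS = ("degree", "clustering", "efficiency")


@dataclass
class BinaryGraph:
    """Unweighted, undirected graph over named ROI nodes."""

    nodes: list[str]
    adjacency: np.ndarray  # (n, n) bool, symmetric, False diagonal

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape must match node count")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-loops are not allowed")
        self._index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, v: str) -> int:
        try:
            return self._index[v]
        except KeyError:
            raise KeyError(f"node {v!r} not in graph")

    def indices(self, subset: Sequence[str]) -> np.ndarray:
        return np.array([self.index(v) for v in subset], dtype=int)

    def to_networkx(self, subset: Sequence[str] | None = None) -> nx.Graph:
        if subset is None:
            idx = np.arange(self.n)
            names = self.nodes
        else:
            idx = self.indices(subset)
            names = list(subset)
        g = nx.from_numpy_array(self.adjacency[np.ix_(idx, idx)])
        return nx.relabel_nodes(g, dict(enumerate(names)))

    def edge_list(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, k=1)
        return [
            (self.nodes[i], self.nodes[j])
            for i, j in zip(*iu)
            if self.adjacency[i, j]
        ]


def threshold_graph(
    stack: ConditionStack,
    c: int,
    s: int,
    q: float = 0.05,
    mode: str = "positive",
) -> BinaryGraph:
    """Binary graph of FDR-surviving edges for one (condition, subject)."""
    adj = stack.graphs(q=q, mode=mode)[c, s]
    return BinaryGraph(nodes=stack.qualified_ids, adjacency=adj.copy())


# ---------------------------------------------------------------------------
# degree centrality


def nodal_degree_centrality(g: BinaryGraph, v: str) -> float:
    """deg(v) / (n - 1) within the full graph; lies in [0, 1]."""
    if g.n < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    return float(g.adjacency[g.index(v)].sum()) / (g.n - 1)


def subset_mean_degree_centrality(
    g: BinaryGraph, subset: Sequence[str]
) -> float:
    """Mean degree centrality over the subgraph induced by ``subset``.

    Each member's degree counts edges to other members only and is
    normalised by ``|subset| - 1``.
    """
    idx = g.indices(subset)
    k = idx.size
    if k < 2:
        raise ValueError(
            "subset must have >= 2 ROIs (use nodal_degree_centrality)"
        )
    if len(set(subset)) != k:
        raise ValueError("subset contains duplicate nodes")
    sub = g.adjacency[np.ix_(idx, idx)]
    return float(sub.sum()) / (k * (k - 1))


# ---------------------------------------------------------------------------
# clustering and efficiency (unweighted, induced subgraph)


def clustering_coefficient(g: BinaryGraph, subset: Sequence[str]) -> float:
    """Average clustering coefficient of the induced subgraph."""
    if len(subset) < 2:
        raise ValueError("subset must have >= 2 ROIs")
    return float(nx.average_clustering(g.to_networkx(subset)))


def global_efficiency(g: BinaryGraph, subset: Sequence[str]) -> float:
    """Mean inverse shortest-path length over pairs of the induced subgraph."""
    if len(subset) < 2:
        raise ValueError("subset must have >= 2 ROIs")
    return float(nx.global_efficiency(g.to_networkx(subset)))


# ---------------------------------------------------------------------------
# metric dispatch


def subset_property(
    g: BinaryGraph, subset: Sequence[str], metric: str = "degree"
) -> float:
    """Graph property of a multi-ROI candidate (induced-subgraph scope)."""
    if metric == "degree":
        return subset_mean_degree_centrality(g, subset)
    if metric == "clustering":
        return clustering_coefficient(g, subset)
    if metric == "efficiency":
        return global_efficiency(g, subset)
    raise ValueError(f"unknown metric {metric!r} (choose from {METRICS})")


def nodal_property(g: BinaryGraph, v: str, metric: str = "degree") -> float:
    """Nodal property of a single ROI within the full graph."""
    if metric == "degree":
        return nodal_degree_centrality(g, v)
    if metric == "clustering":
        return float(nx.clustering(g.to_networkx(), v))
    if metric == "efficiency":
        # nodal efficiency: mean inverse distance from v to every other node
        gx = g.to_networkx()
        lengths = nx.single_source_shortest_path_length(gx, v)
        inv = [1.0 / d for u, d in lengths.items() if u != v]
        return float(sum(inv) / (g.n - 1)) if g.n > 1 else 0.0
    raise ValueError(f"unknown metric {metric!r} (choose from {METRICS})")
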