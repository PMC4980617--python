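"""Small helpers for moving between networkx graphs and boolean adjacency
matrices.  The simulation loop works on dense boolean arrays for speed; the
public API accepts either representation."""

from __future__ import annotations

import networkx as nx
import numpy as np


def as_adjacency(graph) -> np.ndarray:
    """Boolean adjacency matrix of an undirected simple graph.

    Accepts a networkx graph (nodes must be 0..n-1) or any square array-like.
    """
    if isinstance(graph, nx.Graph):
        a = nx.to_numpy_array(graph, nodelist=sorted(graph.nodes()), dtype=bool)
    else:
        a = np.asarray(graph)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency matrix must be square")
        a = a.astype(bool)
    a = a | a.T
    np.fill_diagonal(a, False)
    return a


def to_graph(adjacency: np.ndarray) -> nx.Graph:
    """networkx view of a boolean adjacency matrix (nodes 0..n-1)."""
    g = nx.from_numpy_array(np.asarray(adjacency, dtype=bool))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g
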