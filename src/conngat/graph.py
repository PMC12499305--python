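"""Brain-graph construction from connectivity profiles.

Nodes are ROIs; candidate edge weights are cosine similarities between the
ROIs' connectivity profiles (matrix rows with the self-correlation zeroed).
Only the strongest `density` fraction of node pairs is kept as the topology;
the weights rank edges but do not enter the attention computation.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = ["BrainGraph", "build_graph", "cosine_edge_weights"]


class BrainGraph:
    """Undirected graph over ROIs with per-node feature vectors.

    Attributes
    ----------
    n_nodes : int
    neighbors : list of sets, `neighbors[i]` excludes i itself.
    edge_weight : dict (i, j) -> weight, stored for both orientations.
    node_features : (N, F) array.
    self_loops : whether nodes attend to themselves in message passing.
    """

    def __init__(self, n_nodes: int, edges, weights, node_features, self_loops: bool = True):
        self.n_nodes = int(n_nodes)
        self.neighbors: list[set[int]] = [set() for _ in range(self.n_nodes)]
        self.edge_weight: dict[tuple[int, int], float] = {}
        for (i, j), w in zip(edges, weights):
            if i == j:
                continue
            self.neighbors[i].add(j)
            self.neighbors[j].add(i)
            self.edge_weight[(i, j)] = float(w)
            self.edge_weight[(j, i)] = float(w)
        self.node_features = np.asarray(node_features, dtype=float)
        if self.node_features.shape[0] != self.n_nodes:
            raise ValueError("node_features first dimension must equal n_nodes")
        self.self_loops = bool(self_loops)

    @property
    def undirected_edges(self) -> list[tuple[int, int]]:
        return sorted({(min(i, j), max(i, j)) for (i, j) in self.edge_weight})

    def directed_edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(dst, src) index arrays: one directed edge per (i, j in N(i)) pair,
        plus (i, i) self loops when enabled. Ordered for determinism."""
        dst, src = [], []
        for i in range(self.n_nodes):
            targets = sorted(self.neighbors[i])
            if self.self_loops:
                targets.append(i)
            for j in targets:
                dst.append(i)
                src.append(j)
        return np.asarray(dst, dtype=np.intp), np.asarray(src, dtype=np.intp)


def cosine_edge_weights(fc_values: np.ndarray) -> np.ndarray:
    """All-pairs cosine similarity of connectivity profiles.

    Profiles are matrix rows with the diagonal (self-correlation) zeroed so a
    node's trivial self-entry does not inflate similarity.  Zero-norm rows get
    similarity 0 everywhere, with a warning.
    """
    v = np.asarray(fc_values, dtype=float).copy()
    np.fill_diagonal(v, 0.0)
    norms = np.linalg.norm(v, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"zero-norm connectivity profile for node(s) {np.flatnonzero(zero).tolist()}; "
            "their similarities are set to 0"
        )
        norms = np.where(zero, 1.0, norms)
    sims = (v / norms[:, None]) @ (v / norms[:, None]).T
    sims[zero, :] = 0.0
    sims[:, zero] = 0.0
    np.fill_diagonal(sims, 0.0)
    return sims


def build_graph(
    fc: ConnectivityMatrix | np.ndarray,
    node_features: np.ndarray,
    density: float = 0.10,
    self_loops: bool = True,
) -> BrainGraph:
    """Keep the top `density` fraction of node pairs by cosine similarity.

    Ties are broken lexicographically by (i, j).  The default density of 0.10
    retains the top 10% of connections.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    values = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    n = values.shape[0]
    sims = cosine_edge_weights(values)
    iu, ju = np.triu_indices(n, k=1)
    vals = sims[iu, ju]
    k = math.ceil(density * len(vals))
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    edges = [(int(iu[e]), int(ju[e])) for e in keep]
    weights = [vals[e] for e in keep]
    return BrainGraph(n, edges, weights, node_features, self_loops=self_loops)
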