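"""Weighted, unthresholded brain-network topology metrics.

The WPLI matrix is treated directly as a weighted adjacency matrix — no
threshold is applied, every connection is retained. Conventions follow
the common weighted brain-network toolbox definitions:

- clustering: Onnela geometric-mean-of-triangles form on weights
  normalized by the matrix maximum; the average is taken over nodes with
  degree >= 2 (nodes without two neighbors have no defined triangle).
- path metrics: edge length is the reciprocal of the weight (strong
  connections are short); characteristic path length is the mean finite
  shortest distance over ordered node pairs, and global efficiency is
  the mean inverse distance (1/inf = 0).
- local efficiency of node i: global efficiency of the subgraph induced
  on i's neighbors, 0 with fewer than two neighbors.
- eigenvector centrality: leading eigenvector of the raw weight matrix
  by power iteration, non-negative entries, unit Euclidean norm; on a
  disconnected graph the dominant (largest) component is used and the
  result flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "WeightedGraph",
    "NetworkMetrics",
    "clustering_weighted",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "eigenvector_centrality",
    "network_metrics",
]


@dataclass
class WeightedGraph:
    """Symmetric non-negative weighted adjacency with labeled nodes."""

    adjacency: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if a.min() < 0:
            raise ValueError("weights must be non-negative")
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 0.0)
        self.adjacency = a
        if self.node_labels is None:
            self.node_labels = tuple(str(i) for i in range(a.shape[0]))
        elif len(self.node_labels) != a.shape[0]:
            raise ValueError("node_labels must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class NetworkMetrics:
    """Global scalars and nodal vectors for one weighted graph."""

    avg_clustering: float
    char_path_length: float
    global_efficiency: float
    local_efficiency: np.ndarray
    eigenvector_centrality: np.ndarray
    clustering: np.ndarray
    n_disconnected_pairs: int = 0
    centrality_on_component: bool = False


def _as_graph(g) -> WeightedGraph:
    return g if isinstance(g, WeightedGraph) else WeightedGraph(np.asarray(g, dtype=float))


def clustering_weighted(g) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node, and its average over nodes with k >= 2."""
    g = _as_graph(g)
    if g.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    w = g.adjacency
    wmax = w.max()
    if wmax == 0:
        return np.zeros(g.n_nodes), 0.0
    cbrt = np.cbrt(w / wmax)
    triangles = np.diag(cbrt @ cbrt @ cbrt)  # 2x geometric-mean triangle count
    k = np.count_nonzero(w > 0, axis=1)
    denom = k * (k - 1)
    c = np.zeros(g.n_nodes)
    eligible = denom > 0
    c[eligible] = triangles[eligible] / denom[eligible]
    avg = float(c[eligible].mean()) if eligible.any() else 0.0
    return c, avg


def shortest_path_lengths(g) -> np.ndarray:
    """All-pairs shortest distances with edge length 1/weight (Dijkstra).

    Zero weight means no edge; unreachable pairs are infinity; the
    diagonal is 0.
    """
    g = _as_graph(g)
    w = g.adjacency
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = shortest_path(lengths, method="D", directed=False, unweighted=False)
    return d


def characteristic_path_length(g) -> float:
    """Mean finite shortest distance over ordered off-diagonal pairs."""
    d = shortest_path_lengths(g)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("all node pairs are disconnected")
    return float(d[finite].mean())


def global_efficiency(g) -> float:
    """Mean inverse shortest distance over ordered pairs (1/inf = 0)."""
    d = shortest_path_lengths(g)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].mean())


def local_efficiency(g) -> np.ndarray:
    """Per node: global efficiency of the neighbor-induced subgraph."""
    g = _as_graph(g)
    w = g.adjacency
    eff = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        eff[i] = global_efficiency(WeightedGraph(sub))
    return eff


def eigenvector_centrality(
    g, tol: float = 1e-10, max_iter: int = 10_000
) -> tuple[np.ndarray, bool]:
    """Leading eigenvector of the weight matrix by power iteration.

    Returns (centrality, used_dominant_component). Entries are
    non-negative and the vector has unit Euclidean norm. On a
    disconnected graph the component with the most nodes is used and the
    second element is True.
    """
    g = _as_graph(g)
    w = g.adjacency
    n = g.n_nodes
    n_comp, labels = connected_components(w > 0, directed=False)
    on_component = False
    active = np.arange(n)
    if n_comp > 1:
        sizes = np.bincount(labels)
        active = np.flatnonzero(labels == np.argmax(sizes))
        w = w[np.ix_(active, active)]
        on_component = True
    if w.max() == 0:
        raise ValueError("graph has no edges; eigenvector centrality undefined")
    # iterate on A + cI: same eigenvectors, but the Perron root is strictly
    # dominant even on bipartite graphs (whose spectrum is symmetric)
    shifted = w + w.max() * np.eye(w.shape[0])
    v = np.full(w.shape[0], 1.0 / np.sqrt(w.shape[0]))
    for iteration in range(1, max_iter + 1):
        nxt = shifted @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            raise ValueError("power iteration collapsed to the zero vector")
        nxt /= norm
        if np.linalg.norm(nxt - v) <= tol * np.linalg.norm(nxt):
            v = nxt
            break
        v = nxt
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} iterations"
        )
    v = np.abs(v)  # Perron vector of a non-negative matrix is non-negative
    full = np.zeros(n)
    full[active] = v
    full /= np.linalg.norm(full)
    return full, on_component


def network_metrics(g) -> NetworkMetrics:
    """All global and nodal topology metrics for one weighted graph."""
    g = _as_graph(g)
    clustering, avg_c = clustering_weighted(g)
    d = shortest_path_lengths(g)
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("all node pairs are disconnected")
    char_path = float(d[finite].mean())
    with np.errstate(divide="ignore"):
        inv = np.where(finite & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    glob_eff = float(inv[off].mean())
    centrality, on_comp = eigenvector_centrality(g)
    return NetworkMetrics(
        avg_clustering=avg_c,
        char_path_length=char_path,
        global_efficiency=glob_eff,
        local_efficiency=local_efficiency(g),
        eigenvector_centrality=centrality,
        clustering=clustering,
        n_disconnected_pairs=int(np.count_nonzero(off & ~finite)),
        centrality_on_component=on_comp,
    )
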