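"""Cell-graph construction.

Each tissue core becomes one graph: cells are nodes, and two cells are
connected when their centroids lie within a fixed physical radius
(default 30 um, boundary inclusive).  A Delaunay triangulation of the
centroids provides the neighbourhoods used for cluster features.
All coordinates are micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

__all__ = ["CoreGraph", "build_cell_graph", "delaunay_adjacency",
           "DelaunayResult"]

DEFAULT_RADIUS_UM = 30.0


@dataclass
class CoreGraph:
    """One bag: node features, undirected edges and ordinal labels.

    ``edges`` is an (m, 2) array of index pairs with u < v (each
    undirected edge stored once, no self loops).  The two ordinal label
    tasks always satisfy ``y_s_task + y_e_task == 2``.
    """

    node_features: np.ndarray
    feature_names: list[str]
    edges: np.ndarray
    centroids: np.ndarray
    core_id: str
    slide_id: str = ""
    patient_id: str = ""
    y_s_task: int = -1
    y_e_task: int = -1
    isolated_nodes: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def n_cells(self) -> int:
        return int(self.node_features.shape[0])

    def validate(self) -> None:
        e = self.edges
        if e.size and (e[:, 0] == e[:, 1]).any():
            raise ValueError("self loops not allowed")
        if self.node_features.shape[0] != self.centroids.shape[0]:
            raise ValueError("feature/centroid row count mismatch")
        if self.y_s_task >= 0 and self.y_s_task + self.y_e_task != 2:
            raise ValueError("ordinal task labels must sum to 2")

    def directed_edges(self) -> np.ndarray:
        """Both orientations of every undirected edge, (2m, 2)."""
        if self.edges.size == 0:
            return np.zeros((0, 2), dtype=np.int64)
        return np.vstack([self.edges, self.edges[:, ::-1]])


def build_cell_graph(
    features: np.ndarray,
    centroids: np.ndarray,
    radius: float = DEFAULT_RADIUS_UM,
    feature_names: list[str] | None = None,
    **metadata,
) -> CoreGraph:
    """Connect each cell to every other cell within ``radius`` um.

    The distance test is inclusive: an edge (u, v) exists iff
    ``0 < dist(u, v) <= radius``.  Cells with no neighbour are kept and
    flagged in ``isolated_nodes``.
    """
    features = np.asarray(features, dtype=np.float64)
    centroids = np.asarray(centroids, dtype=np.float64)
    if features.ndim != 2 or centroids.shape != (features.shape[0], 2):
        raise ValueError("features must be (n, d) and centroids (n, 2)")
    if features.shape[0] < 1:
        raise ValueError("graph needs at least one cell")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not np.isfinite(centroids).all():
        raise ValueError("centroids must be finite")

    n = centroids.shape[0]
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if pairs.size:
        # query_pairs is inclusive of r but guard against coincident points
        d = np.linalg.norm(centroids[pairs[:, 0]] - centroids[pairs[:, 1]],
                           axis=1)
        pairs = pairs[d > 0]
        pairs = np.sort(pairs, axis=1)
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    else:
        pairs = np.zeros((0, 2), dtype=np.int64)
    degree = np.zeros(n, dtype=np.int64)
    if pairs.size:
        np.add.at(degree, pairs.ravel(), 1)
    graph = CoreGraph(
        node_features=features,
        feature_names=list(feature_names) if feature_names is not None
        else [f"f{i}" for i in range(features.shape[1])],
        edges=pairs.astype(np.int64),
        centroids=centroids,
        isolated_nodes=np.flatnonzero(degree == 0),
        **metadata,
    )
    graph.validate()
    return graph


@dataclass
class DelaunayResult:
    """Planar triangulation adjacency with physical edge lengths."""

    neighbors: list[np.ndarray]
    edge_lengths: list[np.ndarray]
    fallback_used: bool = False


def delaunay_adjacency(centroids: np.ndarray,
                       fallback_radius: float = DEFAULT_RADIUS_UM
                       ) -> DelaunayResult:
    """Delaunay neighbour lists with Euclidean edge lengths in um.

    Requires >= 3 non-collinear points; degenerate inputs (fewer points
    or an all-collinear set) fall back to radius adjacency and are
    flagged.  Cocircular configurations are resolved deterministically by
    scipy's Qhull with joggle disabled and a fixed point order; ties in
    the choice of diagonal go to the lowest-index triangle fan.
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    n = centroids.shape[0]
    if n >= 3:
        try:
            tri = Delaunay(centroids)
            if tri.simplices.size > 0:
                pairs = set()
                for simplex in np.sort(tri.simplices, axis=1):
                    a, b, c = (int(x) for x in simplex)
                    pairs.update([(a, b), (a, c), (b, c)])
                neigh = [[] for _ in range(n)]
                for a, b in sorted(pairs):
                    neigh[a].append(b)
                    neigh[b].append(a)
                neighbors = [np.array(sorted(v), dtype=np.int64)
                             for v in neigh]
                lengths = [
                    np.linalg.norm(centroids[v] - centroids[i], axis=1)
                    if v.size else np.zeros(0)
                    for i, v in enumerate(neighbors)]
                return DelaunayResult(neighbors, lengths, fallback_used=False)
        except Exception:
            pass
    # collinear or too few points: radius adjacency, flagged
    tree = cKDTree(centroids)
    pairs_arr = tree.query_pairs(r=fallback_radius, output_type="ndarray")
    neigh = [[] for _ in range(n)]
    for a, b in pairs_arr:
        neigh[int(a)].append(int(b))
        neigh[int(b)].append(int(a))
    neighbors = [np.array(sorted(v), dtype=np.int64) for v in neigh]
    lengths = [np.linalg.norm(centroids[v] - centroids[i], axis=1)
               if v.size else np.zeros(0)
               for i, v in enumerate(neighbors)]
    return DelaunayResult(neighbors, lengths, fallback_used=True)
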