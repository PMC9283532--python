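"""Spatial neighbor graphs for cells/spots and their corrupted counterparts.

The spatial expression graph (SEG) couples the preprocessed feature matrix X
with a binary symmetric spatial adjacency A. Two constructions are provided:

* **alpha** (default): the 1-skeleton of the alpha complex at radius ``delta``.
  Each cell's Voronoi region is intersected with a ball of radius ``delta``
  around the cell; an edge (i, j) exists when the two restricted regions
  touch. Equivalently, a Delaunay edge survives when its alpha filtration
  value (the minimum circumradius over the shared Voronoi facet) is at most
  ``delta``. The radius is estimated from the data as the mean k-nearest
  neighbor distance.
* **knn**: union-symmetrized k-nearest neighbors in Euclidean space.

The expression-permuted graph (EPG) — the negative sample for contrastive
training — keeps A and randomly permutes the rows of X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError, cKDTree

from .preprocess import FeatureMatrix

logger = logging.getLogger("spatialflow")

__all__ = [
    "SpatialExpressionGraph",
    "PermutedGraph",
    "build_knn_graph",
    "estimate_delta",
    "build_alpha_graph",
    "build_graph",
    "permute_features",
    "write_edge_list",
    "read_edge_list",
]


@dataclass
class SpatialExpressionGraph:
    """Node features X attached to a symmetric spatial adjacency A."""

    X: np.ndarray
    A: sp.csr_matrix
    coords: np.ndarray
    method: str = "alpha"
    delta: float | None = None
    k: int = 15

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.A = sp.csr_matrix(self.A)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.X.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("adjacency shape does not match feature rows")
        if (self.A != self.A.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if self.A.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def edge_list(self) -> np.ndarray:
        """Unordered edges as an (m, 2) array with i < j."""
        coo = sp.triu(self.A, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])


@dataclass
class PermutedGraph:
    """EPG: row-permuted features over the parent graph's adjacency."""

    X_tilde: np.ndarray
    A: sp.csr_matrix
    permutation: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# kNN graph
# ---------------------------------------------------------------------------

def _knn_indices(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact k nearest neighbors per point (self excluded).

    Ties in distance are broken by lower point index so that the result is
    deterministic on degenerate inputs (grids, duplicated coordinates).
    Returns (indices, distances), each (N, k).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_points (got k={k}, n={n})")

    if n <= 4096:
        from scipy.spatial.distance import cdist

        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d), axis=1)
        idx = order[:, :k]
        dist = np.take_along_axis(d, idx, axis=1)
        return idx, dist

    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=k + 1)
    # drop self (distance-0 duplicates may displace it from column 0)
    out_i = np.empty((n, k), dtype=int)
    out_d = np.empty((n, k))
    rows = np.arange(n)
    self_pos = np.argmax(idx == rows[:, None], axis=1)
    for r in range(n):
        keep = np.delete(np.arange(k + 1), self_pos[r])
        out_i[r] = idx[r, keep]
        out_d[r] = dist[r, keep]
    return out_i, out_d


def build_knn_graph(coords: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Union-symmetrized k-nearest-neighbor adjacency (binary, zero diagonal)."""
    idx, _ = _knn_indices(coords, k)
    n = coords.shape[0]
    rows = np.repeat(np.arange(n), k)
    a = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n), dtype=np.int8
    )
    a = a.maximum(a.T)
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def estimate_delta(coords: np.ndarray, k: int = 15) -> float:
    """Alpha radius: mean over spots of the mean k-nearest-neighbor distance."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] <= k:
        raise ValueError(f"need more than k={k} points, got {coords.shape[0]}")
    _, dist = _knn_indices(coords, k)
    return float(dist.mean())


# ---------------------------------------------------------------------------
# alpha-complex graph
# ---------------------------------------------------------------------------

def _circumcenter(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Circumcenter of triangle abc in the plane."""
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if d == 0:
        return 0.5 * (np.minimum(np.minimum(a, b), c) + np.maximum(np.maximum(a, b), c))
    a2, b2, c2 = (a * a).sum(), (b * b).sum(), (c * c).sum()
    ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
    uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
    return np.array([ux, uy])


def _dist_point_to_facet(p: np.ndarray, start: np.ndarray,
                         end: np.ndarray | None, direction: np.ndarray | None) -> float:
    """Min distance from p to a Voronoi facet: segment [start,end] or ray."""
    if end is not None:
        v = end - start
        denom = float(v @ v)
        t = 0.0 if denom == 0 else float(np.clip((p - start) @ v / denom, 0.0, 1.0))
        closest = start + t * v
    else:
        t = max(0.0, float((p - start) @ direction))
        closest = start + t * direction
    return float(np.linalg.norm(p - closest))


def _alpha_edge_filtration(points: np.ndarray, tri: Delaunay) -> dict:
    """Filtration radius of each Delaunay edge.

    The shared Voronoi facet of edge (i, j) is the segment between the
    circumcenters of the incident triangles (a ray to infinity for hull
    edges); the filtration value is the minimum distance from either endpoint
    to that facet, i.e. the smallest ball radius at which the two restricted
    Voronoi regions meet.
    """
    edge_tris: dict[tuple[int, int], list[int]] = {}
    for t, simplex in enumerate(tri.simplices):
        for a in range(3):
            for b in range(a + 1, 3):
                e = tuple(sorted((int(simplex[a]), int(simplex[b]))))
                edge_tris.setdefault(e, []).append(t)

    centers = np.array([
        _circumcenter(points[s[0]], points[s[1]], points[s[2]])
        for s in tri.simplices
    ])

    filtration = {}
    for (i, j), tris in edge_tris.items():
        p, q = points[i], points[j]
        if len(tris) == 2:
            f = _dist_point_to_facet(p, centers[tris[0]], centers[tris[1]], None)
        else:
            # hull edge: Voronoi facet is a ray from the circumcenter, along
            # the bisector, pointing away from the triangle's third vertex
            t = tris[0]
            other = [v for v in tri.simplices[t] if v not in (i, j)][0]
            mid = 0.5 * (p + q)
            direction = mid - points[other]
            edge = q - p
            # project out the edge component: ray runs along the bisector
            direction = direction - (direction @ edge) / (edge @ edge) * edge
            norm = np.linalg.norm(direction)
            if norm == 0:  # degenerate right-angle case
                direction = np.array([-edge[1], edge[0]]) / np.linalg.norm(edge)
            else:
                direction /= norm
            f = _dist_point_to_facet(p, centers[t], None, direction)
        filtration[(i, j)] = f

    # Cocircular degeneracy: several triangles share one circumcenter (a
    # Voronoi vertex where >3 cells meet). Every pair of co-nearest sites
    # touches there, including pairs that are not Delaunay edges (e.g. both
    # diagonals of a square), with filtration = circumradius.
    scale = max(float(np.ptp(points, axis=0).max()), 1e-300)
    keys: dict[tuple, list[int]] = {}
    for t, c in enumerate(centers):
        keys.setdefault(tuple(np.round(c / scale, 9)), []).append(t)
    for tris in keys.values():
        if len(tris) < 2:
            continue
        members = sorted({int(v) for t in tris for v in tri.simplices[t]})
        if len(members) < 4:
            continue
        c = centers[tris[0]]
        radius = float(np.linalg.norm(points[members[0]] - c))
        for a_i, a in enumerate(members):
            for b in members[a_i + 1:]:
                e = (a, b)
                filtration[e] = min(filtration.get(e, np.inf), radius)
    return filtration


def build_alpha_graph(
    coords: np.ndarray, delta: float, fallback_k: int = 15
) -> sp.csr_matrix:
    """Adjacency of the alpha-complex 1-skeleton at radius ``delta``.

    Edge (i, j) is present exactly when the Voronoi region of i restricted to
    the ball B(r_i, delta) intersects that of j. Degenerate inputs where no
    triangulation exists (all points identical, collinear point sets with
    N > 2) fall back to the kNN graph with a logged warning; two points are
    handled directly from the definition (edge iff delta >= d/2).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if delta <= 0:
        return sp.csr_matrix((n, n), dtype=np.int8)
    if coords.shape[1] != 2:
        logger.warning("alpha graph requires 2-D coordinates; falling back to kNN")
        return build_knn_graph(coords, k=min(fallback_k, n - 1))
    if n == 2:
        d = float(np.linalg.norm(coords[0] - coords[1]))
        a = sp.lil_matrix((2, 2), dtype=np.int8)
        if delta >= d / 2:
            a[0, 1] = a[1, 0] = 1
        return a.tocsr()
    try:
        tri = Delaunay(coords)
    except QhullError:
        logger.warning(
            "degenerate point configuration (identical/collinear); "
            "falling back to kNN graph"
        )
        return build_knn_graph(coords, k=min(fallback_k, n - 1))

    filtration = _alpha_edge_filtration(coords, tri)
    rows, cols = [], []
    for (i, j), f in filtration.items():
        if f <= delta:
            rows += [i, j]
            cols += [j, i]
    a = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def build_graph(
    features: FeatureMatrix | np.ndarray,
    coords: np.ndarray,
    method: str = "alpha",
    k: int = 15,
    delta: float | None = None,
) -> SpatialExpressionGraph:
    """Assemble a :class:`SpatialExpressionGraph` from features and coordinates."""
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features)
    coords = np.asarray(coords, dtype=float)
    if method == "alpha":
        if delta is None:
            delta = estimate_delta(coords, k=k)
        A = build_alpha_graph(coords, delta, fallback_k=k)
    elif method == "knn":
        A = build_knn_graph(coords, k=k)
    else:
        raise ValueError(f"unknown graph method {method!r}; use 'alpha' or 'knn'")
    return SpatialExpressionGraph(X=X, A=A, coords=coords, method=method,
                                  delta=delta, k=k)


# ---------------------------------------------------------------------------
# corrupted graph (negative sample)
# ---------------------------------------------------------------------------

def permute_features(seg: SpatialExpressionGraph, seed: int) -> PermutedGraph:
    """Uniform random row permutation of X with A unchanged."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(seg.n_nodes)
    return PermutedGraph(X_tilde=seg.X[perm], A=seg.A, permutation=perm, seed=seed)


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def write_edge_list(seg: SpatialExpressionGraph, path: str) -> None:
    """Two-column TSV of 0-based node indices, one undirected edge per line."""
    pd.DataFrame(seg.edge_list, columns=["i", "j"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str, n_nodes: int) -> sp.csr_matrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    rows = np.concatenate([df["i"].to_numpy(), df["j"].to_numpy()])
    cols = np.concatenate([df["j"].to_numpy(), df["i"].to_numpy()])
    a = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    a.setdiag(0)
    a.eliminate_zeros()
    return a
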