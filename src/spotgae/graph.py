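"""Spatial neighbor graphs over spot coordinates.

Single-slice graphs come in two flavors: a fixed Euclidean radius (sub-cellular
resolution platforms) and covering-radius KNN (lattice platforms, where each
interior spot has a fixed number of equidistant neighbors — 6 on a hex chip).
Covering-radius KNN links each spot to every spot within the distance of its
k-th nearest neighbor, so distance ties are included deterministically.

Two co-registered slices are pooled into one point set (2DSNG).  Stacks of
three or more slices use the 3DSNG rule: within-slice covering-radius KNN plus
cross-slice neighbors only in the immediately adjacent slice(s), each capture
limited to the minimal in-plane radius covering up to ``cross_cap`` spots.
Non-adjacent slices are never linked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .io import SpatialDataset

__all__ = [
    "SpatialNeighborGraph", "build_sng_radius", "build_sng_knn",
    "build_2dsng", "build_3dsng", "build_graph_for_dataset",
]

# guard against float roundoff when re-testing the covering radius;
# genuine inter-spot distances are never this close together
_RTOL = 1e-9


@dataclass
class SpatialNeighborGraph:
    """Symmetric binary adjacency over spots; self-pairs are never stored."""

    n: int
    edges: set  # unordered pairs as (i, j) tuples with i < j
    mode: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loop stored in edge set")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError("edge endpoint out of range")
        self.edges = {(min(i, j), max(i, j)) for i, j in self.edges}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency (no self-loops)."""
        if not self.edges:
            return sp.csr_matrix((self.n, self.n))
        rows, cols = zip(*self.edges)
        rows, cols = np.array(rows), np.array(cols)
        data = np.ones(len(rows))
        a = sp.coo_matrix((data, (rows, cols)), shape=(self.n, self.n))
        return (a + a.T).tocsr()

    def directed_with_self(self) -> tuple[np.ndarray, np.ndarray]:
        """(src, dst) arrays with both edge directions plus all self-loops.

        The aggregation neighborhood N_i contains i itself; the stored graph
        does not, so self-loops are injected here.
        """
        src = [np.arange(self.n)]
        dst = [np.arange(self.n)]
        if self.edges:
            rows, cols = map(np.array, zip(*self.edges))
            src += [rows, cols]
            dst += [cols, rows]
        return np.concatenate(src), np.concatenate(dst)

    def neighbor_sets(self) -> list[set]:
        out: list[set] = [set() for _ in range(self.n)]
        for i, j in self.edges:
            out[i].add(j)
            out[j].add(i)
        return out


def _check_coords(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be N x 2")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return coords


def build_sng_radius(coords, radius: float) -> SpatialNeighborGraph:
    """Edge (i, j) iff 0 < ||c_i - c_j|| < radius (strict on both sides)."""
    coords = _check_coords(coords)
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(coords)
    edges = set()
    for i, j in tree.query_pairs(radius):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if 0.0 < d < radius:
            edges.add((min(i, j), max(i, j)))
    return SpatialNeighborGraph(len(coords), edges, "radius",
                                {"radius": radius})


def _covering_knn_edges(tree_src: cKDTree, pts: np.ndarray, tree_dst: cKDTree,
                        k: int) -> list[list[int]]:
    """For each point, indices (into tree_dst's data) within its minimal
    radius covering k points of the target set.  When source and target sets
    coincide, the point itself is part of the covered set and is removed by
    the caller."""
    dists, _ = tree_dst.query(pts, k=k)
    if k == 1:
        dists = dists[:, None]
    r = dists[:, -1] * (1.0 + _RTOL)
    return tree_dst.query_ball_point(pts, r)


def build_sng_knn(coords, k: int) -> SpatialNeighborGraph:
    """Covering-radius KNN: link each spot to all spots within the distance
    of its k-th nearest neighbor (ties at that distance included); the edge
    set is symmetrized by union."""
    coords = _check_coords(coords)
    n = len(coords)
    if not (1 <= k < n):
        raise ValueError(f"need 1 <= k < N, got k={k}, N={n}")
    tree = cKDTree(coords)
    # k+1 because the query set contains the point itself at distance 0
    hits = _covering_knn_edges(tree, coords, tree, k + 1)
    edges = set()
    for i, nbrs in enumerate(hits):
        for j in nbrs:
            if j != i:
                edges.add((min(i, j), max(i, j)))
    return SpatialNeighborGraph(n, edges, "knn", {"k": k})


def build_2dsng(slices: list[SpatialDataset], k: int = 6) -> SpatialNeighborGraph:
    """Pool two co-registered slices into one point set and apply KNN."""
    if len(slices) != 2:
        if len(slices) > 2:
            raise ValueError("more than 2 slices: use build_3dsng")
        raise ValueError("build_2dsng needs exactly 2 slices")
    coords = np.vstack([s.coords for s in slices])
    g = build_sng_knn(coords, k)
    g.mode = "sng2d"
    g.params = {"k": k, "n_slices": 2}
    return g


def build_3dsng(slices: list[SpatialDataset], k_intra: int = 6,
                cross_cap: int = 7) -> SpatialNeighborGraph:
    """Stacked-slice graph: within-slice KNN plus adjacent-slice capture.

    Slice order is the vertical stacking order.  For every spot, cross-slice
    neighbors are taken only from the immediately adjacent slice(s), within
    the minimal in-plane radius covering up to ``cross_cap`` spots of that
    slice.  Consecutive slice pairs are scanned in both directions so no
    adjacency is missed; slices two or more apart are never linked.
    """
    if len(slices) < 3:
        raise ValueError("fewer than 3 slices: use build_2dsng (2) or "
                         "build_sng_knn (1)")
    counts = [s.n_spots for s in slices]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    n_total = int(offsets[-1])
    edges: set = set()

    trees = [cKDTree(s.coords) for s in slices]
    # within-slice
    for s_idx, ds in enumerate(slices):
        g = build_sng_knn(ds.coords, k_intra)
        off = offsets[s_idx]
        edges |= {(i + off, j + off) for i, j in g.edges}
    # adjacent-slice capture, both directions of each consecutive pair
    for a in range(len(slices) - 1):
        b = a + 1
        for src_s, dst_s in ((a, b), (b, a)):
            cap = min(cross_cap, counts[dst_s])
            hits = _covering_knn_edges(
                trees[src_s], slices[src_s].coords, trees[dst_s], cap)
            off_src, off_dst = offsets[src_s], offsets[dst_s]
            for i, nbrs in enumerate(hits):
                gi = i + off_src
                for j in nbrs:
                    gj = j + off_dst
                    edges.add((min(gi, gj), max(gi, gj)))
    return SpatialNeighborGraph(n_total, edges, "sng3d",
                                {"k_intra": k_intra, "cross_cap": cross_cap,
                                 "n_slices": len(slices)})


def build_graph_for_dataset(dataset: SpatialDataset, k: int = 6,
                            radius: float | None = None,
                            cross_cap: int = 7) -> SpatialNeighborGraph:
    """Dispatch on slice count: 1 slice -> KNN (or radius if given),
    2 slices -> pooled 2DSNG, >= 3 -> 3DSNG."""
    n_slices = dataset.n_slices
    if n_slices > 1 and np.any(np.diff(dataset.slice_idx) < 0):
        raise ValueError("multi-slice dataset rows must be grouped by slice "
                         "in ascending order for graph/row correspondence")
    if n_slices == 1:
        if radius is not None:
            return build_sng_radius(dataset.coords, radius)
        return build_sng_knn(dataset.coords, k)
    parts = dataset.subset_slices(list(range(1, n_slices + 1)))
    if n_slices == 2:
        return build_2dsng(parts, k)
    return build_3dsng(parts, k_intra=k, cross_cap=cross_cap)
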