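"""Exact k-nearest-neighbour graph over bead pixel positions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist


@dataclass
class SpatialGraph:
    """kNN graph in pixel space.

    ``neighbors[i]`` are the indices of bead i's min(k, n-1) nearest beads
    (ties broken by ascending bead index), ``distances[i]`` the matching
    Euclidean distances. Adjacency queries use the symmetrized edge set:
    i and j are adjacent iff either lists the other.
    """

    neighbors: np.ndarray  # (n, k') int
    distances: np.ndarray  # (n, k') float
    k: int

    @property
    def n_beads(self) -> int:
        return self.neighbors.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        """Symmetrized boolean adjacency (no self loops)."""
        n, kk = self.neighbors.shape
        rows = np.repeat(np.arange(n), kk)
        cols = self.neighbors.ravel()
        A = sp.coo_matrix((np.ones(rows.size, bool), (rows, cols)), shape=(n, n))
        A = (A + A.T).tocsr()
        A.data[:] = True
        A.setdiag(False)
        A.eliminate_zeros()
        return A

    def n_components(self) -> int:
        return int(sp.csgraph.connected_components(self.adjacency(), directed=False)[0])

    def smoothing_lists(self) -> list[np.ndarray]:
        """Per bead: itself plus its own neighbour list (for local averaging)."""
        n = self.n_beads
        return [np.concatenate(([i], self.neighbors[i])) for i in range(n)]


def build_spatial_knn(positions: np.ndarray, k: int, *, block: int = 1024) -> SpatialGraph:
    """Exact kNN under Euclidean pixel distance; ties by ascending index.

    Duplicated coordinates are allowed (zero distances permitted). Computed
    by blockwise all-pairs scan, so the result is exact for any point set.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if k <= 0:
        raise ValueError("k must be positive")
    if n < 2:
        raise ValueError("need at least two beads")
    kk = min(k, n - 1)
    nbr = np.empty((n, kk), dtype=np.int64)
    dst = np.empty((n, kk), dtype=float)
    idx = np.arange(n)
    for start in range(0, n, block):
        stop = min(start + block, n)
        D = cdist(positions[start:stop], positions)
        for r, i in enumerate(range(start, stop)):
            d = D[r].copy()
            d[i] = np.inf  # exclude self
            order = np.lexsort((idx, d))[:kk]
            nbr[i] = order
            dst[i] = d[order]
    return SpatialGraph(neighbors=nbr, distances=dst, k=k)
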