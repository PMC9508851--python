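"""Entropy-guided spatially constrained agglomerative clustering.

The method models bead similarity twice: P, a row-stochastic conditional
probability matrix in expression (PCA) space with per-bead Gaussian
bandwidths calibrated to a target perplexity; and Q, the distribution a
spatial partition induces (uniform over a bead's cluster mates, with a tiny
floor mass elsewhere). The quality of a partition is the cross-entropy
H(P, Q) = -(1/n) sum_i sum_j p(j|i) log q(j|i). Starting from singleton
clusters, the algorithm repeatedly merges the pair of spatially adjacent
clusters whose merge increases H the least, producing a dendrogram that is
cut at the requested number of clusters. Clusters are therefore always
unions of spatially connected subgraphs of the bead kNN graph (except for
logged bridging merges joining disconnected tissue fragments).

For a cluster C of size s in a slide of n beads the induced distribution is

    q(j|i) = (1 - delta) / (s - 1)   for j in C \\ {i}
    q(j|i) = epsilon                 otherwise, delta = epsilon * (n - s)

(singletons place all mass on the floor). Summing over the beads of one
cluster collapses the cross-entropy into per-cluster terms that depend only
on s and on W(C), the total P-mass between members of C:

    n * H = sum_C [ -W(C) * log((1 - delta)/(s - 1)) - (s - W(C)) * log eps ]

so the change from merging A and B depends only on sizes, W(A), W(B) and the
cross mass X(A, B) between them — all maintainable incrementally, which makes
every greedy step exact (identical to recomputing H from scratch) at a cost
independent of n.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .spatial_graph import SpatialGraph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA embedding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingMatrix:
    """Bead x component PCA scores with per-component variance fractions."""

    scores: np.ndarray
    loadings: np.ndarray           # component x gene
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_embed(X, n_components: int) -> EmbeddingMatrix:
    """PCA of the (bead x gene) expression matrix, columns centered first.

    Deterministic up to sign; signs are fixed by making each component's
    largest-magnitude loading positive. If ``n_components`` exceeds the rank
    of the centered data the returned components are truncated to the rank.
    """
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    n, g = X.shape
    if not 1 <= n_components <= min(n, g):
        raise ValueError(f"n_components must lie in [1, {min(n, g)}]")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(n, g) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components > rank:
        logger.warning("requested %d components but rank is %d; truncating", n_components, rank)
        n_components = max(rank, 1)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(n_components), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = U * (s * flip)[None, :]
    total_var = (Xc**2).sum() / max(n - 1, 1)
    var = s**2 / max(n - 1, 1)
    frac = var / total_var if total_var > 0 else np.zeros_like(var)
    return EmbeddingMatrix(scores=scores, loadings=Vt, variance_fraction=frac)


# ---------------------------------------------------------------------------
# conditional affinities
# ---------------------------------------------------------------------------

@dataclass
class AffinityModel:
    """Sparse row-stochastic conditional probabilities p(j|i).

    Each row is supported on the bead's ``m`` nearest candidates in embedding
    space, with a Gaussian kernel whose bandwidth sigma_i is bisected so the
    realized perplexity 2^H(p_i) hits min(u, m).
    """

    P: sp.csr_matrix
    sigma: np.ndarray
    perplexity: float
    m: int
    realized_perplexity: np.ndarray
    converged: np.ndarray

    def check(self, atol_row: float = 1e-9, atol_perp: float = 1e-3) -> None:
        rows = np.asarray(self.P.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=atol_row):
            raise AssertionError("affinity rows do not sum to 1")
        if np.abs(self.P.diagonal()).max(initial=0.0) > 0:
            raise AssertionError("p(i|i) must be 0")
        target = min(self.perplexity, self.m)
        bad = np.abs(self.realized_perplexity - target) > atol_perp
        if (bad & self.converged).any():
            raise AssertionError("converged row misses target perplexity")


def _calibrate_row(d2: np.ndarray, target_perp: float, max_iter: int = 100,
                   tol: float = 1e-6) -> tuple[np.ndarray, float, float, bool]:
    """Bisect the precision beta = 1/(2 sigma^2) to the target perplexity."""
    target_h = math.log(target_perp)  # entropy in nats

    def row(beta: float) -> tuple[np.ndarray, float]:
        e = np.exp(-(d2 - d2.min()) * beta)
        p = e / e.sum()
        nz = p > 0
        h = float(-(p[nz] * np.log(p[nz])).sum())
        return p, h

    beta, lo, hi = 1.0, 0.0, math.inf
    p, h = row(beta)
    converged = False
    for _ in range(max_iter):
        if abs(h - target_h) < tol:
            converged = True
            break
        if h > target_h:   # too flat: sharpen
            lo = beta
            beta = beta * 2 if hi is math.inf else (beta + hi) / 2
        else:
            hi = beta
            beta = (lo + beta) / 2
        p, h = row(beta)
    sigma = math.sqrt(1.0 / (2.0 * beta))
    return p, sigma, math.exp(h), converged


def conditional_affinities(
    E: EmbeddingMatrix | np.ndarray,
    perplexity: float = 35.0,
    *,
    n_candidates: int | None = None,
) -> AffinityModel:
    """Perplexity-calibrated conditional affinities in embedding space.

    Candidates are each bead's min(3u, n-1) nearest beads under Euclidean
    embedding distance (n_candidates overrides). Each row is an isotropic
    Gaussian over its candidates, bandwidth bisected so the realized
    perplexity equals min(u, m) within 1e-3; rows that fail to converge in
    100 bisection steps keep the last midpoint and are flagged.
    """
    Y = E.scores if isinstance(E, EmbeddingMatrix) else np.asarray(E, dtype=float)
    n = Y.shape[0]
    if perplexity < 1:
        raise ValueError("perplexity must be >= 1")
    m = min(int(math.ceil(3 * perplexity)), n - 1) if n_candidates is None \
        else min(int(n_candidates), n - 1)
    if m < 2:
        raise ValueError("need at least two candidates per bead")
    nn = NearestNeighbors(n_neighbors=m + 1).fit(Y)
    dist, idx = nn.kneighbors(Y)
    # drop self (always first at distance 0 for distinct points)
    self_col = idx == np.arange(n)[:, None]
    keep = ~self_col
    keep[~self_col.any(axis=1), -1] = False  # duplicate coords: drop last instead
    idx = idx[keep].reshape(n, m)
    d2 = (dist[keep].reshape(n, m)) ** 2

    target = min(perplexity, m)
    rows_p = np.empty((n, m))
    sigma = np.empty(n)
    realized = np.empty(n)
    converged = np.empty(n, dtype=bool)
    for i in range(n):
        rows_p[i], sigma[i], realized[i], converged[i] = _calibrate_row(d2[i], target)
    if not converged.all():
        logger.warning("%d affinity rows did not converge to target perplexity",
                       int((~converged).sum()))
    P = sp.csr_matrix(
        (rows_p.ravel(), idx.ravel(), np.arange(0, n * m + 1, m)), shape=(n, n)
    )
    return AffinityModel(P=P, sigma=sigma, perplexity=perplexity, m=m,
                         realized_perplexity=realized, converged=converged)


# ---------------------------------------------------------------------------
# partition cross-entropy
# ---------------------------------------------------------------------------

def _check_epsilon(n: int, epsilon: float) -> None:
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if epsilon * (n - 1) >= 1:
        raise ValueError(f"epsilon {epsilon} too large: floor mass would exceed 1")


def partition_cross_entropy(P: AffinityModel | sp.spmatrix, labels: np.ndarray,
                            epsilon: float = 1e-12) -> float:
    """Cross-entropy H(P, Q) of a partition, computed directly from rows.

    Q gives each bead a uniform distribution over its cluster mates with an
    epsilon floor off-cluster; a singleton bead's whole row falls on the
    floor. Smaller H means the partition models P more faithfully.
    """
    Pm = P.P if isinstance(P, AffinityModel) else sp.csr_matrix(P)
    labels = np.asarray(labels)
    n = Pm.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per bead")
    _check_epsilon(n, epsilon)
    coo = Pm.tocoo()
    same = labels[coo.row] == labels[coo.col]
    m_in = np.bincount(coo.row[same], weights=coo.data[same], minlength=n)
    row_sum = np.bincount(coo.row, weights=coo.data, minlength=n)
    sizes = np.bincount(labels, minlength=labels.max() + 1)
    s = sizes[labels].astype(float)
    log_eps = math.log(epsilon)
    contrib = np.where(
        s >= 2,
        -m_in * np.log(np.where(s >= 2, (1 - epsilon * (n - s)) / np.maximum(s - 1, 1), 1.0))
        - (row_sum - m_in) * log_eps,
        -row_sum * log_eps,
    )
    return float(contrib.sum() / n)


# ---------------------------------------------------------------------------
# greedy agglomeration
# ---------------------------------------------------------------------------

@dataclass
class MergeRecord:
    step: int
    left: int
    right: int
    delta_h: float
    size: int
    bridged: bool = False


@dataclass
class PartitionState:
    """Final partition plus the merge dendrogram."""

    labels: np.ndarray                 # per bead, 1-based, size-ordered
    members: dict[int, list[int]]      # final label -> bead indices
    merge_log: list[MergeRecord]
    cross_entropy: float
    n_initial: int
    bridged_steps: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def dendrogram_json(self) -> list[dict]:
        return [
            {"step": r.step, "left": r.left, "right": r.right,
             "delta_h": r.delta_h, "size": r.size, "bridged": r.bridged}
            for r in self.merge_log
        ]


def agglomerate(
    P: AffinityModel,
    G: SpatialGraph,
    target_k: int,
    *,
    epsilon: float = 1e-12,
    positions: np.ndarray | None = None,
    bridge: bool = True,
) -> PartitionState:
    """Greedy cross-entropy agglomeration of spatially adjacent clusters.

    Starts from singletons; at every step merges the adjacent cluster pair
    with the minimal cross-entropy increase (ties broken lexicographically on
    the (smaller id, larger id) pair); stops at ``target_k`` clusters. When
    the spatial graph is disconnected and ``bridge`` is on, exhausted
    components are joined by nearest-centroid merges (logged as bridged);
    with bridging off the algorithm stops at the component count and warns.
    ``positions`` (bead pixel coordinates) are required only for bridging.
    """
    n = P.P.shape[0]
    if G.n_beads != n:
        raise ValueError("affinity model and spatial graph disagree on bead count")
    if not 1 <= target_k <= n:
        raise ValueError(f"target_k must lie in [1, {n}]")
    _check_epsilon(n, epsilon)
    log_eps = math.log(epsilon)

    def contrib(s: int, W: float) -> float:
        if s == 1:
            return -log_eps
        return -W * math.log((1 - epsilon * (n - s)) / (s - 1)) - (s - W) * log_eps

    # cluster state; surviving id after a merge is the smaller one
    alive = np.ones(n, dtype=bool)
    size = np.ones(n, dtype=np.int64)
    W = np.zeros(n)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    version = np.zeros(n, dtype=np.int64)

    # cross P-mass between clusters (both directions), sparse per-cluster maps
    xmap: list[dict[int, float]] = [dict() for _ in range(n)]
    coo = P.P.tocoo()
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if i == j:
            continue
        a, b = (int(i), int(j)) if i < j else (int(j), int(i))
        xmap[a][b] = xmap[a].get(b, 0.0) + float(v)
    for a in range(n):
        for b, v in xmap[a].items():
            xmap[b][a] = v

    adj: list[set[int]] = [set() for _ in range(n)]
    A = G.adjacency().tocoo()
    for i, j in zip(A.row, A.col):
        if i != j:
            adj[int(i)].add(int(j))

    def delta_h(a: int, b: int) -> float:
        x = xmap[a].get(b, 0.0)
        merged = contrib(int(size[a] + size[b]), W[a] + W[b] + x)
        return (merged - contrib(int(size[a]), W[a]) - contrib(int(size[b]), W[b])) / n

    heap: list[tuple[float, int, int, int, int]] = []
    for a in range(n):
        for b in adj[a]:
            if a < b:
                heap.append((delta_h(a, b), a, b, 0, 0))
    heapq.heapify(heap)

    merge_log: list[MergeRecord] = []
    h_current = float(-log_eps)  # all-singleton cross-entropy (rows sum to 1)
    n_clusters = n
    bridged_steps = 0
    step = 0

    def centroid(c: int) -> np.ndarray:
        return positions[members[c]].mean(axis=0)

    while n_clusters > target_k:
        pair = None
        while heap:
            dh, a, b, va, vb = heapq.heappop(heap)
            if alive[a] and alive[b] and version[a] == va and version[b] == vb:
                pair = (a, b, dh, False)
                break
        if pair is None:
            # remaining clusters are mutually non-adjacent (separate components)
            if not bridge or positions is None or n_clusters <= 1:
                logger.warning(
                    "spatial graph exhausted at %d clusters (target %d); "
                    "bridging %s", n_clusters, target_k,
                    "disabled" if not bridge else "impossible without positions")
                break
            ids = np.flatnonzero(alive)
            cents = np.array([centroid(c) for c in ids])
            d = ((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d, np.inf)
            ai, bi = np.unravel_index(int(d.argmin()), d.shape)
            a, b = int(min(ids[ai], ids[bi])), int(max(ids[ai], ids[bi]))
            pair = (a, b, delta_h(a, b), True)
            bridged_steps += 1

        a, b, dh, bridged = pair
        step += 1
        W[a] += W[b] + xmap[a].pop(b, 0.0)
        xmap[b].pop(a, None)
        size[a] += size[b]
        members[a].extend(members.pop(b))
        alive[b] = False
        for other, v in xmap[b].items():
            xmap[other].pop(b, None)
            xmap[a][other] = xmap[a].get(other, 0.0) + v
            xmap[other][a] = xmap[a][other]
        xmap[b] = {}
        adj[b].discard(a)
        adj[a].discard(b)
        for d_ in adj[b]:
            adj[d_].discard(b)
            adj[d_].add(a)
            adj[a].add(d_)
        adj[b] = set()
        version[a] += 1
        version[b] += 1
        h_current += dh
        merge_log.append(MergeRecord(step=step, left=a, right=b, delta_h=dh,
                                     size=int(size[a]), bridged=bridged))
        n_clusters -= 1
        for d_ in adj[a]:
            lo, hi = (a, d_) if a < d_ else (d_, a)
            heapq.heappush(heap, (delta_h(lo, hi), lo, hi,
                                  int(version[lo]), int(version[hi])))

    # final labels: 1..K by decreasing size, ties by smallest member index
    final = sorted(
        (c for c in range(n) if alive[c]),
        key=lambda c: (-int(size[c]), min(members[c])),
    )
    labels = np.empty(n, dtype=np.int64)
    out_members: dict[int, list[int]] = {}
    for rank, c in enumerate(final, start=1):
        out_members[rank] = sorted(members[c])
        labels[out_members[rank]] = rank
    return PartitionState(
        labels=labels,
        members=out_members,
        merge_log=merge_log,
        cross_entropy=h_current,
        n_initial=n,
        bridged_steps=bridged_steps,
    )
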