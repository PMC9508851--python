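"""Cluster expression profiles, marker calling, profile trees, cross-slide PCA.

A cluster's profile is the per-gene arithmetic mean of the normalized layer
over its beads. Markers ("preferential" genes) are called per cluster by a
three-part rule: fold change of depth-normalized means versus all other
beads, in-cluster detection fraction, and a Wilcoxon rank-sum test with
Benjamini-Hochberg control across genes within the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, ranksums
from statsmodels.stats.multitest import multipletests

from .core_io import SpatialExpressionMatrix, validate_assignment

logger = logging.getLogger(__name__)

_LFC_EPS = 1e-9  # pseudocount protecting the fold ratio at zero means


@dataclass
class ClusterProfileSet:
    """Per-cluster mean expression (clusters x genes) with cluster sizes."""

    profiles: pd.DataFrame   # index: cluster label; columns: gene ids
    n_beads: pd.Series       # index: cluster label

    def __post_init__(self) -> None:
        if not self.profiles.index.equals(self.n_beads.index):
            raise ValueError("profiles and n_beads must share the cluster index")


def _labels_array(M: SpatialExpressionMatrix, assignment: pd.Series) -> np.ndarray:
    validate_assignment(assignment)
    missing = [b for b in M.bead_ids if b not in assignment.index]
    if missing:
        raise ValueError(f"{len(missing)} beads lack a cluster label, e.g. {missing[:5]}")
    return assignment.loc[M.bead_ids].to_numpy(int)


def cluster_profiles(M: SpatialExpressionMatrix, assignment: pd.Series,
                     *, layer: str = "normalized") -> ClusterProfileSet:
    """Arithmetic mean of the given layer per gene per cluster."""
    labels = _labels_array(M, assignment)
    X = M.layer(layer)
    out = {}
    sizes = {}
    for lab in np.unique(labels):
        mask = labels == lab
        out[int(lab)] = np.asarray(X[mask].mean(axis=0)).ravel()
        sizes[int(lab)] = int(mask.sum())
    profiles = pd.DataFrame.from_dict(out, orient="index", columns=M.gene_ids)
    profiles.index.name = "cluster"
    return ClusterProfileSet(profiles=profiles, n_beads=pd.Series(sizes, name="n_beads"))


def preferential_genes(
    M: SpatialExpressionMatrix,
    assignment: pd.Series,
    *,
    min_fold: float = 2.0,
    min_detect: float = 0.25,
    fdr: float = 0.05,
    layer: str = "normalized",
) -> pd.DataFrame:
    """Marker table over all (gene, cluster) pairs.

    Columns: gene_id, cluster, log2_fold, detect_fraction, pvalue, qvalue,
    preferential. Fold is the ratio of in-cluster to out-of-cluster mean
    depth-normalized expression (expm1 of the normalized layer); the rank-sum
    test compares normalized values of member beads against all other beads;
    BH is applied across genes within each cluster. Size-1 clusters cannot be
    tested and are skipped with a log message.
    """
    labels = _labels_array(M, assignment)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("marker calling needs at least two clusters")
    X = np.asarray(sp.csr_matrix(M.layer(layer)).todense())
    detected = np.asarray((M.counts > 0).todense())
    linear = np.expm1(X)

    frames = []
    for lab in uniq:
        mask = labels == lab
        if mask.sum() < 2:
            logger.info("cluster %d has a single bead; rank-sum undefined, skipped", lab)
            continue
        mean_in = linear[mask].mean(axis=0)
        mean_out = linear[~mask].mean(axis=0)
        log2_fold = np.log2((mean_in + _LFC_EPS) / (mean_out + _LFC_EPS))
        detect = detected[mask].mean(axis=0)
        pvals = ranksums(X[mask], X[~mask], alternative="greater", axis=0).pvalue
        pvals = np.nan_to_num(pvals, nan=1.0)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        flagged = (
            (2.0**log2_fold >= min_fold) & (detect >= min_detect) & (qvals < fdr)
        )
        frames.append(pd.DataFrame(
            {
                "gene_id": M.gene_ids,
                "cluster": int(lab),
                "log2_fold": log2_fold,
                "detect_fraction": detect,
                "pvalue": pvals,
                "qvalue": qvals,
                "preferential": flagged,
            }
        ))
    return pd.concat(frames, ignore_index=True)


def profile_tree(profile_set: ClusterProfileSet) -> dict:
    """Complete-linkage dendrogram of clusters under 1 - Pearson distance.

    Returns ``{"linkage": scipy linkage matrix, "labels": cluster labels,
    "newick": text}``. A zero-variance profile makes the correlation
    undefined and is an error naming the cluster.
    """
    P = profile_set.profiles
    if len(P) < 2:
        raise ValueError("need at least two profiles")
    vals = P.to_numpy(float)
    sd = vals.std(axis=1)
    flat = P.index[sd == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance profile(s) for cluster(s) {flat}")
    corr = np.corrcoef(vals)
    dist = squareform(1.0 - corr, checks=False)
    Z = sch.linkage(dist, method="complete")
    labels = [str(l) for l in P.index]
    return {"linkage": Z, "labels": labels, "newick": _to_newick(Z, labels)}


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = sch.to_tree(Z)

    def rec(node, parent_dist) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cross_slide_pca(profile_sets: dict[str, ClusterProfileSet],
                    n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of cluster profiles merged across slides.

    Rows are (slide, cluster) pairs; columns the union of genes across the
    slides, genes missing from a slide imputed as 0. Each gene is centered
    and scaled to unit variance before decomposition; zero-variance genes are
    dropped and logged. Returns the score frame and variance fractions.
    """
    from .cluster import pca_embed

    rows = []
    index = []
    genes = sorted(set().union(*(set(ps.profiles.columns) for ps in profile_sets.values())))
    for slide, ps in profile_sets.items():
        block = ps.profiles.reindex(columns=genes, fill_value=0.0)
        rows.append(block.to_numpy(float))
        index.extend((slide, int(c)) for c in ps.profiles.index)
    X = np.vstack(rows)
    sd = X.std(axis=0)
    dropped = int((sd == 0).sum())
    if dropped:
        logger.info("dropping %d zero-variance genes before cross-slide PCA", dropped)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    emb = pca_embed(Z, min(n_components, min(Z.shape)))
    scores = pd.DataFrame(
        emb.scores,
        index=pd.MultiIndex.from_tuples(index, names=["slide", "cluster"]),
        columns=[f"PC{i + 1}" for i in range(emb.n_components)],
    )
    return scores, emb.variance_fraction


def pseudobulk_correlation(M: SpatialExpressionMatrix, bulk: pd.Series
                           ) -> tuple[int, float]:
    """Pearson correlation of the slide pseudo-bulk against a bulk profile.

    Shared genes are those detected (total > 0) in both inputs; the
    correlation is computed on log1p of the summed slide counts versus log1p
    of the bulk values. Returns (n_shared_genes, correlation).
    """
    pseudo = pd.Series(np.asarray(M.counts.sum(axis=0)).ravel(), index=M.gene_ids)
    shared = [g for g in pseudo.index if pseudo[g] > 0 and g in bulk.index and bulk[g] > 0]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared detected genes; need >= 3")
    r = pearsonr(np.log1p(pseudo[shared].to_numpy(float)),
                 np.log1p(bulk[shared].to_numpy(float))).statistic
    return len(shared), float(r)
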