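"""Occupancy filters and depth normalization.

Valid beads own at least a fraction (default 0.5%) of all expressed genes;
valid genes are detected in at least a fraction (default 0.05%) of beads.
Both thresholds are applied with ceil and >=, in one pass each, beads first.
Downstream distance computations use the ``"normalized"`` layer: per-bead
depth scaled to the median total count, then log(1 + x).
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp

from .core_io import SpatialExpressionMatrix


def filter_valid_beads(M: SpatialExpressionMatrix, min_gene_fraction: float = 0.005
                       ) -> SpatialExpressionMatrix:
    """Keep beads detecting at least ceil(fraction * n_expressed_genes) genes.

    "Expressed genes" are the genes with a positive total count in the input;
    occupancies are computed once, on the input, in a single pass.
    """
    if M.n_beads == 0:
        raise ValueError("empty matrix")
    if not 0 < min_gene_fraction < 1:
        raise ValueError("min_gene_fraction must be in (0, 1)")
    n_expressed = int((np.asarray(M.counts.sum(axis=0)).ravel() > 0).sum())
    threshold = math.ceil(min_gene_fraction * n_expressed)
    genes_per_bead = M.counts.getnnz(axis=1)
    keep = genes_per_bead >= threshold
    if not keep.any():
        raise ValueError(
            f"no bead detects >= {threshold} genes "
            f"(max per-bead occupancy seen: {int(genes_per_bead.max())})"
        )
    return M.subset_beads(keep)


def filter_valid_genes(M: SpatialExpressionMatrix, min_bead_fraction: float = 0.0005
                       ) -> SpatialExpressionMatrix:
    """Keep genes detected in at least ceil(fraction * n_beads) beads."""
    if M.n_genes == 0:
        raise ValueError("empty matrix")
    if not 0 < min_bead_fraction < 1:
        raise ValueError("min_bead_fraction must be in (0, 1)")
    threshold = math.ceil(min_bead_fraction * M.n_beads)
    beads_per_gene = M.counts.getnnz(axis=0)
    keep = beads_per_gene >= threshold
    if not keep.any():
        raise ValueError(
            f"no gene detected in >= {threshold} beads "
            f"(max per-gene occupancy seen: {int(beads_per_gene.max())})"
        )
    return M.subset_genes(keep)


def normalize(M: SpatialExpressionMatrix, *, target: float | None = None
              ) -> SpatialExpressionMatrix:
    """Attach the ``"normalized"`` layer: depth-scale then log1p.

    Each bead's counts are scaled so its total equals the median bead total
    (or ``target`` if given), then log(1 + x) is applied. Counts are left
    untouched. The result is invariant to a global rescaling of depth.
    """
    totals = np.asarray(M.counts.sum(axis=1)).ravel()
    assert (totals > 0).all(), "normalize requires filtered input (no empty beads)"
    scale_to = float(np.median(totals)) if target is None else float(target)
    norm = sp.csr_matrix(M.counts, dtype=float, copy=True)
    norm.data *= np.repeat(scale_to / totals, np.diff(norm.indptr))
    norm.data = np.log1p(norm.data)
    M.layers["normalized"] = norm
    return M
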