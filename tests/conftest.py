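import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spotatlas import DomainLayout, SpatialExpressionMatrix, generate_slide, preprocess


def make_matrix(counts, xy=None, bead_ids=None, gene_ids=None) -> SpatialExpressionMatrix:
    """Small in-memory slide from a dense count array (helper, not a fixture)."""
    counts = np.asarray(counts)
    n, g = counts.shape
    bead_ids = bead_ids or [f"b{i}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    if xy is None:
        xy = np.c_[np.arange(n, dtype=float), np.zeros(n)]
    positions = pd.DataFrame(
        {
            "array_row": np.zeros(n, int),
            "array_col": np.arange(n),
            "x": np.asarray(xy)[:, 0],
            "y": np.asarray(xy)[:, 1],
            "in_tissue": True,
        },
        index=pd.Index(bead_ids),
    )
    return SpatialExpressionMatrix(
        bead_ids=np.array(bead_ids, dtype=object),
        gene_ids=np.array(gene_ids, dtype=object),
        counts=sp.csr_matrix(counts),
        positions=positions,
    )


@pytest.fixture(scope="session")
def bench_slide():
    """The standard recovery benchmark: 600 beads, 200 genes, 4 Voronoi
    domains, 10 markers per domain at fold 8."""
    return generate_slide(
        600, 200, layout=DomainLayout("voronoi", 4),
        markers_per_domain=10, marker_fold=8.0, seed=0,
    )


@pytest.fixture(scope="session")
def bench_normalized(bench_slide):
    M, truth = bench_slide
    M = preprocess.filter_valid_beads(M)
    M = preprocess.filter_valid_genes(M)
    M = preprocess.normalize(M)
    return M, truth


def truth_labels_for(M, truth):
    """Planted domain labels aligned to the (possibly filtered) bead set."""
    index = {b: i for i, b in enumerate(f"bead_{i:05d}" for i in range(len(truth.domain_label)))}
    return np.array([truth.domain_label[index[b]] for b in M.bead_ids])
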