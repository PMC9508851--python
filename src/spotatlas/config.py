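"""Pipeline configuration.

All thresholds of the analysis live here so a run is fully described by one
object (plus the input and the seed). Defaults are the pipeline's standard
operating point: bead/gene occupancy fractions, the spatial-Gini selection
threshold, PCA depth, spatial-graph size, affinity perplexity, and the number
of clusters at the dendrogram cut.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping


@dataclass
class PipelineConfig:
    """Parameters controlling every stage of the atlas pipeline.

    Parameters
    ----------
    min_gene_fraction_per_bead
        A bead is valid if it detects at least this fraction of all expressed
        genes (default 0.5%).
    min_bead_fraction_per_gene
        A gene is valid if it is detected in at least this fraction of beads
        (default 0.05%).
    gini_threshold
        Spatially varying genes are those with spatial Gini score >= this.
    pca_components
        Number of principal components of the SVG expression matrix used as
        the embedding for affinities.
    spatial_neighbors
        k of the spatial k-nearest-neighbour graph (merge adjacency).
    perplexity
        Target perplexity (effective neighbour count) of the conditional
        affinity rows in embedding space.
    target_clusters
        Number of clusters at the dendrogram cut.
    kmeans_groups
        Number of temporal groups for the stage-dynamics K-means.
    fdr_threshold
        BH false-discovery-rate threshold for marker calling and enrichment.
    gini_smooth
        Score genes on spatial-neighbour-mean smoothed expression (the
        "spatial" Gini variant) rather than raw per-bead values.
    keep_out_of_tissue
        Keep beads flagged as outside the tissue when reading a dataset.
    random_seed
        Seed for every stochastic stage (synthesis, K-means restarts).
    """

    min_gene_fraction_per_bead: float = 0.005
    min_bead_fraction_per_gene: float = 0.0005
    gini_threshold: float = 0.5
    pca_components: int = 20
    spatial_neighbors: int = 20
    perplexity: float = 35.0
    target_clusters: int = 40
    kmeans_groups: int = 6
    fdr_threshold: float = 0.05
    epsilon: float = 1e-12
    marker_min_fold: float = 2.0
    marker_min_detect: float = 0.25
    gini_smooth: bool = True
    keep_out_of_tissue: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_gene_fraction_per_bead", "min_bead_fraction_per_gene"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.perplexity < 1:
            raise ValueError(f"perplexity must be >= 1; got {self.perplexity}")
        if self.target_clusters < 1:
            raise ValueError("target_clusters must be >= 1")
        if self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")
        if self.spatial_neighbors < 1:
            raise ValueError("spatial_neighbors must be >= 1")
        if not 0.0 <= self.gini_threshold < 1.0:
            raise ValueError("gini_threshold must lie in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        """Build a config from a flat mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))
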