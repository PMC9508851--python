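# spotatlas

Construction of spatial-transcriptomics atlases of developing tissue, built
for sectioned flower buds profiled on bead-array slides (55 µm spots, each
mixing a few cells). The package takes spot-level UMI count matrices with 2D
spot coordinates (Matrix Market counts + barcodes/features/positions tables)
and produces a tissue-domain atlas: valid-bead/valid-gene occupancy filters,
detection of spatially varying genes (SVGs) by a spatial Gini score,
entropy-guided spatially constrained clustering of beads, per-cluster
expression profiles with preferential (marker) gene calls, cross-stage
expression-dynamics grouping, and category over-representation analysis.
A synthetic-slide generator with full ground truth makes every stage
testable without any download.

## The method

**Occupancy filters.** A bead is *valid* if it detects ≥ 0.5% of all
expressed genes; a gene is *valid* if detected in ≥ 0.05% of beads
(both with ⌈·⌉ and ≥, beads first, one pass each). Expression is then
depth-normalized per bead to the median total and log(1+x)-transformed.

**Spatially varying genes.** Each gene's spatial Gini score is

G = Σᵢⱼ |xᵢ − xⱼ| / (2 n² μ),

the Gini coefficient of its depth-normalized expression over beads, after
replacing each bead's value with the mean over the bead and its k = 20
spatial nearest neighbours. Smoothing cancels bead-level sampling noise but
preserves territory-scale structure, so G measures how unevenly a gene's
signal is laid out over the slide: 0 for uniform expression, → 1 for a
signal concentrated in few neighbourhoods. Genes with G ≥ 0.5 are selected.

**Clustering.** The selected genes' normalized expression is embedded by PCA
(20 components). In embedding space, a sparse conditional-probability matrix
P is built: row i is a Gaussian over bead i's nearest candidates with the
bandwidth σᵢ bisected so the realized perplexity 2^H(pᵢ) equals the target
u = 35. A partition of the slide induces a second distribution Q — uniform
over a bead's cluster mates with an ε floor elsewhere — and its quality is
the cross-entropy

H(P, Q) = −(1/n) Σᵢ Σⱼ p(j|i) log q(j|i).

Starting from singletons, the greedy agglomeration repeatedly merges the
pair of *spatially adjacent* clusters (adjacency from the k = 20 spatial kNN
graph) whose merge increases H the least, recording a full dendrogram that
is cut at 40 clusters by default. Clusters are therefore always unions of
spatially connected territory; disconnected tissue fragments are joined by
logged nearest-centroid bridging merges. Every greedy step is exact: a
closed-form per-cluster decomposition of H makes the incremental ΔH equal to
recomputation from scratch.

**Downstream.** Cluster profiles are per-gene means of normalized
expression; markers are called by fold change ≥ 2, in-cluster detection
≥ 0.25 and a rank-sum test at BH FDR < 0.05. Profile dendrograms use
complete linkage on 1 − Pearson distance; profiles from several slides are
z-scored and merged for cross-slide PCA. Cross-stage dynamics z-scores one
designated cluster profile per developmental stage and segments genes into
six temporal groups with restarted K-means. Enrichment uses the one-sided
hypergeometric (Fisher) test with BH control.

## Worked example

```python
import spotatlas as sa

M, truth = sa.generate_slide(600, 200, layout=sa.DomainLayout("voronoi", 4),
                             markers_per_domain=10, marker_fold=8.0, seed=0)
result = sa.run_pipeline(M, sa.PipelineConfig(target_clusters=4, gini_threshold=0.3))
```

prints (via the manifest and result object):

```
beads x genes after filters: 600 x 200
spatially varying genes: 40
clusters: 4 sizes: [255, 138, 122, 85]
final cross-entropy H(P,Q): 5.151
ARI vs planted domains: 1.000
preferential genes called: 40
```

All 40 planted domain markers are detected as SVGs, the k = 4 cut recovers
the four planted Voronoi territories exactly (Adjusted Rand Index 1.0), and
marker calling flags exactly the planted markers. The same pipeline is
exposed on the command line:

```bash
atlas simulate --out slide/ --beads 600 --genes 200 --seed 0
atlas run --input slide/ --out run/ --target-clusters 4
atlas subset --input slide/ --assignments run/clusters.tsv --labels 1,2 --out sub/
```

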