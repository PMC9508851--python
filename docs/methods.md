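# Methods

This note documents the models and procedures implemented in `spotatlas`,
the choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish about real data.

## Data model

A slide is a sparse beads × genes matrix of UMI counts with per-bead array
indices, pixel coordinates and an in-tissue flag. All geometry (neighbour
graphs, distances, bridging) uses the pixel coordinates; array row/col are
carried through for provenance only, which keeps hexagonal-grid handling out
of the math core. Gene identifiers are opaque strings; no genome annotation
is loaded. Beads flagged as outside the tissue are dropped at read time
unless `keep_out_of_tissue` is set (whether out-of-tissue spots should enter
the occupancy statistics is not derivable from first principles; computing
occupancies after their removal is the package's choice).

## Occupancy filters and normalization

"Expressed genes" are genes with positive total count in the input. A bead
is kept if it detects at least ⌈f_b · n_expressed⌉ distinct genes
(f_b = 0.005); a gene is kept if detected in at least ⌈f_g · n_beads⌉ beads
(f_g = 0.0005). The two filters run in that fixed order, beads first, one
pass each, with occupancies computed once on the input — no iteration to a
fixed point. Both occupancy vectors are recorded in the run manifest.

Normalization scales each bead's counts so its total equals the median bead
total, then applies log1p; counts themselves are never modified. With the
default median target the normalized magnitudes track the dataset's own
depth; passing a fixed `target` makes the layer exactly invariant to any
rescaling of sequencing depth (the two properties cannot hold
simultaneously, since a global rescale moves the median with it).

## Spatial Gini score

For a non-negative vector x over n beads the Gini coefficient is computed
with ordered-pairs normalization, G = Σᵢⱼ|xᵢ−xⱼ| / (2n²μ), so a single
positive entry among n scores (n−1)/n and a constant positive vector scores
exactly 0; the implementation uses the equivalent sorted form
Σᵢ(2i−n−1)x₍ᵢ₎/(n Σx) and is verified against both the pairwise definition
and a Lorenz-curve construction.

Two decisions make the score *spatial* and usable as an SVG detector:

1. **Smoothing (default on).** Each bead's value is replaced by the mean
   over itself and its k = 20 spatial nearest neighbours before scoring.
   Without smoothing the statistic is a pure marginal-inequality measure:
   independent per-bead sampling noise inflates housekeeping genes' scores
   above those of genuine domain markers (measured ROC AUC ≈ 0.3 on the
   standard benchmark, i.e. anti-discrimination), and no threshold on the
   raw score separates them. Local averaging cancels iid noise at rate ~1/k
   while preserving territory-scale structure; with it the same benchmark
   gives AUC ≈ 1.0. The unsmoothed variant remains available
   (`smooth=False`) for comparison.
2. **Linear scale (default).** Scores are computed on depth-normalized
   linear expression (expm1 of the normalized layer), not on log1p values.
   Gini measures concentration of expression share, and the log transform
   compresses exactly the high-expression concentration the score must
   detect: on log1p values a two-level marker with in/out contrast c has
   G ≤ f(1−f)·log-contrast/μ, which caps organ-marker scores near 0.3–0.4
   regardless of fold, while the 0.5 selection threshold then selects
   nothing. On the linear scale near-exclusive markers score 0.5–0.75 and
   broadly expressed genes stay below ~0.4, making the fixed 0.5 threshold
   meaningful. A `log_scale` switch preserves the alternative.

Selection keeps genes with G ≥ 0.5, inclusive, in input order. The
threshold semantics imply that selected genes are strongly
organ-restricted; moderately enriched genes (e.g. fold 8 over a small
panel) sit near the boundary, which is why operation-level benchmarks below
do not route through the threshold.

## Embedding and affinities

PCA (default 20 components) of the column-centered normalized expression of
the selected genes, via exact SVD; components are truncated to the matrix
rank when necessary and signs are fixed by making each component's
largest-magnitude loading positive, so embeddings are bit-reproducible.

The conditional affinity matrix P follows the perplexity-calibration
construction standard for stochastic neighbour embeddings: row i is
supported on the m = min(⌈3u⌉, n−1) nearest beads in embedding space,
p(j|i) ∝ exp(−d²ᵢⱼ/2σᵢ²), with σᵢ bisected (≤ 100 iterations) until the
realized perplexity 2^H(pᵢ) matches min(u, m) within 1e−3; unconverged rows
(possible only in degenerate geometry, e.g. exactly equidistant candidates)
keep the last midpoint and are flagged in the manifest. The target u = 35
exceeds the spatial k = 20 by design: the two parameters play different
roles. The spatial graph governs merge adjacency only; the affinity support
is wider so that the calibrated perplexity remains attainable.

## Partition cross-entropy and agglomeration

For a partition with cluster C(i) ∋ i of size s in a slide of n beads,

    q(j|i) = (1 − δ)/(s − 1)  for j ∈ C(i)\{i},   δ = ε(n − s)
    q(j|i) = ε                 otherwise,

with ε = 1e−12; a singleton bead's whole row lies on the floor. This is the
simplest graph-style distribution that keeps H(P,Q) finite for any
partition, is singleton-safe, and rewards exactly what the method needs:
moving P-mass from the ε floor into a cluster lowers H, while padding a
cluster with unrelated beads thins q over more mates and raises it. ε must
satisfy ε(n−1) < 1 (checked); its magnitude only offsets H and does not
reorder merges except through the floor penalty itself.

Summing the cross-entropy over the beads of one cluster gives the
closed-form per-cluster contribution −W·log((1−δ)/(s−1)) − (s−W)·log ε,
where W is the total P-mass between cluster members. The change from
merging A and B therefore depends only on (s, W) of both clusters and the
cross mass X(A,B), all of which are maintained incrementally, so each
greedy ΔH is *exact* — identical (to rounding) to recomputing H from
scratch — at cost independent of n. Candidate merges live in a lazy
min-heap keyed (ΔH, smaller id, larger id); the id tuple is also the
tie-break rule, and the surviving cluster takes the smaller id, making the
whole merge sequence deterministic. Correctness of the incremental
bookkeeping is established by exhaustive-search equivalence on all random
instances with ≤ 8 beads and by direct H recomputation at the final cut.

Merging stops at the requested cluster count (default 40, emitted together
with the full dendrogram). If the spatial graph is disconnected, greedy
merging exhausts each component; with bridging on (default — real slides
can carry several separate buds) the two nearest-centroid clusters are then
joined, logged as non-greedy bridged steps; with bridging off the run stops
at the component count with a warning. Final labels are 1..K in decreasing
cluster size (ties: smaller lowest bead index), so outputs are stable under
any internal id churn.

## Profiles, markers, trees

Cluster profiles are exact per-gene means of the normalized layer over
member beads; the bead-weighted mean of all profiles equals the global mean
vector, which is asserted in tests. Preferential (marker) genes are called
per (gene, cluster) by three conjunctive criteria, all configurable: fold
≥ 2 of in- versus out-of-cluster mean depth-normalized (linear) expression
with a 1e−9 pseudocount, in-cluster detection fraction ≥ 0.25, and a
one-sided Wilcoxon rank-sum test with Benjamini–Hochberg control across
genes within each cluster at FDR < 0.05. The three-part rule is a
conventional, monotone and auditable operationalization of "preferentially
expressed"; singleton clusters cannot be rank-tested and are skipped with a
log record.

Profile dendrograms use complete linkage on 1 − Pearson distance (scipy's
deterministic implementation, verified against a naive complete-linkage
enumeration); zero-variance profiles are an error naming the cluster.
Cross-slide PCA merges profiles over the union of genes (absent genes
imputed as 0 — absence of detection is informative at this sparsity),
z-scores each gene, drops zero-variance genes with a log record, and
decomposes with the same exact-SVD routine. Pseudo-bulk comparison
correlates log1p summed slide counts against a log1p bulk vector over genes
detected in both.

## Stage dynamics

One designated cluster profile per developmental stage forms a gene × stage
matrix; genes absent from a profile enter as 0 (logged) and rows constant
across stages are excluded (logged). Rows are z-scored (population SD) so
that temporal *shape*, not magnitude, is the clustering signal. Grouping
uses restarted Lloyd K-means, written in-package so that the contract is
explicit: k-means++ seeding, empty clusters re-seeded from the farthest
point, within-group sum of squares asserted non-increasing across
iterations, best of 10 restarts by WSS, fully determined by the seed. Tests
cross-check the attained WSS against scikit-learn's implementation. k = 6
is the fixed default; choosing k automatically is out of scope.

## Enrichment

Over-representation of a query set against annotated categories is the
one-sided hypergeometric upper tail P(X ≥ overlap) with the annotation
universe as population ("Fisher's exact test" for a 2×2 table, sidedness
made explicit). Categories below 3 members are not tested; BH runs across
all tested categories of a query, zero-overlap categories included with
p = 1. p-values are verified against a big-integer exact tail sum to 1e−10,
BH against the step-up arithmetic, and the procedure against a null
simulation (random query sets) whose average significant fraction stays
below the nominal 0.05. GO-style term propagation is not applied.

## Synthetic slides

The generator emulates the structure the pipeline must resolve: beads on a
triangular lattice (default spacing 100 px, so k = 20 neighbours ≈ two
rings), contiguous spatial domains as Voronoi territories or nested annuli
(organ whorls), domain-restricted marker genes at a planted fold, a
radially decaying single-focus "primordium" gene (mean
peak·exp(−d²/2ℓ²)), and developmental series in which a designated anther
domain's genes follow planted temporal profiles (six shapes: early/late
spike, monotone rise/fall, mid peak/trough) across stages.

Counts are negative binomial with mean depth_b · baseline_g · fold and
common dispersion, thinned by independent Bernoulli dropout. Defaults —
per-gene baselines lognormal(median 1.0, σ 0.5), dispersion 2.0, per-bead
depth lognormal(σ 0.3), dropout 0.05 — describe a down-sampled
detected-gene panel with over-dispersion typical of UMI data. All
randomness flows from one integer seed through split child streams
(structure vs counts vs stages), so identical seeds give entrywise
identical slides and stage noise is independent of the shared structure.

Benchmark sizes are deliberately desk-scale: the standard recovery
benchmark uses 600 beads × 200 genes with four territories and ten fold-8
markers each, the atlas-scale smoke run 2500 beads × 5000 genes with eight
territories and 25 fold-16 markers each (near-exclusive organ markers, the
regime the 0.5 Gini threshold encodes; ~3% of the panel is selected,
comparable to real atlas fractions). What the passing benchmarks show: the
statistics match their oracles exactly; the greedy merge is exhaustively
correct; planted territory and temporal structure of the stated effect
sizes is recovered essentially perfectly at these noise levels. What they
do not show: robustness to segmentation artefacts, spatially varying
capture efficiency, cell-type mixtures within beads, batch effects between
slides, or annotation noise — none of which the generator emulates.

## Numerical and degenerate-input conventions

Exact kNN by blockwise all-pairs scan with ties broken by ascending bead
index (duplicate coordinates permitted). Sign-fixed SVD everywhere PCA
appears. Affinity bisection tolerance 1e−3 in realized perplexity;
unconverged rows flagged, never silently accepted. ε-floor validity checked
against n. All-zero expression vectors are an error for the Gini score
(callers filter first). TSVs are written with a fixed float format so
identical runs are byte-identical; the JSON manifest (config, stage sizes,
warnings, file hashes) is written last so an interrupted run leaves no
manifest. K-means and synthesis are the only stochastic stages; both take
explicit seeds, and the clustering path is seed-free, so cluster outputs
are identical across runs regardless of downstream seeds.
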