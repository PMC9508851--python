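"""Synthetic slides with known ground truth.

The generator emulates the structure of a sectioned flower bud on a
bead-array slide: beads on a triangular lattice (mimicking the hexagonal
spot arrangement of the platform), a handful of contiguous spatial domains
standing in for organ territories (meristem, tepal, lip, column, anther),
domain-specific marker genes at a planted fold change, and over-dispersed
UMI counts with per-bead depth variation and dropout. Every stochastic
choice flows from one integer seed through split child streams, so a slide
is reproducible entry-for-entry.

Count law: gene g on bead b is negative binomial with mean
``depth_b * baseline_g * fold`` (fold applied when g is a marker of b's
domain) and a common dispersion (shape) parameter, then thinned by an
independent Bernoulli dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .core_io import SpatialExpressionMatrix

# Default noise regime: chosen to resemble a down-sampled detected-gene panel
# (per-gene baseline means around 1 UMI/bead, moderate over-dispersion,
# ~30% log-scale depth variation between beads, light dropout).
DEFAULT_BASELINE_MEDIAN = 1.0
DEFAULT_BASELINE_SIGMA = 0.5
DEFAULT_DISPERSION = 2.0
DEFAULT_DEPTH_SD = 0.3
DEFAULT_DROPOUT = 0.05
DEFAULT_SPACING = 100.0  # pixels between adjacent lattice beads


@dataclass
class DomainLayout:
    """Spatial domain layout: Voronoi territories or nested annuli (whorls)."""

    kind: str = "voronoi"  # "voronoi" | "annuli"
    n_domains: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("voronoi", "annuli"):
            raise ValueError(f"unknown layout kind {self.kind!r}")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated slide, for recovery benchmarks."""

    domain_label: np.ndarray                      # per-bead 0-based domain
    marker_map: dict[str, tuple[int, float]]      # gene -> (domain, fold)
    baseline_mean: np.ndarray                     # per-gene
    dispersion: np.ndarray                        # per-gene NB shape
    depth_factor: np.ndarray                      # per-bead
    gradient_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    seed: int = 0
    dynamic_classes: dict[str, int] = field(default_factory=dict)
    class_profiles: dict[int, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, (_, fold) in self.marker_map.items():
            if fold <= 1:
                raise ValueError(f"marker {gene} has fold {fold}; must exceed 1")
        if np.any(self.depth_factor <= 0):
            raise ValueError("depth factors must be positive")
        counts = np.bincount(self.domain_label)
        if (counts == 0).any():
            raise ValueError("every domain must own at least one bead")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "domain_label": self.domain_label.tolist(),
            "marker_map": {g: [int(d), float(f)] for g, (d, f) in self.marker_map.items()},
            "baseline_mean": self.baseline_mean.tolist(),
            "dispersion": self.dispersion.tolist(),
            "depth_factor": self.depth_factor.tolist(),
            "gradient_genes": {g: [b, float(s)] for g, (b, s) in self.gradient_genes.items()},
            "dynamic_classes": self.dynamic_classes,
            "class_profiles": {str(k): v for k, v in self.class_profiles.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def triangular_lattice(n_beads: int, spacing: float = DEFAULT_SPACING) -> np.ndarray:
    """First ``n_beads`` sites of a near-square triangular lattice (pixels)."""
    side = int(np.ceil(np.sqrt(n_beads)))
    rows = []
    for r in range(side + 1):
        xs = np.arange(side, dtype=float) * spacing + (spacing / 2 if r % 2 else 0.0)
        ys = np.full(side, r * spacing * np.sqrt(3) / 2)
        rows.append(np.c_[xs, ys])
    return np.concatenate(rows)[:n_beads]


def _assign_domains(xy: np.ndarray, layout: DomainLayout, rng: np.random.Generator) -> np.ndarray:
    n = len(xy)
    if layout.n_domains > n:
        raise ValueError("more domains than beads")
    if layout.kind == "voronoi":
        seeds = xy[rng.choice(n, size=layout.n_domains, replace=False)]
        label = cKDTree(seeds).query(xy)[1]
    else:  # nested annuli around the slide centre, equal-area rings
        centre = xy.mean(axis=0)
        r = np.linalg.norm(xy - centre, axis=1)
        edges = np.quantile(r, np.linspace(0, 1, layout.n_domains + 1)[1:-1])
        label = np.searchsorted(edges, r, side="right")
    if np.bincount(label, minlength=layout.n_domains).min() == 0:
        raise ValueError("layout produced an empty domain; use fewer domains or more beads")
    return label.astype(int)


# ---------------------------------------------------------------------------
# slide generation
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, shape: np.ndarray) -> np.ndarray:
    """Negative binomial with given mean and shape r (Poisson as r -> inf)."""
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, np.clip(p, 1e-12, 1.0))


def _build_matrix(counts: np.ndarray, xy: np.ndarray, spacing: float, slide_id: str,
                  gene_ids: Sequence[str]) -> SpatialExpressionMatrix:
    n = counts.shape[0]
    bead_ids = np.array([f"bead_{i:05d}" for i in range(n)], dtype=object)
    positions = pd.DataFrame(
        {
            "array_row": np.round(xy[:, 1] / (spacing * np.sqrt(3) / 2)).astype(int),
            "array_col": np.round(xy[:, 0] / spacing).astype(int),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "in_tissue": True,
        },
        index=pd.Index(bead_ids),
    )
    return SpatialExpressionMatrix(
        bead_ids=bead_ids,
        gene_ids=np.asarray(list(gene_ids), dtype=object),
        counts=sp.csr_matrix(counts),
        positions=positions,
        slide_id=slide_id,
    )


def generate_slide(
    n_beads: int = 600,
    n_genes: int = 200,
    *,
    layout: DomainLayout | None = None,
    markers_per_domain: int = 10,
    marker_fold: float = 8.0,
    baseline_median: float = DEFAULT_BASELINE_MEDIAN,
    baseline_sigma: float = DEFAULT_BASELINE_SIGMA,
    dispersion: float = DEFAULT_DISPERSION,
    depth_sd: float = DEFAULT_DEPTH_SD,
    dropout: float = DEFAULT_DROPOUT,
    spacing: float = DEFAULT_SPACING,
    seed: int = 0,
    slide_id: str = "synthetic",
) -> tuple[SpatialExpressionMatrix, SyntheticTruth]:
    """Generate one slide with planted domains and markers.

    Markers are drawn without replacement from the gene panel; each marker's
    mean is multiplied by ``marker_fold`` on beads of its domain. Identical
    seeds give entrywise-identical slides.
    """
    layout = layout or DomainLayout()
    if marker_fold <= 1 and markers_per_domain > 0:
        raise ValueError("marker_fold must exceed 1")
    if markers_per_domain * layout.n_domains > n_genes:
        raise ValueError("more markers requested than genes available")
    ss = np.random.SeedSequence(seed)
    rng_struct, rng_counts = (np.random.default_rng(s) for s in ss.spawn(2))

    xy = triangular_lattice(n_beads, spacing)
    domain = _assign_domains(xy, layout, rng_struct)

    gene_ids = [f"gene_{j:05d}" for j in range(n_genes)]
    baseline = rng_struct.lognormal(np.log(baseline_median), baseline_sigma, n_genes)
    depth = rng_struct.lognormal(0.0, depth_sd, n_beads)
    marker_idx = rng_struct.choice(n_genes, size=markers_per_domain * layout.n_domains,
                                   replace=False)
    marker_map: dict[str, tuple[int, float]] = {}
    fold_matrix = np.ones((n_beads, n_genes))
    for k, j in enumerate(marker_idx):
        d = k % layout.n_domains
        marker_map[gene_ids[j]] = (int(d), float(marker_fold))
        fold_matrix[domain == d, j] = marker_fold

    mean = depth[:, None] * baseline[None, :] * fold_matrix
    shape = np.full(n_genes, float(dispersion))
    counts = _nb_sample(rng_counts, mean, shape[None, :])
    if dropout > 0:
        counts = counts * (rng_counts.random(counts.shape) >= dropout)

    M = _build_matrix(counts, xy, spacing, slide_id, gene_ids)
    truth = SyntheticTruth(
        domain_label=domain,
        marker_map=marker_map,
        baseline_mean=baseline,
        dispersion=shape,
        depth_factor=depth,
        seed=seed,
    )
    return M, truth


def plant_gradient_gene(
    M: SpatialExpressionMatrix,
    truth: SyntheticTruth,
    focus_bead: str,
    length_scale: float,
    peak_mean: float,
    *,
    seed: int | None = None,
) -> tuple[SpatialExpressionMatrix, SyntheticTruth]:
    """Append one gene decaying radially from a focus bead.

    The new gene's mean at bead b is ``peak_mean * exp(-d(b, focus)^2 /
    (2 * length_scale^2))`` with d in pixels — emulating a single-spot
    primordium signal whose surrounding beads show decreasing expression.
    Counts are sampled for the new gene only; existing entries are untouched.
    """
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    ids = list(M.bead_ids)
    if focus_bead not in ids:
        raise ValueError(f"focus bead {focus_bead!r} not in slide")
    focus_xy = M.xy[ids.index(focus_bead)]
    d2 = ((M.xy - focus_xy) ** 2).sum(axis=1)
    mean = peak_mean * np.exp(-d2 / (2.0 * length_scale**2))
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed if seed is None else seed).spawn(3)[-1])
    disp = float(np.median(truth.dispersion)) if len(truth.dispersion) else DEFAULT_DISPERSION
    new_counts = _nb_sample(rng, mean, np.full_like(mean, disp))

    gene_id = f"gradient_{len(truth.gradient_genes):03d}"
    counts = sp.hstack([M.counts, sp.csr_matrix(new_counts[:, None])], format="csr")
    M2 = SpatialExpressionMatrix(
        bead_ids=M.bead_ids,
        gene_ids=np.append(M.gene_ids, gene_id),
        counts=counts,
        positions=M.positions,
        slide_id=M.slide_id,
    )
    truth2 = SyntheticTruth(
        domain_label=truth.domain_label,
        marker_map=dict(truth.marker_map),
        baseline_mean=np.append(truth.baseline_mean, peak_mean),
        dispersion=np.append(truth.dispersion, disp),
        depth_factor=truth.depth_factor,
        gradient_genes={**truth.gradient_genes, gene_id: (focus_bead, float(length_scale))},
        seed=truth.seed,
        dynamic_classes=dict(truth.dynamic_classes),
        class_profiles=dict(truth.class_profiles),
    )
    return M2, truth2


# ---------------------------------------------------------------------------
# stage series
# ---------------------------------------------------------------------------

#: Six canonical temporal shapes over four stages (positive multipliers):
#: early spike, late spike, monotone rise, monotone fall, mid peak, mid trough.
DEFAULT_CLASS_PROFILES: dict[int, list[float]] = {
    0: [8.0, 1.0, 1.0, 1.0],
    1: [1.0, 1.0, 1.0, 8.0],
    2: [1.0, 2.0, 4.0, 8.0],
    3: [8.0, 4.0, 2.0, 1.0],
    4: [1.0, 6.0, 6.0, 1.0],
    5: [6.0, 1.0, 1.0, 6.0],
}


def _resample_profiles(profiles: dict[int, list[float]], n_stages: int) -> dict[int, list[float]]:
    out = {}
    for k, prof in profiles.items():
        xp = np.linspace(0, 1, len(prof))
        out[k] = np.interp(np.linspace(0, 1, n_stages), xp, prof).tolist()
    return out


def generate_stage_series(
    n_stages: int = 4,
    *,
    n_beads: int = 600,
    n_genes: int = 400,
    layout: DomainLayout | None = None,
    anther_domain: int = 0,
    genes_per_class: int = 50,
    class_profiles: dict[int, list[float]] | None = None,
    markers_per_domain: int = 10,
    marker_fold: float = 8.0,
    dynamic_fold: float = 8.0,
    seed: int = 0,
    **noise_kwargs,
) -> tuple[list[tuple[SpatialExpressionMatrix, SyntheticTruth]], dict[str, int]]:
    """Generate a developmental series of slides sharing gene programs.

    All stages share the gene panel, layout, baselines and marker structure.
    A set of "dynamic" genes is elevated (by ``dynamic_fold``) in a designated
    anther domain, and their in-domain mean is further multiplied per stage by
    the temporal profile of their planted class — emulating genes that rise,
    fall, or peak across bud stages. Returns the per-stage (slide, truth)
    pairs plus the gene -> class map.
    """
    if n_stages < 2:
        raise ValueError("a series needs at least two stages")
    profiles = _resample_profiles(class_profiles or DEFAULT_CLASS_PROFILES, n_stages)
    for k, prof in profiles.items():
        if any(m <= 0 for m in prof):
            raise ValueError(f"class {k} has a non-positive temporal multiplier")
    layout = layout or DomainLayout()
    n_classes = len(profiles)
    n_dynamic = n_classes * genes_per_class
    if n_dynamic + markers_per_domain * layout.n_domains > n_genes:
        raise ValueError("gene panel too small for requested dynamic + marker genes")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 + n_stages)
    rng_struct = np.random.default_rng(children[0])

    xy = triangular_lattice(n_beads, noise_kwargs.get("spacing", DEFAULT_SPACING))
    domain = _assign_domains(xy, layout, rng_struct)
    gene_ids = [f"gene_{j:05d}" for j in range(n_genes)]
    baseline = rng_struct.lognormal(
        np.log(noise_kwargs.get("baseline_median", DEFAULT_BASELINE_MEDIAN)),
        noise_kwargs.get("baseline_sigma", DEFAULT_BASELINE_SIGMA),
        n_genes,
    )
    dispersion = float(noise_kwargs.get("dispersion", DEFAULT_DISPERSION))
    depth_sd = noise_kwargs.get("depth_sd", DEFAULT_DEPTH_SD)
    dropout = noise_kwargs.get("dropout", DEFAULT_DROPOUT)
    spacing = noise_kwargs.get("spacing", DEFAULT_SPACING)

    perm = rng_struct.permutation(n_genes)
    dynamic_idx = perm[:n_dynamic]
    marker_idx = perm[n_dynamic:n_dynamic + markers_per_domain * layout.n_domains]
    class_of = {gene_ids[j]: int(k // genes_per_class)
                for k, j in enumerate(dynamic_idx)}

    marker_map: dict[str, tuple[int, float]] = {}
    static_fold = np.ones((n_beads, n_genes))
    for k, j in enumerate(marker_idx):
        d = k % layout.n_domains
        marker_map[gene_ids[j]] = (int(d), float(marker_fold))
        static_fold[domain == d, j] = marker_fold
    anther_mask = domain == anther_domain
    for j in dynamic_idx:
        marker_map[gene_ids[j]] = (int(anther_domain), float(dynamic_fold))
        static_fold[anther_mask, j] = dynamic_fold

    shape = np.full(n_genes, dispersion)
    series = []
    for s in range(n_stages):
        rng_stage = np.random.default_rng(children[2 + s])
        depth = rng_stage.lognormal(0.0, depth_sd, n_beads)
        stage_fold = static_fold.copy()
        for j in dynamic_idx:
            mult = profiles[class_of[gene_ids[j]]][s]
            stage_fold[anther_mask, j] *= mult
        mean = depth[:, None] * baseline[None, :] * stage_fold
        counts = _nb_sample(rng_stage, mean, shape[None, :])
        if dropout > 0:
            counts = counts * (rng_stage.random(counts.shape) >= dropout)
        M = _build_matrix(counts, xy, spacing, f"stage_{s + 1}", gene_ids)
        truth = SyntheticTruth(
            domain_label=domain,
            marker_map=marker_map,
            baseline_mean=baseline,
            dispersion=shape,
            depth_factor=depth,
            seed=seed,
            dynamic_classes=class_of,
            class_profiles=profiles,
        )
        series.append((M, truth))
    return series, class_of
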