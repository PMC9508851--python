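"""Cross-stage expression dynamics of a curated gene list.

A stage matrix stacks one designated cluster profile per developmental stage
(gene x stage), z-scores each gene across stages so that pattern shape —
not magnitude — carries the signal, and segments the genes into temporal
groups with restarted K-means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class StageMatrix:
    """Gene x stage z-scored expression, with the pre-normalization values."""

    values: pd.DataFrame       # z-scored rows (constant rows removed)
    raw: pd.DataFrame          # assembled values before normalization
    excluded_constant: list[str]
    filled_missing: int        # gene/stage cells absent from a profile, set to 0


def build_stage_matrix(stage_profiles: Sequence[pd.Series], genes: Sequence[str],
                       *, stage_names: Sequence[str] | None = None) -> StageMatrix:
    """Assemble and z-score the gene x stage matrix.

    ``stage_profiles`` holds one designated cluster's per-gene expression per
    stage, in stage order. Genes absent from a profile enter as 0 (logged);
    genes constant across stages cannot be z-scored and are excluded (logged).
    """
    if len(stage_profiles) < 2:
        raise ValueError("need at least two stages")
    names = list(stage_names) if stage_names is not None else [
        f"stage_{i + 1}" for i in range(len(stage_profiles))
    ]
    filled = 0
    cols = {}
    for name, prof in zip(names, stage_profiles):
        aligned = prof.reindex(genes)
        filled += int(aligned.isna().sum())
        cols[name] = aligned.fillna(0.0)
    raw = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    if filled:
        logger.info("%d gene/stage values absent from profiles, set to 0", filled)
    sd = raw.std(axis=1, ddof=0)
    constant = raw.index[sd == 0].tolist()
    if constant:
        logger.info("excluding %d constant-across-stages genes", len(constant))
    kept = raw.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return StageMatrix(values=z, raw=raw, excluded_constant=constant,
                       filled_missing=filled)


def _kmeans_once(X: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 300, tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run with k-means++ seeding and farthest-point re-seeding."""
    n = X.shape[0]
    # k-means++ seeding
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[c] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[c]) ** 2).sum(axis=1))

    prev_wss = np.inf
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dists = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = dists.argmin(axis=1)
        wss = float(dists[np.arange(n), labels].sum())
        assert wss <= prev_wss + 1e-8, "within-group SS increased during Lloyd iteration"
        for c in range(k):
            mask = labels == c
            if mask.any():
                centers[c] = X[mask].mean(axis=0)
            else:  # empty group: re-seed from the farthest point
                far = int(dists[np.arange(n), labels].argmax())
                centers[c] = X[far]
                logger.info("re-seeded empty K-means group %d from farthest point", c)
        if prev_wss - wss < tol:
            break
        prev_wss = wss
    dists = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = dists.argmin(axis=1)
    wss = float(dists[np.arange(n), labels].sum())
    return labels, centers, wss


def kmeans_groups(S: StageMatrix, k: int = 6, *, seed: int = 0,
                  n_restarts: int = 10) -> tuple[pd.Series, pd.DataFrame, float]:
    """Segment the stage matrix rows into k temporal groups.

    Restarted Lloyd's algorithm (k-means++ seeding, best of ``n_restarts`` by
    within-group sum of squares), fully determined by ``seed``. Returns
    1-based group labels per gene, the k x stage centroid frame, and the
    final within-group sum of squares.
    """
    X = S.values.to_numpy(float)
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k must lie in [1, {X.shape[0]}]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        labels, centers, wss = _kmeans_once(X, k, rng)
        if best is None or wss < best[2]:
            best = (labels, centers, wss)
    labels, centers, wss = best
    groups = pd.Series(labels + 1, index=S.values.index, name="group")
    centroids = pd.DataFrame(centers, index=pd.RangeIndex(1, k + 1, name="group"),
                             columns=S.values.columns)
    return groups, centroids, wss
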