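"""Category over-representation analysis.

Fisher's exact test for a 2x2 over-representation table reduces to the
one-sided hypergeometric upper tail: with a universe of N genes, K of them
in a category, and a query set of n genes with x in the category, the
p-value is P(X >= x) for X ~ Hypergeom(N, K, n). Benjamini-Hochberg controls
the false discovery rate across the tested categories of each query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class CategoryAnnotation:
    """Gene -> categories mapping over a background universe."""

    gene_to_categories: dict[str, set[str]]
    category_names: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set(self.gene_to_categories)
        stray = set(self.gene_to_categories) - self.universe
        if stray:
            raise ValueError(
                f"{len(stray)} annotated genes outside the universe, e.g. "
                f"{sorted(stray)[:5]}"
            )

    @property
    def category_members(self) -> dict[str, set[str]]:
        members: dict[str, set[str]] = {}
        for gene, cats in self.gene_to_categories.items():
            for c in cats:
                members.setdefault(c, set()).add(gene)
        return members

    @classmethod
    def from_tables(cls, gene_category_tsv: str | Path,
                    names_tsv: str | Path | None = None,
                    universe: Iterable[str] | None = None) -> "CategoryAnnotation":
        """Load from a two-column (gene, category) TSV plus optional names TSV."""
        pairs = pd.read_csv(gene_category_tsv, sep="\t", header=None,
                            names=["gene", "category"], dtype=str)
        mapping: dict[str, set[str]] = {}
        for gene, cat in pairs.itertuples(index=False):
            mapping.setdefault(gene, set()).add(cat)
        names = {}
        if names_tsv is not None:
            nm = pd.read_csv(names_tsv, sep="\t", header=None,
                             names=["category", "name"], dtype=str)
            names = dict(nm.itertuples(index=False))
        uni = set(universe) if universe is not None else set(mapping)
        return cls(gene_to_categories=mapping, category_names=names, universe=uni)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{p_j >= p_i} m p_j / rank_j."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    gene_set: Iterable[str],
    annotation: CategoryAnnotation,
    *,
    fdr: float = 0.05,
    min_category_size: int = 3,
) -> pd.DataFrame:
    """Over-representation of each category within ``gene_set``.

    Categories smaller than ``min_category_size`` are not tested; BH is
    applied across all tested categories (zero-overlap categories included,
    their p-value being 1). Returns a frame sorted by p-value with columns
    category, name, overlap, set_size, category_size, universe_size, pvalue,
    qvalue, significant.
    """
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    if not annotation.universe:
        raise ValueError("empty annotation universe")
    outside = genes - annotation.universe
    if outside:
        raise ValueError(
            f"{len(outside)} query genes outside the universe, e.g. {sorted(outside)[:5]}"
        )
    N = len(annotation.universe)
    n = len(genes)
    rows = []
    for cat, members in sorted(annotation.category_members.items()):
        K = len(members)
        if K < min_category_size:
            continue
        x = len(genes & members)
        # upper tail P(X >= x) of Hypergeom(N, K, n)
        p = float(hypergeom.sf(x - 1, N, K, n))
        rows.append((cat, annotation.category_names.get(cat, cat), x, n, K, N, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=["category", "name", "overlap", "set_size",
                                     "category_size", "universe_size", "pvalue",
                                     "qvalue", "significant"])
    df = pd.DataFrame(rows, columns=["category", "name", "overlap", "set_size",
                                     "category_size", "universe_size", "pvalue"])
    df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    df["significant"] = df["qvalue"] < fdr
    return df.sort_values(["pvalue", "category"], kind="stable").reset_index(drop=True)
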