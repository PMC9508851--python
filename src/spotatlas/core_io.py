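"""Domain types and I/O for the spot-matrix dialect.

A slide is stored the way 10x-style pipelines deposit it: a Matrix Market
coordinate file of UMI counts (features x barcodes), one-record-per-line
``features`` and ``barcodes`` tables, and a positions table mapping each
barcode to its array indices, pixel coordinates and in-tissue flag. In
memory the package works with beads as rows and genes as columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "pixel_x", "pixel_y"]


class FormatError(ValueError):
    """Raised when an on-disk dataset violates the dialect."""


@dataclass
class SpatialExpressionMatrix:
    """Sparse bead x gene UMI counts with per-bead 2D coordinates.

    ``counts`` rows follow ``bead_ids``, columns follow ``gene_ids``.
    ``positions`` is indexed by bead id with columns ``array_row``,
    ``array_col``, ``x``, ``y`` (pixels) and ``in_tissue``. ``layers`` holds
    derived real-valued matrices of the same shape (e.g. ``"normalized"``).
    """

    bead_ids: np.ndarray
    gene_ids: np.ndarray
    counts: sp.csr_matrix
    positions: pd.DataFrame
    layers: dict[str, sp.spmatrix] = field(default_factory=dict)
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.bead_ids = np.asarray(self.bead_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        nb, ng = self.counts.shape
        if nb != len(self.bead_ids) or ng != len(self.gene_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.bead_ids)} beads x {len(self.gene_ids)} genes"
            )
        if len(set(self.bead_ids)) != nb:
            raise ValueError("bead ids are not unique")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("gene ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValueError("counts must be integral")
        if not self.positions.index.equals(pd.Index(self.bead_ids)):
            raise ValueError("positions index must equal bead_ids, in order")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValueError(f"layer {name!r} shape {layer.shape} != {self.counts.shape}")

    # -- conveniences -----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def xy(self) -> np.ndarray:
        """Pixel coordinates, (n_beads, 2). All geometry uses these."""
        return self.positions[["x", "y"]].to_numpy(dtype=float)

    def layer(self, name: str) -> sp.csr_matrix:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"layer {name!r} not present; have {sorted(self.layers)}") from None

    def subset_beads(self, index: np.ndarray) -> "SpatialExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpatialExpressionMatrix(
            bead_ids=self.bead_ids[index],
            gene_ids=self.gene_ids,
            counts=self.counts[index],
            positions=self.positions.iloc[index],
            layers={k: sp.csr_matrix(v)[index] for k, v in self.layers.items()},
            slide_id=self.slide_id,
        )

    def subset_genes(self, index: np.ndarray) -> "SpatialExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpatialExpressionMatrix(
            bead_ids=self.bead_ids,
            gene_ids=self.gene_ids[index],
            counts=self.counts[:, index],
            positions=self.positions,
            layers={k: sp.csr_matrix(v)[:, index] for k, v in self.layers.items()},
            slide_id=self.slide_id,
        )


# ---------------------------------------------------------------------------
# readers / writers for the spot-matrix dialect
# ---------------------------------------------------------------------------

def _read_positions(path: Path) -> pd.DataFrame:
    first = Path(path).open().readline()
    has_header = "barcode" in first.lower()
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        header=0 if has_header else None,
        names=None if has_header else POSITION_COLUMNS,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"positions table {path} lacks columns {missing}")
    return df


def read_spatial_dataset(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    positions_path: str | Path,
    *,
    keep_out_of_tissue: bool = False,
    slide_id: str | None = None,
) -> SpatialExpressionMatrix:
    """Read a slide from the Matrix Market + tables dialect.

    The matrix is stored features x barcodes and transposed to beads x genes.
    Beads flagged ``in_tissue == 0`` are dropped unless ``keep_out_of_tissue``.
    Gene order follows the features file; bead order follows the barcodes file.
    """
    mat = scipy.io.mmread(str(matrix_path))
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str).to_numpy()
    features = pd.read_csv(features_path, header=None, sep="\t")[0].astype(str).to_numpy()
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix header says {mat.shape} but features/barcodes give "
            f"({len(features)}, {len(barcodes)})"
        )
    counts = sp.csr_matrix(mat.T)
    if counts.nnz and (counts.data < 0).any():
        raise FormatError("negative entries in count matrix")

    pos = _read_positions(Path(positions_path))
    pos = pos.set_index(pos["barcode"].astype(str))
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise FormatError(
            f"{len(missing)} barcodes missing from positions table, e.g. {missing[:5]}"
        )
    pos = pos.loc[barcodes]
    positions = pd.DataFrame(
        {
            "array_row": pos["array_row"].to_numpy(int),
            "array_col": pos["array_col"].to_numpy(int),
            "x": pos["pixel_x"].to_numpy(float),
            "y": pos["pixel_y"].to_numpy(float),
            "in_tissue": pos["in_tissue"].to_numpy(int).astype(bool),
        },
        index=pd.Index(barcodes),
    )
    M = SpatialExpressionMatrix(
        bead_ids=barcodes,
        gene_ids=features,
        counts=counts,
        positions=positions,
        slide_id=slide_id or Path(matrix_path).parent.name,
    )
    if not keep_out_of_tissue:
        M = M.subset_beads(positions["in_tissue"].to_numpy())
    return M


def write_spatial_dataset(M: SpatialExpressionMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write a slide in the same dialect ``read_spatial_dataset`` consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "positions": out / "positions.csv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(M.counts.T.astype(int)))
    paths["features"].write_text("\n".join(map(str, M.gene_ids)) + "\n")
    paths["barcodes"].write_text("\n".join(map(str, M.bead_ids)) + "\n")
    pos = M.positions
    table = pd.DataFrame(
        {
            "barcode": M.bead_ids,
            "in_tissue": pos["in_tissue"].to_numpy(int),
            "array_row": pos["array_row"].to_numpy(int),
            "array_col": pos["array_col"].to_numpy(int),
            "pixel_x": pos["x"].to_numpy(float),
            "pixel_y": pos["y"].to_numpy(float),
        }
    )
    table.to_csv(paths["positions"], index=False)
    return paths


def read_slide_dir(path: str | Path, **kwargs) -> SpatialExpressionMatrix:
    """Read a slide directory written by :func:`write_spatial_dataset`."""
    p = Path(path)
    return read_spatial_dataset(
        p / "matrix.mtx", p / "features.tsv", p / "barcodes.tsv", p / "positions.csv", **kwargs
    )


# ---------------------------------------------------------------------------
# cluster assignments and subsetting
# ---------------------------------------------------------------------------

def validate_assignment(assignment: pd.Series) -> None:
    """Check labels are 1-based contiguous integers covering each bead once."""
    labels = np.unique(assignment.to_numpy(int))
    expected = np.arange(1, labels.size + 1)
    if not np.array_equal(labels, expected):
        raise ValueError(f"cluster labels must be 1..K contiguous; got {labels.tolist()}")
    if assignment.index.has_duplicates:
        raise ValueError("a bead appears more than once in the assignment")


def subset_clusters(
    M: SpatialExpressionMatrix,
    assignment: pd.Series,
    labels: Iterable[int],
) -> tuple[SpatialExpressionMatrix, pd.DataFrame]:
    """Isolate the beads of the requested clusters.

    Returns the restricted matrix (genes unchanged) and a companion metadata
    table (bead, label, x, y) suitable as input to external trajectory tools.
    """
    labels = set(int(l) for l in labels)
    present = set(int(l) for l in assignment.unique())
    missing = labels - present
    if missing:
        raise ValueError(f"requested labels not present in assignment: {sorted(missing)}")
    keep_ids = assignment.index[assignment.isin(labels)]
    mask = np.isin(M.bead_ids.astype(str), keep_ids.astype(str))
    if not mask.any():
        raise ValueError(f"no beads of clusters {sorted(labels)} found in the matrix")
    sub = M.subset_beads(mask)
    meta = pd.DataFrame(
        {
            "bead_id": sub.bead_ids,
            "cluster": assignment.loc[sub.bead_ids].to_numpy(int),
            "x": sub.positions["x"].to_numpy(),
            "y": sub.positions["y"].to_numpy(),
        }
    )
    return sub, meta


# ---------------------------------------------------------------------------
# pipeline outputs
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    # fixed float format keeps re-runs byte-identical
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_outputs(
    run_dir: str | Path,
    *,
    config: Mapping | None = None,
    assignments: pd.DataFrame | None = None,
    dendrogram: Mapping | Sequence | None = None,
    gini: pd.DataFrame | None = None,
    markers: pd.DataFrame | None = None,
    dynamics: pd.DataFrame | None = None,
    enrichment: pd.DataFrame | None = None,
    extra: Mapping[str, Mapping] | None = None,
) -> dict:
    """Write every pipeline product plus a JSON manifest of hashes.

    The manifest is written last, so an interrupted run leaves no manifest.
    Re-running with identical inputs and seed reproduces byte-identical files.
    """
    run = Path(run_dir)
    run.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if assignments is not None:
        _write_tsv(assignments, run / "clusters.tsv")
        written["clusters"] = run / "clusters.tsv"
    if gini is not None:
        _write_tsv(gini, run / "gini.tsv")
        written["gini"] = run / "gini.tsv"
    if markers is not None:
        _write_tsv(markers, run / "markers.tsv")
        written["markers"] = run / "markers.tsv"
    if dynamics is not None:
        _write_tsv(dynamics, run / "dynamics.tsv")
        written["dynamics"] = run / "dynamics.tsv"
    if enrichment is not None:
        _write_tsv(enrichment, run / "enrichment.tsv")
        written["enrichment"] = run / "enrichment.tsv"
    if dendrogram is not None:
        (run / "dendrogram.json").write_text(json.dumps(dendrogram, indent=1, sort_keys=True))
        written["dendrogram"] = run / "dendrogram.json"
    for name, payload in (extra or {}).items():
        p = run / f"{name}.json"
        p.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
        written[name] = p
    manifest = {
        "config": dict(config) if config is not None else None,
        "files": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in written.items()},
    }
    (run / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
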