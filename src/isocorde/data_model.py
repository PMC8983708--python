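"""Core data containers and on-disk formats.

The central object is :class:`CountMatrix`: an isoform x cell matrix of
non-negative expression values together with the annotations every downstream
step needs — a cell -> cell-type label, an isoform -> gene map and (optionally)
per-isoform effective lengths.  Matrices are always oriented isoforms-in-rows,
cells-in-columns.

Two interchangeable on-disk dialects are supported:

* Matrix Market triplet (``matrix.mtx``) plus two annotation TSVs
  (``features.tsv``: isoform_id, gene_id, length; ``cells.tsv``: cell_id,
  cell_type), the standard sparse exchange format for single-cell counts;
* a dense TSV with a header row of cell ids, a first column of isoform ids,
  and the same two annotation TSVs (or gene/length/cell_type columns resolved
  separately).

Reading and writing round-trip values exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclasses.dataclass
class CountMatrix:
    """Isoform x cell expression matrix with annotations.

    Parameters
    ----------
    values
        2-D float array, isoforms in rows, cells in columns. Non-negative.
    isoform_ids, cell_ids
        Unique string identifiers for rows / columns.
    cell_types
        Per-cell categorical label; the number of distinct labels is ``K``.
    gene_of
        isoform id -> gene id.
    length_of
        isoform id -> effective length in bases (optional; required only by
        length normalization).
    """

    values: np.ndarray
    isoform_ids: list[str]
    cell_ids: list[str]
    cell_types: list[str]
    gene_of: dict[str, str]
    length_of: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (isoforms x cells)")
        self.isoform_ids = [str(i) for i in self.isoform_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cell_types = [str(t) for t in self.cell_types]
        n_iso, n_cell = self.values.shape
        if len(self.isoform_ids) != n_iso:
            raise ValueError(
                f"{len(self.isoform_ids)} isoform ids for {n_iso} rows"
            )
        if len(self.cell_ids) != n_cell:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n_cell} columns")
        if len(self.cell_types) != n_cell:
            raise ValueError("cell_types must have one entry per cell")

    # -- derived -----------------------------------------------------------
    @property
    def n_isoforms(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def k_types(self) -> int:
        """Number of distinct cell types (derived, never configured)."""
        return len(set(self.cell_types))

    def type_names(self) -> list[str]:
        """Distinct cell types in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.cell_types:
            seen.setdefault(t)
        return list(seen)

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        """Column indices of cells carrying ``cell_type``."""
        return np.flatnonzero(np.asarray(self.cell_types) == cell_type)

    def library_sizes(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        return self.values.sum(axis=0)

    def lengths(self) -> np.ndarray:
        """Per-isoform effective lengths aligned to rows."""
        if self.length_of is None:
            raise ValueError("matrix carries no isoform lengths")
        try:
            return np.array([self.length_of[i] for i in self.isoform_ids], float)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"missing length for isoform {exc}") from exc

    def genes(self) -> np.ndarray:
        """Per-isoform gene ids aligned to rows."""
        return np.array([self.gene_of[i] for i in self.isoform_ids], object)

    # -- subsetting --------------------------------------------------------
    def subset_isoforms(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep, dtype=int)
        ids = [self.isoform_ids[i] for i in keep]
        return CountMatrix(
            values=self.values[keep, :],
            isoform_ids=ids,
            cell_ids=list(self.cell_ids),
            cell_types=list(self.cell_types),
            gene_of={i: self.gene_of[i] for i in ids if i in self.gene_of},
            length_of=(
                None
                if self.length_of is None
                else {i: self.length_of[i] for i in ids if i in self.length_of}
            ),
        )

    def subset_cells(self, keep: Sequence[int] | np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep, dtype=int)
        return CountMatrix(
            values=self.values[:, keep],
            isoform_ids=list(self.isoform_ids),
            cell_ids=[self.cell_ids[i] for i in keep],
            cell_types=[self.cell_types[i] for i in keep],
            gene_of=dict(self.gene_of),
            length_of=None if self.length_of is None else dict(self.length_of),
        )


class NormalizedMatrix(CountMatrix):
    """Length- and depth-normalized expression; same axes as its source."""


def validate(matrix: CountMatrix) -> list[str]:
    """Check every :class:`CountMatrix` invariant; report, never raise.

    Returns an empty list iff the matrix is valid.
    """
    violations: list[str] = []
    neg = np.argwhere(matrix.values < 0)
    for i, j in neg[:10]:
        violations.append(f"negative value at ({i},{j})")
    if len(neg) > 10:
        violations.append(f"... {len(neg) - 10} further negative values")
    if len(set(matrix.isoform_ids)) != len(matrix.isoform_ids):
        violations.append("duplicate isoform ids")
    if len(set(matrix.cell_ids)) != len(matrix.cell_ids):
        violations.append("duplicate cell ids")
    if matrix.k_types < 2:
        violations.append("fewer than 2 cell types")
    missing_gene = [i for i in matrix.isoform_ids if i not in matrix.gene_of]
    if missing_gene:
        violations.append(f"{len(missing_gene)} isoforms without a gene")
    if matrix.length_of is not None:
        bad = [
            i
            for i in matrix.isoform_ids
            if i not in matrix.length_of or not matrix.length_of[i] > 0
        ]
        if bad:
            violations.append(f"{len(bad)} isoforms with missing/non-positive length")
    return violations


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["isoform_id", "gene_id", "length"]
CELL_COLUMNS = ["cell_id", "cell_type"]


def _read_annotations(
    features_path: str | Path, cells_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    feats = pd.read_csv(features_path, sep="\t", dtype={"isoform_id": str, "gene_id": str})
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    for col in ("isoform_id", "gene_id"):
        if col not in feats.columns:
            raise ValueError(f"features table lacks column {col!r}")
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cells table lacks column {col!r}")
    return feats, cells


def _assemble(
    values: np.ndarray, feats: pd.DataFrame, cells: pd.DataFrame
) -> CountMatrix:
    if values.shape != (len(feats), len(cells)):
        raise ValueError(
            "annotation mismatch: matrix is "
            f"{values.shape} but annotations describe {len(feats)} isoforms "
            f"and {len(cells)} cells"
        )
    isoform_ids = feats["isoform_id"].tolist()
    if len(set(isoform_ids)) != len(isoform_ids):
        raise ValueError("duplicate isoform ids in features table")
    cell_ids = cells["cell_id"].tolist()
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell ids in cells table")
    if np.any(values < 0):
        raise ValueError("negative values in count matrix")
    length_of = None
    if "length" in feats.columns and not feats["length"].isna().all():
        length_of = dict(zip(isoform_ids, feats["length"].astype(float)))
    return CountMatrix(
        values=values,
        isoform_ids=isoform_ids,
        cell_ids=cell_ids,
        cell_types=cells["cell_type"].tolist(),
        gene_of=dict(zip(isoform_ids, feats["gene_id"])),
        length_of=length_of,
    )


def read_counts(
    matrix_path: str | Path | None = None,
    features_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from disk.

    Either the Matrix Market triplet (``matrix_path`` + ``features_path`` +
    ``cells_path``) or a dense TSV (``tsv_path``, header row = cell ids, first
    column = isoform ids) with the two annotation TSVs. Row/column order is
    preserved from file.
    """
    if tsv_path is not None:
        dense = pd.read_csv(tsv_path, sep="\t", index_col=0)
        values = dense.to_numpy(dtype=float)
        if features_path is not None and cells_path is not None:
            feats, cells = _read_annotations(features_path, cells_path)
            if list(dense.index.astype(str)) != feats["isoform_id"].tolist():
                raise ValueError("annotation mismatch: isoform ids differ from TSV rows")
            if list(dense.columns.astype(str)) != cells["cell_id"].tolist():
                raise ValueError("annotation mismatch: cell ids differ from TSV columns")
            return _assemble(values, feats, cells)
        raise ValueError("dense TSV input also requires features_path and cells_path")
    if matrix_path is None or features_path is None or cells_path is None:
        raise ValueError("triplet input requires matrix_path, features_path, cells_path")
    mat = scipy.io.mmread(str(matrix_path))
    values = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
    )
    feats, cells = _read_annotations(features_path, cells_path)
    return _assemble(values, feats, cells)


def write_counts(
    matrix: CountMatrix, path: str | Path, format: str = "mtx"
) -> dict[str, Path]:
    """Write ``matrix`` under directory ``path``.

    ``format='mtx'`` writes a sparse Matrix Market triplet (only non-zero
    entries stored) with ``features.tsv`` and ``cells.tsv``; ``format='tsv'``
    writes a dense ``counts.tsv`` plus the same annotation TSVs. Output is
    parseable by :func:`read_counts`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lengths = (
        matrix.lengths()
        if matrix.length_of is not None
        else np.full(matrix.n_isoforms, np.nan)
    )
    feats = pd.DataFrame(
        {
            "isoform_id": matrix.isoform_ids,
            "gene_id": [matrix.gene_of.get(i, "") for i in matrix.isoform_ids],
            "length": lengths,
        }
    )
    cells = pd.DataFrame({"cell_id": matrix.cell_ids, "cell_type": matrix.cell_types})
    out: dict[str, Path] = {}
    out["features"] = path / "features.tsv"
    feats.to_csv(out["features"], sep="\t", index=False)
    out["cells"] = path / "cells.tsv"
    cells.to_csv(out["cells"], sep="\t", index=False)
    if format == "mtx":
        out["matrix"] = path / "matrix.mtx"
        sparse = scipy.sparse.coo_matrix(matrix.values)
        scipy.io.mmwrite(str(out["matrix"]), sparse)
    elif format == "tsv":
        out["matrix"] = path / "counts.tsv"
        pd.DataFrame(
            matrix.values, index=matrix.isoform_ids, columns=matrix.cell_ids
        ).to_csv(out["matrix"], sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
    return out


@dataclasses.dataclass
class AnalysisConfig:
    """All tunables of the pipeline, defaulting to the published settings."""

    # percentile summarization
    percentiles: int = 10
    # preprocessing
    min_detect_fraction: float = 0.25
    minor_threshold: float = 0.1
    minor_scope: str = "global"  # or "per_cell_type"
    library_lower: float = 0.0
    library_upper: float = float("inf")
    # DE consensus
    de_alpha: float = 0.05
    de_runs: int = 50
    min_run_fraction: float = 0.5
    downsample_targets: dict[str, int] = dataclasses.field(default_factory=dict)
    # clustering
    min_cluster_size: int = 20
    deep_split: int = 4
    qc_min_corr: float = 0.85
    qc_max_violations: int = 3
    expand_threshold: float = 0.9
    merge_height: float = 0.1
    qc2_min_corr: float = 0.7
    qc2_max_violations: int = 10
    recursive_thresholds: tuple[float, ...] = (0.9, 0.8, 0.7)
    final_merge_height: float = 0.1
    # coDIU
    codiu_alpha: float = 0.05
    codiu_theta: float = 10.0
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.percentiles < 1:
            raise ValueError("percentiles must be >= 1")
        for name, lo, hi in (
            ("min_detect_fraction", 0.0, 1.0),
            ("minor_threshold", 0.0, 1.0),
            ("de_alpha", 0.0, 1.0),
            ("min_run_fraction", 0.0, 1.0),
            ("qc_min_corr", -1.0, 1.0),
            ("expand_threshold", -1.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.minor_scope not in ("global", "per_cell_type"):
            raise ValueError("minor_scope must be 'global' or 'per_cell_type'")
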