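"""Length/depth normalization and quality-control filters.

Smart-seq-style single-cell quantification against a long-read transcriptome
shows a strong isoform-length bias. The normalization used here divides each
count by a per-cell depth factor and the square root of the isoform length in
kilobases:

    y_ij = c_ij / ( (1e-6 * sum_i c_ij) * sqrt(1e-3 * l_i) )

so an isoform of length 1000 nt reduces exactly to counts-per-million. The
library size is taken over all isoforms present in the matrix at call time;
run this before feature filtering to normalize against the full library.

The QC filters mirror common single-cell practice: library-size outlier
removal, cell-type-aware detection filtering (non-zero in >= 25% of cells of
at least one type), minor-isoform removal (< 10% of the gene's expression),
and the requirement that genes keep >= 2 isoforms so isoform-level co-usage
remains definable.
"""

from __future__ import annotations

import numpy as np

from .data_model import CountMatrix, NormalizedMatrix


def length_normalize(matrix: CountMatrix) -> NormalizedMatrix:
    """Depth- and length-normalize counts (see module docstring).

    Requires positive effective lengths for every isoform; raises on all-zero
    cells (undefined depth factor). Zeros map to zeros.
    """
    lengths = matrix.lengths()
    if np.any(~(lengths > 0)):
        raise ValueError("all isoform lengths must be positive")
    libraries = matrix.library_sizes()
    if np.any(libraries <= 0):
        bad = np.flatnonzero(libraries <= 0)
        raise ValueError(f"cells with zero library size: {bad.tolist()[:10]}")
    depth = 1e-6 * libraries  # per cell
    length_factor = np.sqrt(1e-3 * lengths)  # per isoform
    y = matrix.values / (depth[np.newaxis, :] * length_factor[:, np.newaxis])
    return NormalizedMatrix(
        values=y,
        isoform_ids=list(matrix.isoform_ids),
        cell_ids=list(matrix.cell_ids),
        cell_types=list(matrix.cell_types),
        gene_of=dict(matrix.gene_of),
        length_of=None if matrix.length_of is None else dict(matrix.length_of),
    )


def filter_cells_by_library_size(
    matrix: CountMatrix, lower: float, upper: float
) -> CountMatrix:
    """Keep cells with lower <= total counts <= upper (order preserved)."""
    if not lower < upper:
        raise ValueError("lower bound must be below upper bound")
    libraries = matrix.library_sizes()
    keep = np.flatnonzero((libraries >= lower) & (libraries <= upper))
    if keep.size == 0:
        raise ValueError("library-size filter removed every cell")
    return matrix.subset_cells(keep)


def detection_mask(matrix: CountMatrix, min_fraction: float = 0.25) -> np.ndarray:
    """Boolean row mask: isoform detected (count > 0) in >= ``min_fraction``
    of the cells of at least one cell type (inclusive comparison)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    keep = np.zeros(matrix.n_isoforms, dtype=bool)
    for t in matrix.type_names():
        cols = matrix.cells_of_type(t)
        frac = (matrix.values[:, cols] > 0).mean(axis=1)
        keep |= frac >= min_fraction
    return keep


def filter_features_by_detection(
    matrix: CountMatrix, min_fraction: float = 0.25
) -> CountMatrix:
    """Drop isoforms not detected in >= ``min_fraction`` of any one cell type."""
    return matrix.subset_isoforms(np.flatnonzero(detection_mask(matrix, min_fraction)))


def filter_minor_isoforms(
    matrix: CountMatrix, threshold: float = 0.1, scope: str = "global"
) -> CountMatrix:
    """Drop isoforms carrying < ``threshold`` of their gene's summed counts.

    ``scope='global'`` computes each isoform's share over all cells;
    ``scope='per_cell_type'`` keeps an isoform if it reaches the threshold
    share within at least one cell type. Single-isoform genes have share 1 and
    are never dropped.
    """
    if scope not in ("global", "per_cell_type"):
        raise ValueError(f"unknown scope {scope!r}")
    genes = matrix.genes()
    keep = np.zeros(matrix.n_isoforms, dtype=bool)
    scopes = (
        [np.arange(matrix.n_cells)]
        if scope == "global"
        else [matrix.cells_of_type(t) for t in matrix.type_names()]
    )
    for cols in scopes:
        iso_total = matrix.values[:, cols].sum(axis=1)
        for g in np.unique(genes):
            rows = np.flatnonzero(genes == g)
            gene_total = iso_total[rows].sum()
            if gene_total <= 0:
                continue  # no expression in this scope: share undefined
            share = iso_total[rows] / gene_total
            keep[rows] |= share >= threshold
    # genes with zero expression in every scope: share undefined, not minor
    overall = matrix.values.sum(axis=1)
    for g in np.unique(genes):
        rows = np.flatnonzero(genes == g)
        if overall[rows].sum() <= 0:
            keep[rows] = True
    return matrix.subset_isoforms(np.flatnonzero(keep))


def require_multi_isoform_genes(
    matrix: CountMatrix, selected_isoforms: list[str]
) -> list[str]:
    """Retain only selected isoforms whose gene has >= 2 isoforms selected.

    Removal is per-gene all-or-nothing, so a single pass reaches the fixpoint.
    """
    per_gene: dict[str, list[str]] = {}
    for iso in selected_isoforms:
        per_gene.setdefault(matrix.gene_of[iso], []).append(iso)
    return [
        iso for iso in selected_isoforms if len(per_gene[matrix.gene_of[iso]]) >= 2
    ]
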