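"""Percentile summarization and co-expression metrics.

Sparse, bursty single-cell counts make per-cell correlation of isoform
expression noisy and hard to interpret. The percentile correlation sidesteps
cell-level matching: within each cell type, an isoform's expression across
that type's cells is summarized by p+1 quantiles (probabilities 0, 1/p, ...,
1, linear interpolation between order statistics), and Pearson correlation is
then computed between isoforms over the concatenated K*(p+1) summary vectors.
Two isoforms correlate highly when they show similarly broad expression
distributions in each type and similar relative changes between types.

For benchmarking, four per-cell metrics are provided over the same
normalized matrix: Pearson, Spearman, a zero-inflated Kendall tau (mixture
adjustment for the point mass of zeros) and the proportionality measure rho
(log-based, pseudocount 1, zeros retained).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.stats

from .data_model import CountMatrix

METRICS = ("percentile", "pearson", "spearman", "zi_kendall", "rho")


@dataclasses.dataclass
class PercentileProfile:
    """Per-isoform K x (p+1) quantile summaries, cell types concatenated.

    ``values`` has shape (n_isoforms, K*(p+1)); within each cell-type block
    the values are non-decreasing (first = type minimum, last = maximum).
    ``summary='median_only'`` is the degenerate one-value-per-type mode.
    """

    values: np.ndarray
    isoform_ids: list[str]
    type_names: list[str]
    p: int
    summary: str = "percentiles"

    @property
    def block_size(self) -> int:
        return self.values.shape[1] // len(self.type_names)

    def row(self, isoform_id: str) -> np.ndarray:
        return self.values[self.isoform_ids.index(isoform_id)]


def percentile_summarize(
    matrix: CountMatrix, p: int = 10, summary: str = "percentiles"
) -> PercentileProfile:
    """Summarize each isoform's within-type expression by p+1 quantiles.

    Every cell type must contain at least 2 cells. With ``p=10`` each type
    contributes 11 values spanning the type minimum to maximum.
    ``summary='median_only'`` instead keeps a single per-type median.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if summary not in ("percentiles", "median_only"):
        raise ValueError(f"unknown summary mode {summary!r}")
    types = matrix.type_names()
    blocks = []
    for t in types:
        cols = matrix.cells_of_type(t)
        if cols.size < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells")
        sub = matrix.values[:, cols]
        if summary == "median_only":
            blocks.append(np.median(sub, axis=1, keepdims=True))
        else:
            probs = np.linspace(0.0, 1.0, p + 1)
            blocks.append(np.quantile(sub, probs, axis=1).T)
    return PercentileProfile(
        values=np.hstack(blocks),
        isoform_ids=list(matrix.isoform_ids),
        type_names=types,
        p=p,
        summary=summary,
    )


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric isoform x isoform co-expression matrix with a metric tag."""

    values: np.ndarray
    isoform_ids: list[str]
    metric: str


def _pearson_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows correlate 0 with
    everything (unit diagonal kept) so downstream distances stay defined."""
    x = np.asarray(values, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance profiles; their correlations are set to 0"
        )
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    r = unit @ unit.T
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def percentile_correlation(profiles: PercentileProfile) -> CorrelationMatrix:
    """Pearson correlation over the flattened K*(p+1) percentile vectors."""
    if profiles.values.shape[0] < 2:
        raise ValueError("need at least 2 isoforms")
    return CorrelationMatrix(
        values=_pearson_rows(profiles.values),
        isoform_ids=list(profiles.isoform_ids),
        metric="percentile",
    )


def zero_inflated_kendall(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau adjusted for a point mass at zero (Pimentel's tau*).

    tau* = p11^2 * tau11 + 2 (p00 p11 - p01 p10), where pab are the joint
    zero/positive probabilities and tau11 is the classical Kendall tau-b over
    the observations where both vectors are positive. With no zeros this
    reduces exactly to the classical tau.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    zx, zy = x == 0, y == 0
    n = x.size
    p00 = np.mean(zx & zy)
    p01 = np.mean(zx & ~zy)
    p10 = np.mean(~zx & zy)
    p11 = np.mean(~zx & ~zy)
    both = ~zx & ~zy
    if both.sum() >= 2:
        xb, yb = x[both], y[both]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            tau11 = 0.0
        else:
            tau11 = scipy.stats.kendalltau(xb, yb).statistic
            if not np.isfinite(tau11):
                tau11 = 0.0
    else:
        tau11 = 0.0
    return float(p11**2 * tau11 + 2 * (p00 * p11 - p01 * p10))


def _rho_matrix(values: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Proportionality rho_ij = 2 cov(li, lj) / (var li + var lj) over
    l = log(x + pseudocount); zeros are kept, not dropped."""
    logs = np.log(np.asarray(values, float) + pseudocount)
    cov = np.cov(logs)
    cov = np.atleast_2d(cov)
    var = np.diag(cov)
    denom = var[:, None] + var[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = 2.0 * cov / denom
    rho[~np.isfinite(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def metric(
    data: CountMatrix | PercentileProfile | np.ndarray,
    name: str,
    isoform_ids: list[str] | None = None,
) -> CorrelationMatrix:
    """Compute a named co-expression matrix.

    ``name='percentile'`` requires a :class:`PercentileProfile`; the four
    cell-level metrics take the per-cell expression matrix (rows = isoforms).
    """
    if name not in METRICS:
        raise ValueError(f"unknown metric {name!r}; choose from {METRICS}")
    if name == "percentile":
        if not isinstance(data, PercentileProfile):
            raise TypeError("percentile metric needs a PercentileProfile")
        return percentile_correlation(data)
    if isinstance(data, PercentileProfile):
        raise TypeError(f"{name} is a cell-level metric; pass per-cell expression")
    if isinstance(data, CountMatrix):
        values = data.values
        ids = list(data.isoform_ids)
    else:
        values = np.asarray(data, float)
        ids = isoform_ids or [str(i) for i in range(values.shape[0])]
    if name == "pearson":
        out = _pearson_rows(values)
    elif name == "spearman":
        ranks = scipy.stats.rankdata(values, axis=1)
        out = _pearson_rows(ranks)
    elif name == "rho":
        out = _rho_matrix(values)
    else:  # zi_kendall
        n = values.shape[0]
        out = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = zero_inflated_kendall(values[i], values[j])
    return CorrelationMatrix(values=out, isoform_ids=ids, metric=name)
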