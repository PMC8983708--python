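"""Multi-group differential expression with a negative-binomial GLM.

Each isoform is tested for any expression difference across the K cell types
by a likelihood-ratio test between

    log mu_ij = beta_0i + sum_{k=2..K} beta_ki T_kj        (full)
    log mu_ij = beta_0i                                     (intercept-only)

with counts modelled as negative binomial; the LR statistic is referred to a
chi-square with K-1 degrees of freedom. The per-isoform dispersion is
estimated by a within-group method of moments (floored at 1e-8) unless a
fixed theta is supplied. An optional per-observation weight vector is
accepted so externally computed zero-inflation weights (e.g. ZinBWaVE-style)
can be injected; weight estimation itself is out of scope.

Because glial/neural cell numbers are typically very unbalanced, the module
also implements a downsampling consensus: R independent rounds of per-type
random cell subsampling, re-filtering and DE testing, with the consensus set
defined as the isoforms significant (BH FDR < alpha) in at least a fraction
of the runs, plus Jaccard-index agreement summaries over all run pairs.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .data_model import CountMatrix
from .preprocess import detection_mask

DISPERSION_FLOOR = 1e-8


def estimate_dispersion(y: np.ndarray, cell_types: Sequence[str]) -> float:
    """Method-of-moments NB dispersion alpha (var = mu + alpha mu^2).

    Moments are taken within each cell type (so genuine between-type
    differences do not inflate the estimate) and combined by a cell-number
    weighted average, floored at ``DISPERSION_FLOOR``.
    """
    y = np.asarray(y, dtype=float)
    types = np.asarray(cell_types)
    alphas, weights = [], []
    for t in np.unique(types):
        yk = y[types == t]
        if yk.size < 2:
            continue
        mu = yk.mean()
        if mu <= 0:
            continue
        var = yk.var(ddof=1)
        alphas.append(max((var - mu) / mu**2, 0.0))
        weights.append(yk.size)
    if not alphas:
        return DISPERSION_FLOOR
    return max(float(np.average(alphas, weights=weights)), DISPERSION_FLOOR)


def _design(cell_types: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies for types 2..K (first-appearance
    order fixes the reference type)."""
    types = np.asarray(cell_types)
    seen: dict[str, None] = {}
    for t in types:
        seen.setdefault(t)
    names = list(seen)
    X = np.ones((types.size, len(names)))
    for k, name in enumerate(names[1:], start=1):
        X[:, k] = types == name
    return X, names


def nb_multigroup_test(
    y_row: np.ndarray,
    cell_types: Sequence[str],
    weights: np.ndarray | None = None,
    theta: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """LR test of any between-type expression difference for one isoform.

    Returns ``(lr_stat, p_value, coefficients)``; a degenerate or
    non-converging fit yields ``(nan, nan, nan-array)`` rather than raising.
    """
    y = np.asarray(y_row, dtype=float)
    types = np.asarray(cell_types)
    k = len(set(types.tolist()))
    if k < 2:
        raise ValueError("need at least 2 cell types")
    counts = pd.Series(types).value_counts()
    if counts.min() < 2:
        raise ValueError("every cell type needs at least 2 cells")
    X, _ = _design(types)
    nan_out = (float("nan"), float("nan"), np.full(X.shape[1], np.nan))
    if not np.any(y > 0):
        return nan_out
    alpha = 1.0 / theta if theta is not None else estimate_dispersion(y, types)
    family = sm.families.NegativeBinomial(alpha=alpha)
    kwargs = {} if weights is None else {"var_weights": np.asarray(weights, float)}
    try:
        full = sm.GLM(y, X, family=family, **kwargs).fit()
        null = sm.GLM(y, X[:, :1], family=family, **kwargs).fit()
    except Exception:
        return nan_out
    lr = 2.0 * (full.llf - null.llf)
    if not np.isfinite(lr):
        return nan_out
    lr = max(lr, 0.0)
    p = float(scipy.stats.chi2.sf(lr, df=k - 1))
    return float(lr), p, np.asarray(full.params)


@dataclasses.dataclass
class DEResult:
    """Per-isoform test results; ``table`` has columns lr, p, fdr."""

    table: pd.DataFrame
    coefficients: pd.DataFrame
    alpha: float

    @property
    def de_isoforms(self) -> set[str]:
        sig = self.table["fdr"] < self.alpha
        return set(self.table.index[sig.fillna(False)])


def run_de(
    matrix: CountMatrix,
    alpha: float = 0.05,
    weights: np.ndarray | None = None,
    theta: float | None = None,
) -> DEResult:
    """Test every isoform and BH-adjust p-values across all tested isoforms.

    Isoforms whose fit fails are kept in the table with NA p/FDR and excluded
    from the BH family. The DE set is {FDR < alpha}.
    """
    lrs, ps, coefs = [], [], []
    for i in range(matrix.n_isoforms):
        w = None if weights is None else weights[i]
        lr, p, beta = nb_multigroup_test(
            matrix.values[i], matrix.cell_types, weights=w, theta=theta
        )
        lrs.append(lr)
        ps.append(p)
        coefs.append(beta)
    table = pd.DataFrame({"lr": lrs, "p": ps}, index=matrix.isoform_ids)
    fdr = np.full(len(table), np.nan)
    ok = table["p"].notna().to_numpy()
    if ok.any():
        fdr[ok] = multipletests(table["p"].to_numpy()[ok], method="fdr_bh")[1]
    table["fdr"] = fdr
    _, names = _design(matrix.cell_types)
    coef_df = pd.DataFrame(coefs, index=matrix.isoform_ids, columns=names)
    return DEResult(table=table, coefficients=coef_df, alpha=alpha)


def downsample_cells(
    cell_types: Sequence[str], targets: dict[str, int], seed: int
) -> np.ndarray:
    """Per-type random cell subsets without replacement (deterministic per seed).

    Types absent from ``targets`` are fully retained. Returns sorted column
    indices into the original cell order.
    """
    types = np.asarray(cell_types)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    seen: dict[str, None] = {}
    for t in types:
        seen.setdefault(t)
    for t in seen:
        idx = np.flatnonzero(types == t)
        if t in targets:
            n = targets[t]
            if n > idx.size:
                raise ValueError(
                    f"target {n} exceeds the {idx.size} available {t!r} cells"
                )
            idx = rng.choice(idx, size=n, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|; two empty sets agree perfectly (1 by convention)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def agreement_summary(de_sets: Sequence[set]) -> tuple[float, float, int]:
    """Mean and sd of pairwise Jaccard over all C(R,2) run pairs."""
    if len(de_sets) < 2:
        raise ValueError("need at least 2 runs to summarize agreement")
    values = [jaccard(a, b) for a, b in itertools.combinations(de_sets, 2)]
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return float(np.mean(values)), sd, len(values)


@dataclasses.dataclass
class ConsensusDESet:
    """Downsampling-consensus DE output."""

    runs: list[set[str]]
    consensus: set[str]
    jaccard_mean: float
    jaccard_sd: float
    n_comparisons: int


Engine = Callable[[CountMatrix], set]


def consensus_de(
    matrix: CountMatrix,
    targets: dict[str, int],
    R: int = 50,
    min_run_fraction: float = 0.5,
    seeds: Sequence[int] | None = None,
    alpha: float = 0.05,
    min_detect_fraction: float = 0.25,
    engines: Sequence[Engine] | None = None,
    theta: float | None = None,
) -> ConsensusDESet:
    """Downsample -> re-filter -> test, R times; keep recurrent DE isoforms.

    Each run re-applies the detection filter on the subsampled cells (zeros
    become more abundant after downsampling) and unions the DE sets of all
    configured engines (default: the built-in NB GLM LR test). An isoform
    enters the consensus if DE in >= ceil(min_run_fraction * R) runs
    (inclusive).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if seeds is None:
        seeds = list(range(R))
    if len(seeds) != R:
        raise ValueError("need exactly one seed per run")
    if engines is None:
        engines = [lambda m: run_de(m, alpha=alpha, theta=theta).de_isoforms]
    run_sets: list[set[str]] = []
    for seed in seeds:
        cols = downsample_cells(matrix.cell_types, targets, seed)
        sub = matrix.subset_cells(cols)
        sub = sub.subset_isoforms(
            np.flatnonzero(detection_mask(sub, min_detect_fraction))
        )
        de: set[str] = set()
        for engine in engines:
            de |= set(engine(sub))
        run_sets.append(de)
    counts: dict[str, int] = {}
    for s in run_sets:
        for iso in s:
            counts[iso] = counts.get(iso, 0) + 1
    need = int(np.ceil(min_run_fraction * R))
    consensus = {iso for iso, c in counts.items() if c >= need}
    if R > 1:
        jm, js, npairs = agreement_summary(run_sets)
    else:
        jm, js, npairs = 1.0, 0.0, 0
    return ConsensusDESet(
        runs=run_sets,
        consensus=consensus,
        jaccard_mean=jm,
        jaccard_sd=js,
        n_comparisons=npairs,
    )
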