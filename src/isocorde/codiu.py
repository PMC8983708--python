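"""Differential and co-differential isoform usage (DIU / coDIU).

A gene shows *differential isoform usage* (DIU) when at least two of its
isoforms land in different co-expression clusters: its isoform selection
pattern changes across cell types. Two genes show *co-differential isoform
usage* (coDIU) when at least two of their isoforms were assigned to the same
clusters — their isoform switches are coordinated across cell types — and a
stacked negative-binomial GLM confirms that the coordination is carried by
the clusters rather than by gene-level expression.

For a candidate gene pair with one representative isoform per gene per
shared cluster, the stacked response z (all isoform count vectors
concatenated; |z| = sum_g I_g * N, i.e. 4N in the two-gene / two-cluster
case) is modelled with log link and fixed dispersion theta:

    log mu = b0 + b1*G2 + b2*C2 + sum_k gamma_k*T_k + b3*G2*C2
             + sum_k delta_k*T_k*G2 + sum_k tau_k*T_k*C2

Type-II likelihood-ratio tests drop one interaction at a time (all main
effects and the other interaction retained). A pair is positive for coDIU
when the cluster x cell-type interaction is significant (BH FDR < alpha) and
the gene x cell-type interaction is not (FDR > alpha); the two interaction
p-value families are BH-adjusted separately. A gene is called coDIU when it
is positive in at least one pair.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterAssignment
from .data_model import CountMatrix


def label_diu(
    assignment: ClusterAssignment, gene_of: Mapping[str, str]
) -> set[str]:
    """Genes with >= 2 (clustered) isoforms in >= 2 distinct clusters."""
    clusters_per_gene: dict[str, set[int]] = {}
    for iso, label in zip(assignment.isoform_ids, assignment.labels):
        if label == 0 or iso not in gene_of:
            continue
        clusters_per_gene.setdefault(gene_of[iso], set()).add(int(label))
    return {g for g, cl in clusters_per_gene.items() if len(cl) >= 2}


@dataclasses.dataclass
class CandidatePair:
    """A gene pair sharing >= 2 clusters, with one representative isoform
    per gene per shared cluster."""

    gene_a: str
    gene_b: str
    shared_clusters: tuple[int, ...]
    representatives: dict[str, dict[int, str]]  # gene -> cluster -> isoform


def candidate_pairs(
    assignment: ClusterAssignment,
    gene_of: Mapping[str, str],
    mean_expression: Mapping[str, float] | None = None,
) -> list[CandidatePair]:
    """Enumerate gene pairs with >= 2 shared clusters.

    When a gene has several isoforms in one shared cluster, the
    representative is the isoform with the highest mean expression
    (``mean_expression``); without expression information the
    lexicographically smallest id is taken.
    """
    iso_by_gene_cluster: dict[str, dict[int, list[str]]] = {}
    for iso, label in zip(assignment.isoform_ids, assignment.labels):
        if label == 0 or iso not in gene_of:
            continue
        iso_by_gene_cluster.setdefault(gene_of[iso], {}).setdefault(
            int(label), []
        ).append(iso)

    def representative(gene: str, cluster: int) -> str:
        isos = iso_by_gene_cluster[gene][cluster]
        if mean_expression is not None:
            return max(isos, key=lambda i: (mean_expression.get(i, 0.0), i))
        return min(isos)

    pairs: list[CandidatePair] = []
    genes = sorted(iso_by_gene_cluster)
    for ga, gb in itertools.combinations(genes, 2):
        shared = sorted(
            set(iso_by_gene_cluster[ga]) & set(iso_by_gene_cluster[gb])
        )
        if len(shared) < 2:
            continue
        pairs.append(
            CandidatePair(
                gene_a=ga,
                gene_b=gb,
                shared_clusters=tuple(shared),
                representatives={
                    g: {c: representative(g, c) for c in shared} for g in (ga, gb)
                },
            )
        )
    return pairs


@dataclasses.dataclass
class CoDIUFit:
    """Interaction test results for one candidate pair."""

    pair: CandidatePair
    p_cluster_type: float
    p_gene_type: float
    lr_cluster_type: float
    lr_gene_type: float
    coefficients: np.ndarray | None
    converged: bool

    _n_obs: int = 0

    @property
    def n_obs(self) -> int:
        """Length of the stacked response z (sum_g I_g * N)."""
        return self._n_obs


def _stacked_design(
    pair: CandidatePair, counts: CountMatrix
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Build the stacked response and covariate blocks for the coDIU GLM."""
    types = np.asarray(counts.cell_types)
    seen: dict[str, None] = {}
    for t in types:
        seen.setdefault(t)
    type_names = list(seen)
    t_dummies = np.column_stack([types == t for t in type_names[1:]]).astype(float)
    if t_dummies.ndim == 1:
        t_dummies = t_dummies[:, None]
    shared = pair.shared_clusters
    n_cells = counts.n_cells
    row_of = {iso: i for i, iso in enumerate(counts.isoform_ids)}
    z_parts, g2_parts, c_parts, t_parts = [], [], [], []
    for gi, gene in enumerate((pair.gene_a, pair.gene_b)):
        for ci, cluster in enumerate(shared):
            iso = pair.representatives[gene][cluster]
            if iso not in row_of:
                raise ValueError(f"isoform {iso!r} missing from the count matrix")
            z_parts.append(counts.values[row_of[iso]])
            g2_parts.append(np.full(n_cells, float(gi)))
            c_block = np.zeros((n_cells, len(shared) - 1))
            if ci > 0:
                c_block[:, ci - 1] = 1.0
            c_parts.append(c_block)
            t_parts.append(t_dummies)
    z = np.concatenate(z_parts)
    g2 = np.concatenate(g2_parts)
    c = np.vstack(c_parts)
    t = np.vstack(t_parts)
    blocks = {
        "intercept": np.ones((z.size, 1)),
        "G": g2[:, None],
        "C": c,
        "T": t,
        "GxC": g2[:, None] * c,
        "TxG": t * g2[:, None],
        "TxC": np.hstack([t * c[:, j : j + 1] for j in range(c.shape[1])]),
    }
    return z, blocks


def codiu_test(
    pair: CandidatePair,
    counts: CountMatrix,
    theta: float = 10.0,
) -> CoDIUFit:
    """Fit the stacked NB GLM and run both type-II LR interaction tests.

    The response is raw counts over all N cells for every representative
    isoform; dispersion is fixed (theta = 10 by default). Non-convergence
    yields a flagged fit (NaN p-values) that callers exclude from BH.
    """
    if len(pair.shared_clusters) < 2:
        raise ValueError("pair must share at least 2 clusters")
    z, blocks = _stacked_design(pair, counts)
    order = ["intercept", "G", "C", "T", "GxC", "TxG", "TxC"]
    family = sm.families.NegativeBinomial(alpha=1.0 / theta)

    def fit(drop: str | None) -> tuple[float, int] | None:
        X = np.hstack([blocks[b] for b in order if b != drop])
        try:
            res = sm.GLM(z, X, family=family).fit(maxiter=200)
        except Exception:
            return None
        if not np.isfinite(res.llf):
            return None
        return float(res.llf), X.shape[1]

    full = fit(None)
    no_txc = fit("TxC")
    no_txg = fit("TxG")
    failed = full is None or no_txc is None or no_txg is None
    if failed:
        return CoDIUFit(
            pair=pair,
            p_cluster_type=float("nan"),
            p_gene_type=float("nan"),
            lr_cluster_type=float("nan"),
            lr_gene_type=float("nan"),
            coefficients=None,
            converged=False,
        )
    llf_full, _ = full
    lr_c = max(2.0 * (llf_full - no_txc[0]), 0.0)
    lr_g = max(2.0 * (llf_full - no_txg[0]), 0.0)
    df_c = blocks["TxC"].shape[1]
    df_g = blocks["TxG"].shape[1]
    fit_obj = CoDIUFit(
        pair=pair,
        p_cluster_type=float(scipy.stats.chi2.sf(lr_c, df=df_c)),
        p_gene_type=float(scipy.stats.chi2.sf(lr_g, df=df_g)),
        lr_cluster_type=lr_c,
        lr_gene_type=lr_g,
        coefficients=None,
        converged=True,
    )
    fit_obj._n_obs = z.size
    return fit_obj


@dataclasses.dataclass
class CoDIUResult:
    """BH-adjusted pair table and the gene-level coDIU call."""

    table: pd.DataFrame
    positive_pairs: list[CandidatePair]
    genes: set[str]


def call_codiu(fits: Sequence[CoDIUFit], alpha: float = 0.05) -> CoDIUResult:
    """BH per interaction family; a pair is positive iff cluster x type FDR
    < alpha AND gene x type FDR > alpha; genes positive in >= 1 pair."""
    converged = [f for f in fits if f.converged]
    rows = []
    fdr_c = np.array([])
    fdr_g = np.array([])
    if converged:
        fdr_c = multipletests(
            [f.p_cluster_type for f in converged], method="fdr_bh"
        )[1]
        fdr_g = multipletests([f.p_gene_type for f in converged], method="fdr_bh")[1]
    positive: list[CandidatePair] = []
    genes: set[str] = set()
    for f, qc, qg in zip(converged, fdr_c, fdr_g):
        is_pos = bool(qc < alpha and qg > alpha)
        rows.append(
            {
                "gene_a": f.pair.gene_a,
                "gene_b": f.pair.gene_b,
                "shared_clusters": ",".join(map(str, f.pair.shared_clusters)),
                "p_cluster_type": f.p_cluster_type,
                "fdr_cluster_type": qc,
                "p_gene_type": f.p_gene_type,
                "fdr_gene_type": qg,
                "codiu": is_pos,
            }
        )
        if is_pos:
            positive.append(f.pair)
            genes |= {f.pair.gene_a, f.pair.gene_b}
    for f in fits:
        if not f.converged:
            rows.append(
                {
                    "gene_a": f.pair.gene_a,
                    "gene_b": f.pair.gene_b,
                    "shared_clusters": ",".join(map(str, f.pair.shared_clusters)),
                    "p_cluster_type": float("nan"),
                    "fdr_cluster_type": float("nan"),
                    "p_gene_type": float("nan"),
                    "fdr_gene_type": float("nan"),
                    "codiu": False,
                }
            )
    return CoDIUResult(table=pd.DataFrame(rows), positive_pairs=positive, genes=genes)


def build_network(result: CoDIUResult, assignment: ClusterAssignment):
    """Cluster-level coDIU network (networkx Graph).

    Nodes are clusters (attribute ``size`` = member count); an edge between
    clusters (c1, c2) carries the set of distinct coDIU genes whose positive
    pairs share both clusters, with ``weight`` = that count. Undirected; a
    gene appearing in several positive pairs on the same cluster pair is
    counted once.
    """
    import networkx as nx

    g = nx.Graph()
    for label in assignment.cluster_labels():
        g.add_node(label, size=len(assignment.members(label)))
    edge_genes: dict[tuple[int, int], set[str]] = {}
    for pair in result.positive_pairs:
        for c1, c2 in itertools.combinations(sorted(pair.shared_clusters), 2):
            edge_genes.setdefault((c1, c2), set()).update(
                (pair.gene_a, pair.gene_b)
            )
    for (c1, c2), genes in edge_genes.items():
        g.add_edge(c1, c2, weight=len(genes), genes=sorted(genes))
    return g


def peak_types(
    metas: Mapping[int, np.ndarray], type_names: Sequence[str]
) -> dict[int, list[str]]:
    """Cell types where each cluster's metatranscript 'peaks'.

    Heuristic: a cluster peaks in the types whose per-type mean of the
    metatranscript exceeds the across-type mean + 1 sd (ddof=0); if no type
    qualifies, the single highest type is taken.
    """
    out: dict[int, list[str]] = {}
    k = len(type_names)
    for label, meta in metas.items():
        per_type = np.asarray(meta, float).reshape(k, -1).mean(axis=1)
        cut = per_type.mean() + per_type.std()
        peaks = [t for t, v in zip(type_names, per_type) if v > cut]
        if not peaks:
            peaks = [type_names[int(np.argmax(per_type))]]
        out[label] = peaks
    return out


def celltype_summary(
    network,
    metas: Mapping[int, np.ndarray],
    type_names: Sequence[str],
) -> pd.DataFrame:
    """K x K table of coDIU gene counts per cell-type pair.

    Each network edge contributes its weight to every unordered pair of cell
    types in which its two clusters peak (see :func:`peak_types`).
    """
    peaks = peak_types(metas, type_names)
    summary = pd.DataFrame(
        0, index=list(type_names), columns=list(type_names), dtype=int
    )
    for c1, c2, data in network.edges(data=True):
        involved = sorted(set(peaks.get(c1, [])) | set(peaks.get(c2, [])))
        for ta, tb in itertools.combinations_with_replacement(involved, 2):
            summary.loc[ta, tb] += data["weight"]
            if ta != tb:
                summary.loc[tb, ta] += data["weight"]
    return summary
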