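import numpy as np
import pytest

from isocorde import (
    CountMatrix,
    build_network,
    call_codiu,
    candidate_pairs,
    celltype_summary,
    codiu_test,
    label_diu,
)
from isocorde.clustering import ClusterAssignment
from isocorde.codiu import CandidatePair, CoDIUFit, _stacked_design


def _assignment(mapping):
    ids = list(mapping)
    return ClusterAssignment(
        isoform_ids=ids, labels=np.array([mapping[i] for i in ids], int)
    )


def _nb_counts(rng, means_per_iso, n_per_type=30, theta=10.0):
    K = len(next(iter(means_per_iso.values())))
    types = sum([[f"t{k + 1}"] * n_per_type for k in range(K)], [])
    ids = list(means_per_iso)
    rows = []
    for iso in ids:
        mu = np.repeat(means_per_iso[iso], n_per_type).astype(float)
        rows.append(rng.negative_binomial(theta, theta / (theta + mu)))
    return CountMatrix(
        values=np.array(rows, float),
        isoform_ids=ids,
        cell_ids=[f"c{j}" for j in range(len(types))],
        cell_types=types,
        gene_of={i: i.split("_")[0] for i in ids},
    )


_PAIR = CandidatePair(
    "gA",
    "gB",
    (1, 2),
    {"gA": {1: "gA_i1", 2: "gA_i2"}, "gB": {1: "gB_i1", 2: "gB_i2"}},
)

HI, LO = 40.0, 10.0
_SWITCH = {
    "gA_i1": [HI, HI, LO, LO],
    "gA_i2": [LO, LO, HI, HI],
    "gB_i1": [HI, HI, LO, LO],
    "gB_i2": [LO, LO, HI, HI],
}


def test_diu_requires_two_isoforms_in_two_clusters():
    genes = {"gA_i1": "gA", "gA_i2": "gA", "gB_i1": "gB", "gB_i2": "gB",
             "gC_i1": "gC", "gC_i2": "gC", "gC_i3": "gC"}
    a = _assignment(
        {"gA_i1": 1, "gA_i2": 2, "gB_i1": 1, "gB_i2": 1,
         "gC_i1": 1, "gC_i2": 1, "gC_i3": 2}
    )
    assert label_diu(a, genes) == {"gA", "gC"}


def test_candidate_pairs_need_two_shared_clusters():
    genes = {f"{g}_i{k}": g for g in ("g1", "g2", "g3") for k in (1, 2, 3)}
    a = _assignment(
        {
            "g1_i1": 1, "g1_i2": 2, "g1_i3": 3,
            "g2_i1": 2, "g2_i2": 3, "g2_i3": 0,
            "g3_i1": 1, "g3_i2": 4, "g3_i3": 0,
        }
    )
    pairs = candidate_pairs(a, genes)
    assert len(pairs) == 1
    assert (pairs[0].gene_a, pairs[0].gene_b) == ("g1", "g2")
    assert pairs[0].shared_clusters == (2, 3)


def test_representative_is_highest_mean_expression():
    genes = {"g1_a": "g1", "g1_b": "g1", "g1_c": "g1", "g2_a": "g2", "g2_b": "g2"}
    a = _assignment({"g1_a": 1, "g1_b": 1, "g1_c": 2, "g2_a": 1, "g2_b": 2})
    pairs = candidate_pairs(
        a, genes, mean_expression={"g1_a": 1.0, "g1_b": 9.0, "g1_c": 2.0,
                                   "g2_a": 3.0, "g2_b": 4.0}
    )
    assert pairs[0].representatives["g1"][1] == "g1_b"


def test_stacked_design_dimensionality_is_4n():
    rng = np.random.default_rng(0)
    counts = _nb_counts(rng, _SWITCH, n_per_type=25)
    z, blocks = _stacked_design(_PAIR, counts)
    n = counts.n_cells
    assert z.size == 4 * n
    assert blocks["T"].shape == (4 * n, counts.k_types - 1)
    assert blocks["TxC"].shape == (4 * n, counts.k_types - 1)


def test_codiu_detects_coordinated_switch_and_rejects_gene_effect():
    rng = np.random.default_rng(1)
    counts = _nb_counts(rng, _SWITCH, n_per_type=30)
    fit = codiu_test(_PAIR, counts)
    assert fit.converged
    assert fit.p_cluster_type < 0.05
    assert fit.p_gene_type > 0.05
    # different gene-level trajectories: gene x type interaction lights up
    skew = dict(_SWITCH)
    skew["gB_i1"] = [5 * HI, HI, LO, LO]
    skew["gB_i2"] = [5 * LO, LO, HI, HI]
    counts2 = _nb_counts(np.random.default_rng(2), skew, n_per_type=30)
    fit2 = codiu_test(_PAIR, counts2)
    assert fit2.p_gene_type < 0.05


def test_codiu_pvalues_invariant_under_gene_swap():
    rng = np.random.default_rng(3)
    counts = _nb_counts(rng, _SWITCH, n_per_type=20)
    fit = codiu_test(_PAIR, counts)
    swapped = CandidatePair(
        "gB",
        "gA",
        (1, 2),
        {"gB": _PAIR.representatives["gB"], "gA": _PAIR.representatives["gA"]},
    )
    fit_sw = codiu_test(swapped, counts)
    assert fit.p_cluster_type == pytest.approx(fit_sw.p_cluster_type, abs=1e-10)
    assert fit.p_gene_type == pytest.approx(fit_sw.p_gene_type, abs=1e-10)


def test_codiu_pvalues_invariant_under_cluster_swap():
    rng = np.random.default_rng(4)
    counts = _nb_counts(rng, _SWITCH, n_per_type=20)
    fit = codiu_test(_PAIR, counts)
    relabeled = CandidatePair(
        "gA",
        "gB",
        (1, 2),
        {
            "gA": {1: "gA_i2", 2: "gA_i1"},
            "gB": {1: "gB_i2", 2: "gB_i1"},
        },
    )
    fit_rl = codiu_test(relabeled, counts)
    assert fit.p_cluster_type == pytest.approx(fit_rl.p_cluster_type, abs=1e-10)
    assert fit.p_gene_type == pytest.approx(fit_rl.p_gene_type, abs=1e-10)


def _fake_fit(pair, p_ct, p_gt):
    return CoDIUFit(
        pair=pair,
        p_cluster_type=p_ct,
        p_gene_type=p_gt,
        lr_cluster_type=1.0,
        lr_gene_type=1.0,
        coefficients=None,
        converged=True,
    )


def test_call_rule_requires_both_criteria():
    single = call_codiu([_fake_fit(_PAIR, 0.001, 0.8)], alpha=0.05)
    assert single.genes == {"gA", "gB"}
    both_sig = call_codiu([_fake_fit(_PAIR, 0.04, 0.04)], alpha=0.05)
    assert both_sig.genes == set()
    assert not both_sig.table["codiu"].any()


def test_bh_families_are_adjusted_separately():
    pairs = [
        CandidatePair(f"a{k}", f"b{k}", (1, 2), {}) for k in range(4)
    ]
    fits = [
        _fake_fit(pairs[0], 0.001, 0.9),
        _fake_fit(pairs[1], 0.002, 0.9),
        _fake_fit(pairs[2], 0.9, 0.001),
        _fake_fit(pairs[3], 0.8, 0.7),
    ]
    res = call_codiu(fits, alpha=0.05)
    t = res.table.set_index("gene_a")
    # cluster-type FDRs adjusted within their own family of 4
    assert t.loc["a0", "fdr_cluster_type"] == pytest.approx(0.004)
    assert t.loc["a2", "fdr_gene_type"] == pytest.approx(0.004)
    assert res.genes == {"a0", "b0", "a1", "b1"}


def test_network_edges_count_distinct_genes_once():
    pair_ab = CandidatePair("gA", "gB", (1, 2), {})
    pair_ac = CandidatePair("gA", "gC", (1, 2), {})
    res = call_codiu(
        [_fake_fit(pair_ab, 0.001, 0.9), _fake_fit(pair_ac, 0.001, 0.9)],
        alpha=0.05,
    )
    a = _assignment({"x1": 1, "x2": 1, "x3": 2, "x4": 2})
    net = build_network(res, a)
    assert net.edges[1, 2]["weight"] == 3  # gA counted once
    assert net.nodes[1]["size"] == 2


def test_empty_calls_give_empty_edge_set():
    res = call_codiu([_fake_fit(_PAIR, 0.9, 0.9)], alpha=0.05)
    net = build_network(res, _assignment({"x1": 1, "x2": 2}))
    assert net.number_of_edges() == 0


def test_celltype_summary_accumulates_peak_types():
    pair = CandidatePair("gA", "gB", (1, 2), {})
    res = call_codiu([_fake_fit(pair, 0.001, 0.9)], alpha=0.05)
    a = _assignment({"x1": 1, "x2": 2})
    net = build_network(res, a)
    # cluster 1 peaks in type A, cluster 2 in type B (2 types, 3 values each)
    metas = {
        1: np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0]),
        2: np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]),
    }
    summary = celltype_summary(net, metas, ["A", "B"])
    assert summary.loc["A", "B"] == 2
    assert summary.loc["B", "A"] == 2


def test_null_random_clusters_positive_rate_near_nominal():
    """With no cluster-dependent structure, the fraction of pairs passing
    the coDIU rule at alpha=0.05 stays at or below nominal + 3 points."""
    flat = {k: [20.0, 20.0, 20.0, 20.0] for k in _SWITCH}
    positives = 0
    n_pairs = 300
    for r in range(n_pairs):
        counts = _nb_counts(np.random.default_rng(5000 + r), flat, n_per_type=25)
        fit = codiu_test(_PAIR, counts)
        positives += fit.p_cluster_type < 0.05 and fit.p_gene_type > 0.05
    assert positives / n_pairs <= 0.05 + 0.03


def test_planted_codiu_recovery_recall():
    """Coordinated 4-fold isoform switches across 2 clusters are recovered
    with recall >= 0.9 at alpha = 0.05 after per-family BH."""
    fits = []
    n_planted = 40
    for r in range(n_planted):
        counts = _nb_counts(np.random.default_rng(9000 + r), _SWITCH, n_per_type=30)
        fits.append(codiu_test(_PAIR, counts))
    res = call_codiu(fits, alpha=0.05)
    recall = len(res.positive_pairs) / n_planted
    assert recall >= 0.9
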