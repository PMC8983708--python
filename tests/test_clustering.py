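import numpy as np
import pytest

from isocorde import (
    cluster_pipeline,
    dendrogram,
    dynamic_cut,
    expand,
    merge,
    metatranscripts,
    qc_filter,
    recursive_assign,
    to_distance,
)
from isocorde.clustering import (
    ClusterAssignment,
    DistanceMatrix,
    UNCLUSTERED,
    apply_merge,
)
from isocorde.correlation import CorrelationMatrix, PercentileProfile


def _corr(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"i{k}" for k in range(values.shape[0])]
    return CorrelationMatrix(values=values, isoform_ids=ids, metric="percentile")


def _profiles(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"i{k}" for k in range(values.shape[0])]
    return PercentileProfile(
        values=values, isoform_ids=ids, type_names=["A"], p=values.shape[1] - 1
    )


# ---------------------------------------------------------------------------
# distance transform
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "r, d", [(1.0, 0.0), (-0.5, 1.0), (0.0, 1.0), (0.25, 0.75), (0.999, 0.001)]
)
def test_distance_transform_cases(r, d):
    c = _corr([[1.0, r], [r, 1.0]])
    out = to_distance(c)
    assert out.values[0, 1] == pytest.approx(d)
    assert out.values[0, 0] == 0.0


def test_distance_maps_into_unit_interval_with_zero_only_at_one():
    rng = np.random.default_rng(0)
    r = np.clip(rng.uniform(-1, 1, size=(20, 20)), -1, 1)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    d = to_distance(_corr(r)).values
    assert d.min() >= 0.0 and d.max() <= 1.0
    off = ~np.eye(20, dtype=bool)
    assert np.all((d[off] == 0) == (r[off] == 1))


# ---------------------------------------------------------------------------
# dendrogram vs a brute-force average-linkage oracle
# ---------------------------------------------------------------------------


def _naive_average_linkage_heights(dist):
    """O(n^3) agglomeration: repeatedly join the closest pair of clusters,
    recomputing all-pairs mean distances from scratch."""
    clusters = [[k] for k in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([[dist[x, y] for y in clusters[b]] for x in clusters[a]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


def test_average_linkage_matches_naive_oracle():
    rng = np.random.default_rng(42)
    points = rng.normal(size=(10, 3))
    dist = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    dist /= dist.max()
    tree = dendrogram(DistanceMatrix(values=dist, isoform_ids=list("abcdefghij")))
    np.testing.assert_allclose(
        np.sort(tree[:, 2]), np.sort(_naive_average_linkage_heights(dist)), rtol=1e-10
    )


def test_two_leaves_merge_at_their_distance():
    d = DistanceMatrix(values=np.array([[0.0, 0.3], [0.3, 0.0]]), isoform_ids=["a", "b"])
    tree = dendrogram(d)
    assert tree.shape == (1, 4)
    assert tree[0, 2] == pytest.approx(0.3)


def test_equilateral_triplet_merges_at_equal_heights():
    d = np.ones((3, 3)) - np.eye(3)
    tree = dendrogram(DistanceMatrix(values=d, isoform_ids=["a", "b", "c"]))
    np.testing.assert_allclose(tree[:, 2], [1.0, 1.0])


# ---------------------------------------------------------------------------
# dynamic cut
# ---------------------------------------------------------------------------


def _blob_distance(sizes, intra=0.05, inter=0.9, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    d = np.full((n, n), inter) + rng.uniform(0, 0.02, (n, n))
    start = 0
    for s in sizes:
        block = rng.uniform(0, intra, (s, s))
        d[start : start + s, start : start + s] = block
        start += s
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, isoform_ids=[f"i{k}" for k in range(n)])


def test_two_separated_blobs_give_two_full_clusters():
    dist = _blob_distance([30, 30])
    tree = dendrogram(dist)
    a = dynamic_cut(tree, dist.isoform_ids, min_cluster_size=20)
    assert a.n_clusters == 2
    assert a.fraction_unclustered == 0.0
    assert sorted(len(a.members(l)) for l in a.cluster_labels()) == [30, 30]


def test_min_cluster_size_larger_than_n_leaves_everything_unclustered():
    dist = _blob_distance([10, 10])
    tree = dendrogram(dist)
    a = dynamic_cut(tree, dist.isoform_ids, min_cluster_size=25)
    assert a.n_clusters == 0
    assert a.fraction_unclustered == 1.0


def test_no_cluster_below_min_size_and_deep_split_monotonicity():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(80, 4))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    d /= d.max()
    dist = DistanceMatrix(values=d, isoform_ids=[f"i{k}" for k in range(80)])
    tree = dendrogram(dist)
    counts = []
    for ds in range(5):
        a = dynamic_cut(tree, dist.isoform_ids, deep_split=ds, min_cluster_size=5)
        for label in a.cluster_labels():
            assert len(a.members(label)) >= 5
        counts.append(a.n_clusters)
    assert counts == sorted(counts)  # larger deepSplit never fewer clusters


def test_benchmark_parameters_recover_planted_blobs():
    dist = _blob_distance([15, 15, 15], seed=3)
    tree = dendrogram(dist)
    a = dynamic_cut(tree, dist.isoform_ids, deep_split=4, min_cluster_size=10)
    assert a.n_clusters == 3


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


def _assignment(labels, ids=None):
    labels = np.asarray(labels, int)
    ids = ids or [f"i{k}" for k in range(labels.size)]
    return ClusterAssignment(isoform_ids=ids, labels=labels)


def test_qc_filter_boundary_on_violation_count():
    # member 0 correlates poorly with exactly 2 of its 4 partners
    r = np.ones((5, 5))
    r[0, 1] = r[1, 0] = 0.5
    r[0, 2] = r[2, 0] = 0.5
    a = _assignment([1, 1, 1, 1, 1])
    kept = qc_filter(a, _corr(r), min_corr=0.85, max_violations=3)
    assert kept.labels[0] == 1  # 2 violations < 3: retained
    r[0, 3] = r[3, 0] = 0.5
    evicted = qc_filter(a, _corr(r), min_corr=0.85, max_violations=3)
    assert evicted.labels[0] == UNCLUSTERED
    assert list(evicted.labels[1:]) == [1, 1, 1, 1]


def test_qc_filter_is_single_pass_against_entry_composition():
    # 1--2 and 1--3 weak, 2--3 weak: all three accumulate 2 violations
    # against the entry composition with max_violations=2 and are evicted
    # together (no sequential re-evaluation)
    r = np.ones((4, 4))
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        r[i, j] = r[j, i] = 0.1
    a = _assignment([1, 1, 1, 1])
    out = qc_filter(a, _corr(r), min_corr=0.85, max_violations=2)
    assert list(out.labels) == [UNCLUSTERED] * 3 + [1]


def test_perfect_cluster_unchanged_by_either_qc_setting():
    r = np.ones((6, 6))
    a = _assignment([1] * 6)
    for kwargs in ({"min_corr": 0.85, "max_violations": 3},
                   {"min_corr": 0.7, "max_violations": 10}):
        out = qc_filter(a, _corr(r), **kwargs)
        assert list(out.labels) == [1] * 6


# ---------------------------------------------------------------------------
# metatranscripts / expansion / merging / recursive assignment
# ---------------------------------------------------------------------------


def test_metatranscript_is_mean_of_scaled_members():
    values = np.array(
        [
            [0.0, 1.0, 2.0],   # scales to [0, .5, 1]
            [10.0, 30.0, 50.0],  # scales to [0, .5, 1]
            [5.0, 5.0, 9.0],   # scales to [0, 0, 1]
        ]
    )
    prof = _profiles(values)
    a = _assignment([1, 1, 1])
    meta = metatranscripts(prof, a)[1]
    np.testing.assert_allclose(meta, [0.0, 1 / 3, 1.0])


def test_singleton_cluster_metatranscript_is_scaled_member():
    prof = _profiles([[2.0, 4.0, 6.0], [9.0, 9.0, 9.0]])
    a = _assignment([1, 2])
    metas = metatranscripts(prof, a)
    np.testing.assert_allclose(metas[1], [0.0, 0.5, 1.0])


def test_expand_assigns_above_threshold_and_ties_go_to_lowest_label():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    prof = _profiles(np.vstack([v, v, 2 * v + 1, v + 0.01 * np.arange(4)]))
    a = _assignment([1, 2, 2, 0])
    out = expand(a, prof, threshold=0.9)
    # candidate correlates ~1 with both cluster metatranscripts: label 1 wins
    assert out.labels[3] == 1
    assert out.step_log["i3"] == "expand"


def test_expand_leaves_low_correlation_isoforms_unclustered():
    prof = _profiles(
        [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 3.0, 0.0]]
    )
    a = _assignment([1, 1, 0])
    out = expand(a, prof, threshold=0.9)
    assert out.labels[2] == UNCLUSTERED


def test_merge_joins_near_identical_metatranscripts_only():
    metas = {
        1: np.array([0.0, 0.5, 1.0, 0.2]),
        2: np.array([0.01, 0.52, 0.99, 0.21]),  # r ~ 1 with cluster 1
        3: np.array([1.0, 0.1, 0.0, 0.9]),
    }
    mapping = merge(metas, cut_height=0.1)
    assert mapping[1] == mapping[2]
    assert mapping[3] != mapping[1]
    far = {1: metas[1], 3: metas[3]}
    assert merge(far, cut_height=0.1) == {1: 1, 3: 2}


def test_manual_merge_override():
    metas = {1: np.array([0.0, 1.0]), 2: np.array([1.0, 0.0]), 3: np.array([0.5, 1.0])}
    mapping = merge(metas, manual_merges=[{1, 2}])
    assert mapping[1] == mapping[2]
    assert mapping[3] not in (mapping[1],)


def test_recursive_assignment_waits_for_matching_threshold():
    rng = np.random.default_rng(8)
    v = np.linspace(0, 1, 12)
    cluster = np.vstack([v, v, v])
    # candidate engineered to correlate ~0.75 with the cluster profile
    ortho = rng.normal(size=12)
    ortho -= ortho.mean()
    ortho -= (ortho @ (v - v.mean())) / np.sum((v - v.mean()) ** 2) * (v - v.mean())
    vc = v - v.mean()
    target = 0.75
    cand = vc + np.sqrt(1 / target**2 - 1) * np.linalg.norm(vc) * ortho / np.linalg.norm(ortho)
    prof = _profiles(np.vstack([cluster, cand + 5.0]))
    a = _assignment([1, 1, 1, 0])
    out_high = expand(a, prof, threshold=0.9)
    assert out_high.labels[3] == UNCLUSTERED
    out = recursive_assign(a, prof, thresholds=(0.9, 0.8, 0.7))
    assert out.labels[3] == 1
    assert out.step_log["i3"] == "recursive@0.7"


def test_anticorrelated_isoform_is_still_force_assigned():
    v = np.linspace(0, 1, 8)
    prof = _profiles(np.vstack([v, v, -v]))
    a = _assignment([1, 1, 0])
    out = recursive_assign(a, prof)
    assert out.labels[2] == 1
    assert out.step_log["i2"] == "forced_assign"
    assert out.fraction_unclustered == 0.0


def test_recursive_assign_requires_clusters():
    prof = _profiles([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(ValueError, match="no clusters"):
        recursive_assign(_assignment([0, 0]), prof)


def test_apply_merge_relabels_members():
    a = _assignment([1, 2, 3, 0])
    out = apply_merge(a, {1: 1, 2: 1, 3: 2})
    assert list(out.labels) == [1, 1, 2, 0]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def test_pipeline_clusters_everything_and_is_deterministic(sim_small):
    from isocorde import length_normalize, percentile_summarize

    prof = percentile_summarize(length_normalize(sim_small.matrix), p=10)
    r1 = cluster_pipeline(prof, min_cluster_size=10)
    r2 = cluster_pipeline(prof, min_cluster_size=10)
    np.testing.assert_array_equal(r1.assignment.labels, r2.assignment.labels)
    assert r1.assignment.fraction_unclustered == 0.0
    stages = [entry["stage"] for entry in r1.provenance]
    assert stages[0] == "dynamic_cut" and stages[-1] == "final_merge"
    labels = r1.assignment.cluster_labels()
    assert labels == list(range(1, len(labels) + 1))  # compacted
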