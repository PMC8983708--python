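"""Semi-automated isoform clustering.

The pipeline turns a percentile-correlation matrix into co-expression
modules:

1. correlation -> distance: d = 1 - r for r > 0, else 1 (negative
   correlations are floored; only positive co-expression is clustered);
2. average-linkage hierarchical clustering;
3. a dynamic tree cut with per-branch adaptive splitting, a minimum cluster
   size, and (with the PAM stage disabled) leaves left unclustered;
4. refinement: a within-cluster correlation QC filter, metatranscript-based
   cluster expansion, profile-similarity merging, and a recursive assignment
   of the remaining unclustered isoforms with successively lower thresholds,
   ending in forced maximum-correlation assignment.

A *metatranscript* is a cluster's representative profile: the mean of the
members' percentile profiles after min-max scaling each member to [0, 1]
(so strongly expressed isoforms do not dominate). Correlations between an
isoform and a metatranscript are plain Pearson over the K*(p+1) vectors and
are unaffected by the isoform's own scale.

The dynamic cut implements the hybrid tree-cut contract with an explicit
per-branch relative-gap criterion: a branch is split into its two children
when both children hold at least ``min_cluster_size`` leaves and the relative
height gap (branch height minus taller child height, over branch height)
exceeds a threshold that decreases with ``deep_split`` (0..4). Larger
``deep_split`` therefore never yields fewer clusters on the same tree.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .correlation import CorrelationMatrix, PercentileProfile, _pearson_rows

UNCLUSTERED = 0

# relative-gap thresholds indexed by deep_split 0..4; monotone decreasing
_DEEP_SPLIT_GAP = (0.25, 0.15, 0.10, 0.05, 0.0)


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric distances in [0, 1] with zero diagonal."""

    values: np.ndarray
    isoform_ids: list[str]


def to_distance(corr: CorrelationMatrix) -> DistanceMatrix:
    """d = 1 - r when r > 0, else 1; diagonal forced to 0."""
    r = corr.values
    d = np.where(r > 0, 1.0 - r, 1.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, isoform_ids=list(corr.isoform_ids))


def dendrogram(dist: DistanceMatrix) -> np.ndarray:
    """Average-linkage tree (scipy linkage matrix) over the distance matrix."""
    condensed = ssd.squareform(dist.values, checks=False)
    return sch.linkage(condensed, method="average")


@dataclasses.dataclass
class ClusterAssignment:
    """isoform -> cluster label (0 = unclustered) with a refinement log."""

    isoform_ids: list[str]
    labels: np.ndarray  # int, 0 = unclustered
    step_log: dict[str, str] = dataclasses.field(default_factory=dict)

    def copy(self) -> "ClusterAssignment":
        return ClusterAssignment(
            isoform_ids=list(self.isoform_ids),
            labels=self.labels.copy(),
            step_log=dict(self.step_log),
        )

    def cluster_labels(self) -> list[int]:
        return sorted(int(l) for l in np.unique(self.labels) if l != UNCLUSTERED)

    def members(self, label: int) -> list[str]:
        return [self.isoform_ids[i] for i in np.flatnonzero(self.labels == label)]

    def member_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels())

    @property
    def unclustered_ids(self) -> list[str]:
        return self.members(UNCLUSTERED)

    @property
    def fraction_unclustered(self) -> float:
        return float(np.mean(self.labels == UNCLUSTERED))

    def label_of(self, isoform_id: str) -> int:
        return int(self.labels[self.isoform_ids.index(isoform_id)])

    def compact(self) -> "ClusterAssignment":
        """Relabel clusters 1..C in order of their current (sorted) labels."""
        out = self.copy()
        for new, old in enumerate(self.cluster_labels(), start=1):
            out.labels[self.labels == old] = new
        return out

    def record(self, ids: list[str] | np.ndarray, stage: str) -> None:
        for i in ids:
            self.step_log[str(i)] = stage


def _leaves_below(node: sch.ClusterNode) -> np.ndarray:
    return np.asarray(node.pre_order(lambda leaf: leaf.id), dtype=int)


def dynamic_cut(
    tree: np.ndarray,
    isoform_ids: list[str],
    deep_split: int = 4,
    min_cluster_size: int = 20,
    pam_stage: bool = False,
    cut_height: float | None = None,
) -> ClusterAssignment:
    """Adaptive per-branch cut of an average-linkage tree.

    The tree is first cut at ``cut_height`` (default 0.99 * max merge
    height); components smaller than ``min_cluster_size`` are left
    unclustered. Each remaining component is then recursively split at its
    top merge whenever both sub-branches hold >= ``min_cluster_size`` leaves
    and the relative height gap exceeds the ``deep_split`` threshold. Every
    emitted cluster has >= ``min_cluster_size`` members.
    """
    if pam_stage:
        raise NotImplementedError("the PAM reassignment stage is not supported")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    n = tree.shape[0] + 1
    if len(isoform_ids) != n:
        raise ValueError("isoform_ids must match the tree's leaf count")
    labels = np.zeros(n, dtype=int)
    if n < min_cluster_size:
        return ClusterAssignment(isoform_ids=list(isoform_ids), labels=labels)
    if cut_height is None:
        cut_height = 0.99 * float(tree[:, 2].max())
    gap_threshold = _DEEP_SPLIT_GAP[deep_split]

    root, nodes = sch.to_tree(tree, rd=True)

    # component roots: maximal nodes with merge height <= cut_height
    def component_roots(node: sch.ClusterNode) -> list[sch.ClusterNode]:
        if node.is_leaf() or node.dist <= cut_height:
            return [node]
        return component_roots(node.left) + component_roots(node.right)

    def split(node: sch.ClusterNode) -> list[sch.ClusterNode]:
        if node.is_leaf() or node.count < 2 * min_cluster_size:
            return [node]
        left, right = node.left, node.right
        if min(left.count, right.count) < min_cluster_size:
            return [node]
        child_h = max(left.dist, right.dist)
        gap = (node.dist - child_h) / node.dist if node.dist > 0 else 0.0
        if gap > gap_threshold:
            return split(left) + split(right)
        return [node]

    clusters: list[np.ndarray] = []
    for comp in component_roots(root):
        if comp.count < min_cluster_size:
            continue  # unassigned leaves (pamStage disabled)
        for sub in split(comp):
            clusters.append(_leaves_below(sub))
    # deterministic labels: order clusters by smallest leaf index
    clusters.sort(key=lambda idx: int(idx.min()))
    for label, idx in enumerate(clusters, start=1):
        labels[idx] = label
    out = ClusterAssignment(isoform_ids=list(isoform_ids), labels=labels)
    out.record(isoform_ids, "dynamic_cut")
    return out


def qc_filter(
    assignment: ClusterAssignment,
    corr: CorrelationMatrix,
    min_corr: float = 0.85,
    max_violations: int = 3,
) -> ClusterAssignment:
    """Move weakly connected members to the unclustered group.

    A member is removed iff it has >= ``max_violations`` within-cluster
    partners with correlation < ``min_corr``, evaluated in a single pass
    against the cluster composition at entry.
    """
    out = assignment.copy()
    r = corr.values
    for label in assignment.cluster_labels():
        idx = assignment.member_indices(label)
        if idx.size < 2:
            continue
        block = r[np.ix_(idx, idx)]
        violations = (block < min_corr).sum(axis=1) - (np.diag(block) < min_corr)
        evict = idx[violations >= max_violations]
        out.labels[evict] = UNCLUSTERED
        out.record([assignment.isoform_ids[i] for i in evict], "qc_filter")
    return out


def _minmax_scale_rows(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=1, keepdims=True)
    span = x.max(axis=1, keepdims=True) - lo
    span = np.where(span == 0, 1.0, span)
    return (x - lo) / span


def metatranscripts(
    profiles: PercentileProfile, assignment: ClusterAssignment
) -> dict[int, np.ndarray]:
    """Cluster representative profiles: mean of min-max-scaled member profiles."""
    if list(profiles.isoform_ids) != list(assignment.isoform_ids):
        raise ValueError("profiles and assignment must cover the same isoforms")
    metas: dict[int, np.ndarray] = {}
    for label in assignment.cluster_labels():
        idx = assignment.member_indices(label)
        if idx.size == 0:
            raise ValueError(f"cluster {label} is empty")
        metas[label] = _minmax_scale_rows(profiles.values[idx]).mean(axis=0)
    return metas


def _corr_to_meta(
    profiles: PercentileProfile, idx: np.ndarray, metas: dict[int, np.ndarray]
) -> tuple[np.ndarray, list[int]]:
    """Pearson correlation of each profile row in ``idx`` against each
    metatranscript; returns (len(idx) x n_clusters array, label order)."""
    labels = sorted(metas)
    stack = np.vstack([profiles.values[idx], np.array([metas[l] for l in labels])])
    r = _pearson_rows(stack)
    return r[: idx.size, idx.size :], labels


def expand(
    assignment: ClusterAssignment,
    profiles: PercentileProfile,
    metas: dict[int, np.ndarray] | None = None,
    threshold: float = 0.9,
) -> ClusterAssignment:
    """Assign unclustered isoforms to their best-correlated cluster.

    An isoform joins the maximally correlated cluster among those with
    r >= ``threshold``; ties resolve to the highest r then the lowest label.
    Metatranscripts are computed once at entry (single pass).
    """
    out = assignment.copy()
    idx = np.flatnonzero(assignment.labels == UNCLUSTERED)
    if idx.size == 0:
        return out
    if metas is None:
        metas = metatranscripts(profiles, assignment)
    if not metas:
        raise ValueError("no clusters to expand")
    r, labels = _corr_to_meta(profiles, idx, metas)
    best = np.argmax(r, axis=1)  # argmax takes the first (lowest label) on ties
    best_r = r[np.arange(idx.size), best]
    join = best_r >= threshold
    for i, j, ok in zip(idx, best, join):
        if ok:
            out.labels[i] = labels[j]
            out.step_log[assignment.isoform_ids[i]] = "expand"
    return out


def merge(
    metas: dict[int, np.ndarray],
    cut_height: float = 0.1,
    n_clusters: int | None = None,
    manual_merges: list[set[int]] | None = None,
) -> dict[int, int]:
    """Group clusters whose metatranscripts have near-identical profiles.

    Metatranscript percentile-correlation distances (d = 1 - r for r > 0,
    else 1) are hierarchically clustered (average linkage) and cut either at
    a constant ``cut_height`` or, if ``n_clusters`` is given, at the height
    producing exactly that many groups. ``manual_merges`` (sets of labels to
    force together) overrides the automatic grouping. Returns an
    old-label -> new-label map with new labels 1..C ordered by each group's
    lowest original label.
    """
    labels = sorted(metas)
    if manual_merges is not None:
        groups: list[set[int]] = [set(g) for g in manual_merges]
        grouped = set().union(*groups) if groups else set()
        groups += [{l} for l in labels if l not in grouped]
    elif len(labels) < 2:
        groups = [{l} for l in labels]
    else:
        stack = np.array([metas[l] for l in labels])
        r = _pearson_rows(stack)
        d = np.where(r > 0, 1.0 - r, 1.0)
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        link = sch.linkage(ssd.squareform(d, checks=False), method="average")
        if n_clusters is not None:
            flat = sch.fcluster(link, t=n_clusters, criterion="maxclust")
        else:
            flat = sch.fcluster(link, t=cut_height, criterion="distance")
        groups = [
            {labels[i] for i in np.flatnonzero(flat == g)} for g in np.unique(flat)
        ]
    groups.sort(key=min)
    mapping: dict[int, int] = {}
    for new, group in enumerate(groups, start=1):
        for old in group:
            mapping[old] = new
    return mapping


def apply_merge(
    assignment: ClusterAssignment, mapping: dict[int, int]
) -> ClusterAssignment:
    out = assignment.copy()
    for old, new in mapping.items():
        out.labels[assignment.labels == old] = new
    return out


def recursive_assign(
    assignment: ClusterAssignment,
    profiles: PercentileProfile,
    thresholds: tuple[float, ...] = (0.9, 0.8, 0.7),
    final: str = "max_correlation",
) -> ClusterAssignment:
    """Assign every remaining unclustered isoform.

    Per threshold: assign qualifying isoforms (r >= threshold to the best
    metatranscript), recompute metatranscripts, repeat until no change; then
    lower the threshold. Finally any stragglers are force-assigned to their
    maximally correlated cluster (the max may be < threshold or even < 0), so
    the unclustered set is empty on return.
    """
    if assignment.n_clusters == 0:
        raise ValueError("no clusters exist; cannot assign")
    out = assignment.copy()
    for thr in thresholds:
        while True:
            before = int((out.labels == UNCLUSTERED).sum())
            if before == 0:
                break
            nxt = expand(out, profiles, threshold=thr)
            changed = int((nxt.labels == UNCLUSTERED).sum()) < before
            for iso, stage in nxt.step_log.items():
                if stage == "expand" and out.step_log.get(iso) != "expand":
                    nxt.step_log[iso] = f"recursive@{thr}"
            out = nxt
            if not changed:
                break
    idx = np.flatnonzero(out.labels == UNCLUSTERED)
    if idx.size and final == "max_correlation":
        metas = metatranscripts(profiles, out)
        r, labels = _corr_to_meta(profiles, idx, metas)
        best = np.argmax(r, axis=1)
        for i, j in zip(idx, best):
            out.labels[i] = labels[j]
            out.step_log[out.isoform_ids[i]] = "forced_assign"
    return out


@dataclasses.dataclass
class PipelineResult:
    assignment: ClusterAssignment
    provenance: list[dict]


def cluster_pipeline(
    profiles: PercentileProfile,
    corr: CorrelationMatrix | None = None,
    deep_split: int = 4,
    min_cluster_size: int = 20,
    qc_min_corr: float = 0.85,
    qc_max_violations: int = 3,
    expand_threshold: float = 0.9,
    merge_height: float = 0.1,
    qc2_min_corr: float = 0.7,
    qc2_max_violations: int = 10,
    recursive_thresholds: tuple[float, ...] = (0.9, 0.8, 0.7),
    final_merge_height: float = 0.1,
) -> PipelineResult:
    """Full semi-automated clustering.

    Stages: dynamic cut -> QC filter -> expansion -> merge -> second (looser)
    QC filter -> recursive assignment -> final merge. Emits a provenance log
    with per-stage cluster/unclustered counts; deterministic for fixed
    inputs.
    """
    if corr is None:
        corr = CorrelationMatrix(
            values=_pearson_rows(profiles.values),
            isoform_ids=list(profiles.isoform_ids),
            metric="percentile",
        )
    log: list[dict] = []

    def note(stage: str, a: ClusterAssignment) -> None:
        log.append(
            {
                "stage": stage,
                "n_clusters": a.n_clusters,
                "n_unclustered": int((a.labels == UNCLUSTERED).sum()),
            }
        )

    tree = dendrogram(to_distance(corr))
    a = dynamic_cut(
        tree,
        list(profiles.isoform_ids),
        deep_split=deep_split,
        min_cluster_size=min_cluster_size,
    )
    note("dynamic_cut", a)
    a = qc_filter(a, corr, min_corr=qc_min_corr, max_violations=qc_max_violations)
    note("qc_filter", a)
    if a.n_clusters == 0:
        raise ValueError("no clusters survived the dynamic cut + QC filter")
    a = expand(a, profiles, threshold=expand_threshold)
    note("expand", a)
    a = apply_merge(a, merge(metatranscripts(profiles, a), cut_height=merge_height))
    note("merge", a)
    a = qc_filter(a, corr, min_corr=qc2_min_corr, max_violations=qc2_max_violations)
    note("qc_filter_2", a)
    if a.n_clusters == 0:
        raise ValueError("no clusters survived the second QC filter")
    a = recursive_assign(a, profiles, thresholds=recursive_thresholds)
    note("recursive_assign", a)
    a = apply_merge(
        a, merge(metatranscripts(profiles, a), cut_height=final_merge_height)
    )
    a = a.compact()
    note("final_merge", a)
    return PipelineResult(assignment=a, provenance=log)
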