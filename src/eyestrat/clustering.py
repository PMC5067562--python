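"""Subject stratification: Ward clustering plus a dynamic hybrid tree cut.

The stratification pipeline is: Hamming distances between subjects -> unsigned
topological overlap -> Ward agglomerative clustering of the TOM profiles ->
dynamic hybrid tree cut into subgroups -> subgroups rank-ordered by mean total
score, so that label 1 is always the lowest-performing subgroup in any cohort
(homologous labels across cohorts come from each cohort's own rank ordering,
never from transferring cluster labels).

Ward linkage is implemented via the Lance-Williams recurrence applied
*directly* to the supplied dissimilarity (the historical "ward.D" dialect of
the tools this pipeline descends from); the squared-dissimilarity dialect
("ward.D2", what :func:`scipy.cluster.hierarchy.linkage` computes) is exposed
as an option.

The tree cut finds a branch-specific cut height instead of one global height:
a branch is split into its two children only when each child is internally
tight (core scatter) and clearly separated from the join (merge-height gap),
with the stringency of both criteria controlled by ``deep_split``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .data_model import ItemResponseMatrix, ValidationError, total_scores
from .similarity import (
    SubjectDistanceMatrix,
    hamming_distance_matrix,
    rescale_distance,
    tom_dissimilarity,
    tom_profile_distance,
    topological_overlap_from_distance,
)


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history in the scipy linkage-matrix layout.

    ``merges`` has one row per merge: the two merged node indices (original
    observations are ``0..n-1``, the cluster created by merge ``t`` is
    ``n + t``), the merge height, and the merged cluster size.
    """

    merges: np.ndarray  # (n-1, 4)
    ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class SubgroupAssignment:
    """Rank-ordered subgroup labels: 1..K ascending in mean total score, 0 = unassigned."""

    subject_ids: tuple[str, ...]
    labels: np.ndarray
    n_subgroups: int
    subgroup_mean_scores: tuple[float, ...]
    provenance: dict = field(default_factory=dict)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


@dataclass(frozen=True)
class ItemSplit:
    """Partition of the item list into an easy and a difficult subset."""

    easy: tuple[str, ...]
    difficult: tuple[str, ...]


def ward_linkage(d: SubjectDistanceMatrix, variant: str = "direct") -> LinkageTree:
    """Ward agglomerative clustering of a dissimilarity matrix.

    ``variant="direct"`` applies the Lance-Williams Ward recurrence to the
    dissimilarities as given: after merging clusters i and j, the
    dissimilarity to any cluster k becomes::

        [(n_i + n_k) d(i,k) + (n_j + n_k) d(j,k) - n_k d(i,j)]
            / (n_i + n_j + n_k)

    and at every step the pair with minimal current dissimilarity is merged,
    ties broken by the lexicographically lowest index pair.
    ``variant="squared"`` delegates to scipy's Ward (the recurrence on
    squared dissimilarities).
    """
    n = d.n
    if n < 2:
        raise ValueError("ward_linkage requires at least 2 elements")
    if variant == "squared":
        merges = _scipy_linkage(squareform(d.values, checks=False), method="ward")
        return LinkageTree(merges=merges, ids=d.ids)
    if variant != "direct":
        raise ValueError(f"unknown Ward variant {variant!r}")

    dist = d.values.astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    size = np.ones(n)
    node_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        # row-major argmin = lowest (i, j) pair among ties
        flat = np.argmin(dist)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = dist[i, j]
        lo, hi = sorted((node_id[i], node_id[j]))
        merges[step] = (lo, hi, h, size[i] + size[j])
        # Lance-Williams update into slot i
        k = active.copy()
        k[i] = k[j] = False
        si, sj, sk = size[i], size[j], size[k]
        new = ((si + sk) * dist[i, k] + (sj + sk) * dist[j, k] - sk * h) / (
            si + sj + sk
        )
        dist[i, k] = new
        dist[k, i] = new
        dist[j, :] = np.inf
        dist[:, j] = np.inf
        active[j] = False
        size[i] += size[j]
        size[j] = 0
        node_id[i] = n + step
    return LinkageTree(merges=merges, ids=d.ids)


def _tree_members(tree: LinkageTree) -> list[np.ndarray]:
    """Member (leaf) index arrays for every node, leaves first."""
    n = tree.n_leaves
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    for a, b, _, _ in tree.merges:
        members.append(np.concatenate([members[int(a)], members[int(b)]]))
    return members


def deep_split_criteria(deep_split: int) -> tuple[float, float]:
    """Map ``deep_split`` (0-4) to (max core scatter, min gap).

    Both thresholds live on the dissimilarity scale after division by the
    largest observed dissimilarity. Stringency is monotone: higher
    ``deep_split`` tolerates more internal scatter in a branch and demands a
    smaller separation gap before splitting, producing more and finer
    clusters. The constants interpolate linearly from conservative (0) to
    aggressive (4) and are pinned by the planted-partition recovery test
    suite.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    max_core_scatter = 0.55 + 0.05 * deep_split
    min_gap = 0.09 - 0.02 * deep_split
    return max_core_scatter, min_gap


def dynamic_hybrid_cut(
    tree: LinkageTree,
    d: SubjectDistanceMatrix,
    min_cluster_size: int = 20,
    deep_split: int = 1,
    assign_outliers: bool = True,
) -> np.ndarray:
    """Cut a dendrogram at branch-specific heights into clusters.

    Returns labels in ``{0, 1, ..., K}`` (0 = unassigned outlier). Split
    decisions are made on the dissimilarity scale (normalized by the largest
    observed dissimilarity, so thresholds are scale-free): a node is split
    into its two child branches only when

    * the separation gap — the mean cross-branch dissimilarity minus the
      larger of the two branches' core scatters (their mean within-branch
      dissimilarities) — is at least the ``deep_split``-controlled minimum
      gap, and
    * each branch's core scatter is at most the maximum core scatter, i.e.
      a branch so internally diffuse that it cannot be a cluster core never
      forces a split on its own.

    A child smaller than ``min_cluster_size`` at an accepted split is pruned
    as outliers rather than forming a cluster. When the root admits no
    eligible split (e.g. all pairwise dissimilarities equal), all elements
    form one cluster. Pruned elements are afterwards assigned to the cluster
    with minimal mean dissimilarity, provided that mean does not exceed the
    cluster's admission radius (the largest mean-to-others dissimilarity of
    any current member).
    """
    if tuple(tree.ids) != tuple(d.ids):
        raise ValidationError("tree and distance matrix refer to different elements")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    max_core_scatter, min_gap = deep_split_criteria(deep_split)

    n = tree.n_leaves
    members = _tree_members(tree)
    children = {n + t: (int(a), int(b)) for t, (a, b, _, _) in enumerate(tree.merges)}
    off_max = d.values.max()
    dvals = d.values / off_max if off_max > 0 else d.values

    def scatter(node: int) -> float:
        m = members[node]
        if len(m) < 2:
            return 0.0
        sub = dvals[np.ix_(m, m)]
        return float(sub.sum() / (len(m) * (len(m) - 1)))

    clusters: list[np.ndarray] = []
    pruned: list[np.ndarray] = []

    def eligible_split(node: int) -> bool:
        if node < n or off_max <= 0:
            return False
        a, b = children[node]
        sc = max(scatter(a), scatter(b))
        if sc > max_core_scatter:
            return False
        cross = float(dvals[np.ix_(members[a], members[b])].mean())
        return cross - sc >= min_gap

    def visit(node: int) -> None:
        if not eligible_split(node):
            clusters.append(members[node])
            return
        a, b = children[node]
        big = [c for c in (a, b) if len(members[c]) >= min_cluster_size]
        small = [c for c in (a, b) if len(members[c]) < min_cluster_size]
        if not big:
            clusters.append(members[node])
            return
        for c in small:
            pruned.append(members[c])
        for c in big:
            visit(c)

    visit(2 * n - 2)

    labels = np.zeros(n, dtype=int)
    for idx, m in enumerate(clusters, start=1):
        labels[m] = idx

    if assign_outliers and pruned and clusters:
        radii = np.empty(len(clusters))
        for c, m in enumerate(clusters):
            sub = dvals[np.ix_(m, m)]
            radii[c] = (sub.sum(axis=1) / max(len(m) - 1, 1)).max()
        for m in pruned:
            for e in m:
                means = np.array([dvals[e, mm].mean() for mm in clusters])
                best = int(np.argmin(means))
                if means[best] <= radii[best]:
                    labels[e] = best + 1
    return labels


def rank_order_subgroups(
    labels: np.ndarray,
    scores: np.ndarray,
    subject_ids: Sequence[str] | None = None,
    provenance: dict | None = None,
) -> SubgroupAssignment:
    """Remap cluster labels so that label 1 has the lowest mean total score.

    Ties in mean score are broken by the smaller original cluster index.
    Unassigned elements (label 0) are preserved.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must be aligned")
    raw = sorted(set(labels[labels > 0]))
    if not raw:
        raise ValueError("no nonzero labels: empty assignment")
    means = {c: scores[labels == c].mean() for c in raw}
    order = sorted(raw, key=lambda c: (means[c], c))
    remap = {c: r + 1 for r, c in enumerate(order)}
    new_labels = np.array([remap.get(c, 0) for c in labels], dtype=int)
    if subject_ids is None:
        subject_ids = tuple(str(i) for i in range(len(labels)))
    return SubgroupAssignment(
        subject_ids=tuple(subject_ids),
        labels=new_labels,
        n_subgroups=len(order),
        subgroup_mean_scores=tuple(means[c] for c in order),
        provenance=dict(provenance or {}),
    )


def stratify_cohort(
    m: ItemResponseMatrix,
    min_cluster_size: int = 20,
    deep_split: int = 1,
    assign_outliers: bool = True,
    ward_variant: str = "direct",
    seed: int | None = None,
) -> SubgroupAssignment:
    """Full stratification of one cohort into rank-ordered subgroups.

    Composition: subject Hamming distances (max-rescaled so the least
    similar pair has zero adjacency) -> topological overlap -> Ward
    clustering of the TOM profiles (Euclidean distance between TOM rows,
    i.e. the square TOM matrix handed to the linkage as row observations) ->
    dynamic hybrid cut, with branch eligibility and outlier admission judged
    on the raw Hamming dissimilarity -> rank ordering by mean total score.
    The pipeline is deterministic; the seed is recorded in provenance only.
    """
    d = hamming_distance_matrix(m, axis="subjects")
    tom = topological_overlap_from_distance(rescale_distance(d))
    tree = ward_linkage(tom_profile_distance(tom), variant=ward_variant)
    labels = dynamic_hybrid_cut(
        tree,
        d,
        min_cluster_size=min_cluster_size,
        deep_split=deep_split,
        assign_outliers=assign_outliers,
    )
    scores = total_scores(m)
    provenance = {
        "cohort": m.cohort[0] if m.cohort else None,
        "group": m.group[0] if m.group else None,
        "min_cluster_size": min_cluster_size,
        "deep_split": deep_split,
        "assign_outliers": assign_outliers,
        "ward_variant": ward_variant,
        "seed": seed,
    }
    return rank_order_subgroups(
        labels, scores, subject_ids=m.subject_ids, provenance=provenance
    )


def split_items_easy_difficult(m: ItemResponseMatrix) -> ItemSplit:
    """Split items into easy vs difficult via the item-axis clustering tree.

    The identical network pipeline is run along the item axis and the tree's
    top split taken; the side with the higher overall percent-correct is the
    easy set.
    """
    if m.n_items < 2:
        raise ValueError("need at least 2 items to split")
    d = hamming_distance_matrix(m, axis="items")
    tom = topological_overlap_from_distance(rescale_distance(d))
    tree = ward_linkage(tom_profile_distance(tom))
    members = _tree_members(tree)
    a, b = (int(x) for x in tree.merges[-1, :2])
    set_a = [m.item_ids[i] for i in members[a]]
    set_b = [m.item_ids[i] for i in members[b]]
    pc_a = m.matrix[:, members[a]].mean()
    pc_b = m.matrix[:, members[b]].mean()
    if pc_a >= pc_b:
        easy, difficult = set_a, set_b
    else:
        easy, difficult = set_b, set_a
    return ItemSplit(easy=tuple(easy), difficult=tuple(difficult))
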