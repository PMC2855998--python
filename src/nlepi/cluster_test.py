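"""Hierarchical clustering of samples and the label-permutation cluster test.

Samples are clustered agglomeratively on a chosen probe subset (by default
Euclidean distance on log2(intensity + 1), average linkage). The tree's final
merge defines a two-way partition; the "cluster result" for a focal group is
its count vector across the block holding the majority of an anchor group
versus the other block. The Monte-Carlo test permutes the sample labels and
asks how often a random labelling reproduces the observed cluster result —
the tree itself never changes under label permutation, so it is computed
exactly once.

The agglomeration is implemented directly (Lance-Williams updates) rather
than delegated, so that tie-breaking is part of the contract: among equal
minimum distances, the pair with the lexicographically smallest cluster ids
merges first, and on tie-free input the merge history coincides with the
standard implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .io_formats import ExpressionMatrix

Distance = Literal["euclidean", "correlation"]
Linkage = Literal["average", "complete"]
MatchMode = Literal["exact", "at-least"]


@dataclass
class LinkageTree:
    """Sample dendrogram: scipy-style merge history plus the leaf ids.

    Row i of ``merges`` is (id_a, id_b, height, size): leaves are numbered
    0..n-1 in ``sample_ids`` order and the cluster formed by row i gets id
    n + i.
    """

    merges: np.ndarray
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def leaves_of(self, cluster_id: int) -> list[int]:
        n = self.n_samples
        stack, leaves = [int(cluster_id)], []
        while stack:
            node = stack.pop()
            if node < n:
                leaves.append(node)
            else:
                row = self.merges[node - n]
                stack.extend((int(row[0]), int(row[1])))
        return sorted(leaves)


@dataclass
class PartitionTestResult:
    """Observed two-way cluster result and its permutation-null frequency."""

    tree: LinkageTree
    partition: tuple[frozenset, frozenset]
    observed_pattern: tuple[int, int]
    n_permutations: int
    n_matches: int
    seed: int
    mode: MatchMode

    @property
    def match_frequency(self) -> float:
        return self.n_matches / self.n_permutations


def _transform(values: np.ndarray) -> np.ndarray:
    return np.log2(values + 1.0)


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    probe_subset: Iterable[str],
    distance: Distance = "euclidean",
    linkage: Linkage = "average",
) -> LinkageTree:
    """Agglomerative clustering of samples on ``probe_subset``.

    Distances are computed between sample profiles of log2(intensity + 1).
    Deterministic: equal minimum distances are resolved in favour of the
    lowest-id cluster pair.
    """
    probes = list(probe_subset)
    if not probes:
        raise ValueError("probe_subset is empty")
    missing = set(probes) - set(matrix.probe_ids)
    if missing:
        raise KeyError(f"probes not in matrix: {sorted(missing)[:5]}")
    profiles = _transform(matrix.intensities.loc[probes].to_numpy()).T  # samples x probes
    n = profiles.shape[0]
    if n < 2:
        raise ValueError("need >=2 samples to cluster")
    dist = squareform(pdist(profiles, metric=distance))
    return _agglomerate(dist, list(matrix.sample_ids), linkage)


def _agglomerate(dist: np.ndarray, sample_ids: list[str], linkage: Linkage) -> LinkageTree:
    n = len(sample_ids)
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    index_of = {i: i for i in range(n)}  # cluster id -> row in d
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        ids = sorted(active)
        best = (np.inf, None)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dij = d[index_of[a], index_of[b]]
                if dij < best[0]:  # strict <: earlier (lower-id) pair wins ties
                    best = (dij, (a, b))
        height, (a, b) = best
        new_id = n + step
        size = active[a] + active[b]
        merges[step] = (a, b, height, size)
        ra, rb = index_of[a], index_of[b]
        for c in active:
            if c in (a, b):
                continue
            rc = index_of[c]
            if linkage == "average":
                d_new = (active[a] * d[rc, ra] + active[b] * d[rc, rb]) / size
            else:
                d_new = max(d[rc, ra], d[rc, rb])
            d[rc, ra] = d[ra, rc] = d_new
        d[rb, :] = d[:, rb] = np.inf
        del active[a], active[b], index_of[a], index_of[b]
        active[new_id] = size
        index_of[new_id] = ra
    return LinkageTree(merges=merges, sample_ids=sample_ids)


def cut_two(tree: LinkageTree) -> tuple[frozenset, frozenset]:
    """The two sample blocks obtained by removing the final merge."""
    if tree.n_samples < 2:
        raise ValueError("need >=2 samples to cut")
    last = tree.merges[-1]
    block_a = frozenset(tree.sample_ids[i] for i in tree.leaves_of(int(last[0])))
    block_b = frozenset(tree.sample_ids[i] for i in tree.leaves_of(int(last[1])))
    return block_a, block_b


def concordance_pattern(
    partition: tuple[frozenset, frozenset],
    labels: pd.Series,
    focal_group: str,
    anchor_group: str = "HN",
) -> tuple[int, int]:
    """Count focal-group samples (anchor-majority block, other block).

    The anchor block is the partition block holding the majority of the
    anchor group's samples; a tie goes to the block containing the anchor
    sample that appears first in ``labels``.
    """
    block_a, block_b = partition
    covered = block_a | block_b
    missing = set(labels.index) - covered
    if missing:
        raise ValueError(f"labels cover samples outside the partition: {sorted(missing)[:5]}")
    anchor = [s for s in labels.index if labels[s] == anchor_group]
    focal = [s for s in labels.index if labels[s] == focal_group]
    if not anchor:
        raise ValueError(f"anchor group {anchor_group!r} absent")
    if not focal:
        raise ValueError(f"focal group {focal_group!r} absent")
    in_a = sum(1 for s in anchor if s in block_a)
    in_b = len(anchor) - in_a
    if in_a > in_b:
        majority = block_a
    elif in_b > in_a:
        majority = block_b
    else:
        majority = block_a if anchor[0] in block_a else block_b
    n_in = sum(1 for s in focal if s in majority)
    return n_in, len(focal) - n_in


def permutation_cluster_test(
    matrix: ExpressionMatrix,
    probe_subset: Iterable[str],
    labels: pd.Series,
    focal_group: str,
    anchor_group: str = "HN",
    n_permutations: int = 10_000,
    seed: int = 0,
    mode: MatchMode = "exact",
    distance: Distance = "euclidean",
    linkage: Linkage = "average",
) -> PartitionTestResult:
    """Monte-Carlo label-permutation test of the observed cluster result.

    The tree and two-way partition are computed once (permuting labels does
    not alter sample distances). Each permutation shuffles the label vector
    uniformly and recomputes the concordance pattern; ``mode='exact'`` counts
    permutations whose pattern equals the observed one, ``'at-least'`` counts
    patterns at least as concordant in the observed direction.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if labels.nunique() < 2:
        raise ValueError("labels must contain at least two classes")
    tree = hierarchical_cluster(matrix, probe_subset, distance, linkage)
    partition = cut_two(tree)
    observed = concordance_pattern(partition, labels, focal_group, anchor_group)
    n_focal = sum(observed)
    majority_side = observed[0] >= n_focal / 2
    rng = np.random.default_rng(seed)
    values = labels.to_numpy()
    # array fast path equivalent to concordance_pattern (same tie-break:
    # labels order is positional order here)
    in_a = np.array([s in partition[0] for s in labels.index])
    n_matches = 0
    for _ in range(n_permutations):
        perm = rng.permutation(values)
        anchor_mask = perm == anchor_group
        focal_mask = perm == focal_group
        a_count = int(np.count_nonzero(anchor_mask & in_a))
        b_count = int(np.count_nonzero(anchor_mask)) - a_count
        if a_count > b_count:
            majority_a = True
        elif b_count > a_count:
            majority_a = False
        else:
            majority_a = bool(in_a[int(np.argmax(anchor_mask))])
        n_focal_in = int(np.count_nonzero(focal_mask & (in_a == majority_a)))
        pattern = (n_focal_in, int(np.count_nonzero(focal_mask)) - n_focal_in)
        if mode == "exact":
            n_matches += pattern == observed
        else:
            n_matches += (
                pattern[0] >= observed[0] if majority_side else pattern[0] <= observed[0]
            )
    return PartitionTestResult(
        tree=tree,
        partition=partition,
        observed_pattern=observed,
        n_permutations=n_permutations,
        n_matches=int(n_matches),
        seed=seed,
        mode=mode,
    )


def spearman_fold_correlation(
    folds_a: Sequence[float], folds_b: Sequence[float]
) -> float:
    """Spearman rank correlation of two fold-change vectors (ties mid-ranked)."""
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("fold changes must be positive")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(a, b).statistic)
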