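"""Group comparison: permutation tests, resampled group distances, UPGMA
clustering, and PC-score tests.

The permutation test statistic is the absolute difference of group means;
the p-value convention includes the observed statistic in the null set
(``(count >= observed + 1) / (n + 1)``), which guarantees p > 0 and makes
the smallest attainable p equal to 1/(n+1).  Singleton groups (individual
fossils) are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .procrustes import PCAResult


@dataclass(frozen=True)
class PermutationResult:
    group_a: str
    group_b: str
    observed_stat: float
    p_value: float
    n_permutations: int
    seed: int


def perm_test(values_a: Sequence[float], values_b: Sequence[float],
              n: int = 10_000, seed: int = 0,
              group_a: str = "a", group_b: str = "b",
              rng: np.random.Generator | None = None) -> PermutationResult:
    """Two-group permutation test on |mean_a - mean_b|.

    Deterministic given the seed; the permutation count is respected
    exactly.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 and b.size == 0:
        raise ValueError("both groups are empty")
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one value")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na, m = a.size, pooled.size
    perms = rng.permuted(np.broadcast_to(pooled, (n, m)).copy(), axis=1)
    stats = np.abs(perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1))
    p = (int((stats >= observed).sum()) + 1) / (n + 1)
    return PermutationResult(group_a, group_b, float(observed), p, n, seed)


def pairwise_perm_tests(groups: Mapping[str, Sequence[float]],
                        n: int = 10_000, seed: int = 0,
                        adjust: str = "none") -> pd.DataFrame:
    """Permutation tests for all unordered group pairs.

    ``adjust='BH'`` adds Benjamini-Hochberg adjusted p-values; raw
    p-values are always reported.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    labels = sorted(groups)
    pairs = list(combinations(labels, 2))
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (ga, gb), ss in zip(pairs, streams):
        res = perm_test(groups[ga], groups[gb], n=n, seed=seed,
                        group_a=ga, group_b=gb,
                        rng=np.random.default_rng(ss))
        rows.append({"group_a": ga, "group_b": gb,
                     "observed_stat": res.observed_stat,
                     "p_value": res.p_value,
                     "n_permutations": n})
    df = pd.DataFrame(rows)
    if adjust == "BH":
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def group_distance_matrix(groups: Mapping[str, Sequence[float]],
                          n: int = 1_000, seed: int = 0
                          ) -> tuple[np.ndarray, list[str]]:
    """Resampling-averaged distances between group means.

    ``D(g, h)`` is the mean over replicates of ``|mean_g* - mean_h*|``
    where each replicate resamples each group's values with replacement
    within the group.  Singleton (and constant) groups degenerate to the
    plain mean difference.  Symmetric with zero diagonal.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = sorted(groups)
    rng = np.random.default_rng(seed)
    rep_means = np.empty((n, len(labels)))
    for j, g in enumerate(labels):
        vals = np.asarray(groups[g], dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {g!r} is empty")
        if vals.size == 1:
            rep_means[:, j] = vals[0]
        else:
            draws = rng.choice(vals, size=(n, vals.size), replace=True)
            rep_means[:, j] = draws.mean(axis=1)
    D = np.abs(rep_means[:, :, None] - rep_means[:, None, :]).mean(axis=0)
    np.fill_diagonal(D, 0.0)
    return D, labels


# -------------------------------------------------------------------- UPGMA

@dataclass
class ClusterNode:
    """Node of an ultrametric dendrogram; leaves have height 0."""

    height: float
    label: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [lab for ch in self.children for lab in ch.leaves()]


@dataclass
class ClusterTree:
    """Rooted binary ultrametric tree over group labels."""

    root: ClusterNode
    labels: tuple[str, ...]

    def newick(self) -> str:
        def quote(label: str) -> str:
            # unquoted newick turns underscores into spaces
            if any(ch in label for ch in " _()[]:;,'\""):
                return "'" + label.replace("'", "''") + "'"
            return label

        def fmt(node: ClusterNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{quote(node.label)}:{bl:.10g}"
            inner = ",".join(fmt(ch, node.height) for ch in node.children)
            return f"({inner}):{bl:.10g}"
        inner = ",".join(fmt(ch, self.root.height)
                         for ch in self.root.children)
        return f"({inner});"

    def cophenetic(self) -> tuple[np.ndarray, list[str]]:
        """Pairwise cophenetic distances (2 x merge height) between leaves."""
        labels = sorted(self.labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        D = np.zeros((len(labels), len(labels)))

        def walk(node: ClusterNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            sides = [walk(ch) for ch in node.children]
            for i, li in enumerate(sides):
                for lj in sides[i + 1:]:
                    for a in li:
                        for b in lj:
                            D[idx[a], idx[b]] = D[idx[b], idx[a]] = \
                                2.0 * node.height
            return [lab for s in sides for lab in s]

        walk(self.root)
        return D, labels


def upgma(D: np.ndarray, labels: Sequence[str]) -> ClusterTree:
    """Average-linkage agglomeration of a distance matrix.

    Merge height is half the average inter-cluster distance; ties are
    broken by the lexicographically smallest pair of cluster name-sets
    (compared by their smallest member label).
    """
    D = np.asarray(D, dtype=float)
    m = len(labels)
    if D.shape != (m, m):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("diagonal must be zero")
    if m < 2:
        raise ValueError("need at least 2 labels")

    nodes: dict[str, ClusterNode] = {
        lab: ClusterNode(0.0, label=lab) for lab in labels}
    sizes = {lab: 1 for lab in labels}
    minlab = {lab: lab for lab in labels}
    dist = {frozenset((a, b)): float(D[i, j])
            for i, a in enumerate(labels)
            for j, b in enumerate(labels) if i < j}
    active = list(labels)
    counter = 0
    while len(active) > 1:
        best = min(
            ((dist[frozenset((a, b))], tuple(sorted((minlab[a], minlab[b]))),
              a, b)
             for i, a in enumerate(active) for b in active[i + 1:]),
        )
        d, _, a, b = best
        counter += 1
        new = f"__c{counter}"
        nodes[new] = ClusterNode(d / 2.0,
                                 children=(nodes[a], nodes[b]))
        sizes[new] = sizes[a] + sizes[b]
        minlab[new] = min(minlab[a], minlab[b])
        for c in active:
            if c in (a, b):
                continue
            da = dist.pop(frozenset((a, c)))
            db = dist.pop(frozenset((b, c)))
            dist[frozenset((new, c))] = \
                (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
        dist.pop(frozenset((a, b)))
        active = [c for c in active if c not in (a, b)] + [new]
    return ClusterTree(root=nodes[active[0]], labels=tuple(labels))


def pc_perm_tests(pca: PCAResult, groups: Mapping[str, Sequence[int]],
                  components: Sequence[int] = (1, 2),
                  n: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Pairwise permutation tests on PC scores, per component.

    ``groups`` maps group label -> row indices into the score matrix;
    ``components`` are 1-based.
    """
    frames = []
    for comp in components:
        if not 1 <= comp <= pca.scores.shape[1]:
            raise IndexError(f"component {comp} out of range")
        col = pca.scores[:, comp - 1]
        score_groups = {g: col[np.asarray(idx, dtype=int)]
                        for g, idx in groups.items()}
        df = pairwise_perm_tests(score_groups, n=n, seed=seed + comp)
        df.insert(0, "component", comp)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
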