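"""Maximum-information-spanning-tree (MIST) and pairwise MIE entropies.

Both approximations assemble a joint entropy from 1D marginal entropies
and pairwise mutual informations.  MIST keeps only a maximum-weight
spanning tree of the complete MI graph, which makes it an upper bound on
the true joint entropy (it discards, never double-counts, shared
information); truncated MIE subtracts every pair and can over-correct
when correlations form loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import MIMatrix

__all__ = ["MISTResult", "mist_pairwise", "mie_pairwise", "mist_partitioned"]

#: the six unordered subsystem-pair categories of a bound complex
CATEGORIES = (("A", "A"), ("B", "B"), ("Y", "Y"),
              ("A", "B"), ("A", "Y"), ("B", "Y"))


@dataclass
class MISTResult:
    """Pairwise-order MIST entropy and its spanning tree.

    ``entropy = s1d_sum - i2d_total`` with ``i2d_total`` the sum of tree
    edge MIs; ``tree_edges`` lists (i, j, mi) with i < j.
    """

    s1d_sum: float
    tree_edges: list[tuple[int, int, float]]
    i2d_total: float

    @property
    def entropy(self) -> float:
        return self.s1d_sum - self.i2d_total


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _as_matrix(mi) -> np.ndarray:
    m = mi.values if isinstance(mi, MIMatrix) else np.asarray(mi, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("MI must be a square matrix")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("MI matrix must be symmetric")
    return m


def mist_pairwise(s1d, mi) -> MISTResult:
    """Maximum-weight spanning tree entropy (Kruskal, deterministic ties).

    Edges are processed in order of decreasing MI with lexicographic
    (i, j) tie-break, so the tree — not only its weight — is reproducible.
    With fewer than 2 DOFs the edge set is empty and the entropy is just
    the marginal sum.
    """
    s1d = np.asarray([float(s) for s in np.atleast_1d(s1d)], dtype=float)
    d = s1d.size
    if d < 2:
        return MISTResult(float(s1d.sum()), [], 0.0)
    m = _as_matrix(mi)
    if m.shape[0] != d:
        raise ValueError(f"s1d has {d} entries but MI is {m.shape[0]}x{m.shape[0]}")
    iu, ju = np.triu_indices(d, k=1)
    order = np.lexsort((ju, iu, -m[iu, ju]))
    uf = _UnionFind(d)
    edges: list[tuple[int, int, float]] = []
    for e in order:
        i, j = int(iu[e]), int(ju[e])
        if uf.union(i, j):
            edges.append((i, j, float(m[i, j])))
            if len(edges) == d - 1:
                break
    i2d = float(sum(w for _, _, w in edges))
    return MISTResult(float(s1d.sum()), edges, i2d)


def mie_pairwise(s1d, mi) -> float:
    """Pairwise-truncated MIE entropy: sum of 1D marginals minus MI of
    *every* pair (units of R)."""
    s1d = np.asarray([float(s) for s in np.atleast_1d(s1d)], dtype=float)
    if s1d.size < 2:
        return float(s1d.sum())
    m = _as_matrix(mi)
    iu, ju = np.triu_indices(s1d.size, k=1)
    return float(s1d.sum() - m[iu, ju].sum())


def mist_partitioned(s1d, mi, subsystem_labels):
    """One global MIST with edge MIs attributed to subsystem categories.

    Returns ``(MISTResult, category_sums)`` where ``category_sums`` maps
    each unordered label pair in {A, B, Y} to the total MI of the tree
    edges joining those subsystems; the six sums add up to ``i2d_total``
    exactly (partition conservation).
    """
    labels = list(subsystem_labels)
    s1d = np.atleast_1d(s1d)
    if len(labels) != s1d.size:
        raise ValueError("one subsystem label per DOF required")
    bad = [l for l in labels if l not in ("A", "B", "Y")]
    if bad:
        raise ValueError(f"unlabeled or unknown subsystem labels: {sorted(set(bad))}")
    result = mist_pairwise(s1d, mi)
    sums = {c: 0.0 for c in CATEGORIES}
    for i, j, w in result.tree_edges:
        cat = tuple(sorted((labels[i], labels[j])))
        sums[cat] += w
    return result, sums
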