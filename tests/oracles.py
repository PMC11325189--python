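"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths they check: alignment scores come
from exhaustive enumeration of all global alignments, linkage trees from a
naive recompute-everything agglomerator, and ARI from direct pair counting.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Set, Tuple

from funfamkit.alignment import ScoringScheme
from funfamkit.distance_engine import DistanceHalfMatrix
from funfamkit.tree_build import MergeRecord


def brute_force_align_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Best global alignment score by exhaustive enumeration of all paths.

    Recursion over (i, j, last_move) without memoization enumerates every
    monotone alignment path once, charging gap_open on the first position
    of a gap run and gap_extend on continuations — feasible for the short
    strings the tests use.
    """
    go, ge = scheme.gap_open, scheme.gap_extend
    la, lb = len(a), len(b)

    def rec(i: int, j: int, last: str) -> float:
        if i == la and j == lb:
            return 0.0
        best = float("-inf")
        if i < la and j < lb:
            best = max(best, scheme.score(a[i], b[j]) + rec(i + 1, j + 1, "D"))
        if i < la:  # gap in b
            cost = ge if last == "U" else go
            best = max(best, -cost + rec(i + 1, j, "U"))
        if j < lb:  # gap in a
            cost = ge if last == "L" else go
            best = max(best, -cost + rec(i, j + 1, "L"))
        return best

    return rec(0, 0, "D")


def naive_agglomerate(matrix: DistanceHalfMatrix, linkage: str) -> List[MergeRecord]:
    """Closest-pair agglomeration recomputing every cluster distance from
    the original leaf distances at every step (no Lance-Williams updates)."""
    leaf_dist: Dict[Tuple[str, str], float] = {}
    n = matrix.n
    for k in range(matrix.condensed.size):
        i, j = DistanceHalfMatrix.unrank(k, n)
        a, b = matrix.ids[i], matrix.ids[j]
        key = (a, b) if a < b else (b, a)
        leaf_dist[key] = float(matrix.condensed[k])

    def d0(x: str, y: str) -> float:
        return leaf_dist[(x, y) if x < y else (y, x)]

    def cluster_distance(A: Set[str], B: Set[str]) -> float:
        values = [d0(x, y) for x in A for y in B]
        if linkage == "average":
            return sum(values) / len(values)
        if linkage == "single":
            return min(values)
        return max(values)

    clusters: Dict[str, Set[str]] = {leaf: {leaf} for leaf in matrix.ids}
    merges: List[MergeRecord] = []
    for step in range(1, n):
        best = None
        for a, b in combinations(sorted(clusters), 2):
            d = cluster_distance(clusters[a], clusters[b])
            cand = (d, a, b)
            if best is None or cand < best:
                best = cand
        d, left, right = best
        new_id = f"node_{step:04d}"
        merges.append(MergeRecord(step=step, left_id=left, right_id=right, new_id=new_id, height=d))
        clusters[new_id] = clusters.pop(left) | clusters.pop(right)
    return merges


def pair_counting_ari(labels_a: Dict[str, object], labels_b: Dict[str, object]) -> float:
    """Adjusted Rand index by direct enumeration of element pairs."""
    elements = sorted(labels_a)
    same_a = same_b = same_both = 0
    n_pairs = 0
    for x, y in combinations(elements, 2):
        n_pairs += 1
        sa = labels_a[x] == labels_a[y]
        sb = labels_b[x] == labels_b[y]
        same_a += sa
        same_b += sb
        same_both += sa and sb
    if n_pairs == 0:
        return 1.0
    expected = same_a * same_b / n_pairs
    maximum = (same_a + same_b) / 2.0
    if maximum == expected:
        return 1.0
    return (same_both - expected) / (maximum - expected)


def partition_of(funfams) -> Set[frozenset]:
    """FunFam list -> set of frozen member sets (id-agnostic comparison)."""
    return {frozenset(ff.member_ids) for ff in funfams}
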