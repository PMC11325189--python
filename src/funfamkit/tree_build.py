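"""Agglomerative construction of the relationship tree over starting clusters.

Starting from a condensed distance half-matrix over cluster
representatives, the closest pair of clusters is merged repeatedly until a
single root remains, yielding a full binary merge tree.  Inter-cluster
distances are maintained with the Lance-Williams update for the chosen
linkage; ties on the minimum distance are broken by the lexicographically
smallest (left id, right id) pair so the merge list is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .distance_engine import DistanceHalfMatrix

__all__ = [
    "LINKAGES",
    "MergeRecord",
    "RelationshipTree",
    "agglomerate",
    "to_newick",
    "write_merge_trace",
    "read_merge_trace",
]

LINKAGES = ("average", "single", "complete")


@dataclass(frozen=True)
class MergeRecord:
    step: int
    left_id: str
    right_id: str
    new_id: str
    height: float


@dataclass
class RelationshipTree:
    """Binary merge tree: n leaves (cluster ids) and n-1 merge records.

    ``node_members`` is populated by the tree-cutting stage's refill step
    and maps every node id to the full set of sequence ids below it.
    """

    leaves: List[str]
    merges: List[MergeRecord]
    root_id: str
    node_members: Optional[Dict[str, FrozenSet[str]]] = None

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(set(self.leaves)) != n:
            raise ValueError("leaf ids must be unique")
        if n >= 2 and len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        used_children: Set[str] = set()
        known: Set[str] = set(self.leaves)
        for rec in self.merges:
            for child in (rec.left_id, rec.right_id):
                if child not in known:
                    raise ValueError(f"merge step {rec.step}: unknown child {child!r}")
                if child in used_children:
                    raise ValueError(f"node {child!r} appears as a child twice")
                used_children.add(child)
            if rec.new_id in known:
                raise ValueError(f"merge step {rec.step}: node id {rec.new_id!r} reused")
            known.add(rec.new_id)
        if self.merges and self.merges[-1].new_id != self.root_id:
            raise ValueError("root_id must be the last merge's new node")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def children(self) -> Dict[str, Tuple[str, str]]:
        return {rec.new_id: (rec.left_id, rec.right_id) for rec in self.merges}

    def parents(self) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for rec in self.merges:
            out[rec.left_id] = rec.new_id
            out[rec.right_id] = rec.new_id
        return out

    def heights(self) -> Dict[str, float]:
        h = {leaf: 0.0 for leaf in self.leaves}
        for rec in self.merges:
            h[rec.new_id] = rec.height
        return h

    def subtree_leaves(self, node_id: str) -> List[str]:
        """Leaves below ``node_id``, in left-to-right tree order."""
        kids = self.children()
        out: List[str] = []
        stack = [node_id]
        while stack:
            node = stack.pop()
            if node in kids:
                left, right = kids[node]
                stack.append(right)
                stack.append(left)
            else:
                out.append(node)
        return out


def agglomerate(matrix: DistanceHalfMatrix, linkage: str = "average") -> RelationshipTree:
    """Build the relationship tree by iterative closest-pair merging.

    ``average`` uses the unweighted group-average (UPGMA-style) update
    d(A+B, C) = (|A| d(A,C) + |B| d(B,C)) / (|A| + |B|); ``single`` and
    ``complete`` use min and max.  New internal nodes are named
    ``node_0001``, ``node_0002``, ... in merge order.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    n = matrix.n
    if n < 2:
        raise ValueError("agglomerate requires at least 2 items")
    for leaf in matrix.ids:
        if leaf.startswith("node_"):
            raise ValueError(f"leaf id {leaf!r} collides with internal node naming")

    dist: Dict[Tuple[str, str], float] = {}
    for k in range(matrix.condensed.size):
        i, j = DistanceHalfMatrix.unrank(k, n)
        a, b = matrix.ids[i], matrix.ids[j]
        key = (a, b) if a < b else (b, a)
        dist[key] = float(matrix.condensed[k])
    sizes: Dict[str, int] = {leaf: 1 for leaf in matrix.ids}
    active: List[str] = sorted(matrix.ids)
    merges: List[MergeRecord] = []

    for step in range(1, n):
        best: Optional[Tuple[float, str, str]] = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                d = dist[(a, b)]
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, left, right = best  # type: ignore[misc]
        new_id = f"node_{step:04d}"
        merges.append(MergeRecord(step=step, left_id=left, right_id=right, new_id=new_id, height=d))
        sl, sr = sizes[left], sizes[right]
        for other in active:
            if other in (left, right):
                continue
            dl = dist.pop((left, other) if left < other else (other, left))
            dr = dist.pop((right, other) if right < other else (other, right))
            if linkage == "average":
                dn = (sl * dl + sr * dr) / (sl + sr)
            elif linkage == "single":
                dn = min(dl, dr)
            else:
                dn = max(dl, dr)
            dist[(new_id, other) if new_id < other else (other, new_id)] = dn
        dist.pop((left, right) if left < right else (right, left))
        active = sorted(set(active) - {left, right} | {new_id})
        sizes[new_id] = sl + sr

    return RelationshipTree(leaves=list(matrix.ids), merges=merges, root_id=merges[-1].new_id)


def to_newick(tree: RelationshipTree, heights: bool = True) -> str:
    """Serialize the tree as Newick, leaves labelled with cluster ids.

    With ``heights`` the branch length of a node is its parent's merge
    height minus its own (leaves sit at height 0), i.e. an ultrametric
    reading of the merge heights.
    """
    kids = tree.children()
    h = tree.heights()

    def render(node: str, parent_height: Optional[float]) -> str:
        if node in kids:
            left, right = kids[node]
            inner = f"({render(left, h[node])},{render(right, h[node])})"
            label = inner
        else:
            label = node
        if heights and parent_height is not None:
            return f"{label}:{max(parent_height - h[node], 0.0):.6g}"
        return label

    if tree.n_leaves == 1:
        return f"{tree.leaves[0]};"
    return render(tree.root_id, None) + ";"


def write_merge_trace(tree: RelationshipTree, path) -> None:
    """Write the merge list as TSV (step, left, right, new, height).

    A leading ``#leaves:`` line preserves the leaf order so the trace
    round-trips to an identical tree.
    """
    with Path(path).open("w") as fh:
        fh.write("#leaves:\t" + "\t".join(tree.leaves) + "\n")
        fh.write("step\tleft\tright\tnew\theight\n")
        for rec in tree.merges:
            fh.write(f"{rec.step}\t{rec.left_id}\t{rec.right_id}\t{rec.new_id}\t{rec.height!r}\n")


def read_merge_trace(path) -> RelationshipTree:
    with Path(path).open() as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#leaves:"):
            raise ValueError(f"{path}: expected a #leaves: header line")
        leaves = first.split("\t")[1:]
        header = fh.readline()
        if not header.startswith("step"):
            raise ValueError(f"{path}: expected a column header line")
        merges: List[MergeRecord] = []
        for line in fh:
            if not line.strip():
                continue
            step, left, right, new, height = line.rstrip("\n").split("\t")
            merges.append(
                MergeRecord(step=int(step), left_id=left, right_id=right, new_id=new, height=float(height))
            )
    if not merges:
        raise ValueError(f"{path}: merge trace contains no merges")
    return RelationshipTree(leaves=leaves, merges=merges, root_id=merges[-1].new_id)
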