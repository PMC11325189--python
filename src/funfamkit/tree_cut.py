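"""Refilling the relationship tree and cutting it into functional families.

After the tree is built over cluster representatives, each leaf is refilled
with its cluster's full member set and MSA, internal-node MSAs are formed
bottom-up by profile alignment, and the tree is evaluated post-order: a
merge is accepted only when both children are accepted, the two child
alignments show no more than ``d_max`` differentially conserved positions,
and (optionally) the merge height stays under a distance ceiling.  The
FunFams are the member sets of the maximal accepted subtrees — the largest
coherent subsets in which a putative function is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set

from .alignment import ScoringScheme, align_members, blosum62_scheme, profile_align
from .conservation import ConservationParams, _dcp_from_split
from .core_model import Alignment, DomainSequence, FunFam, StartingCluster
from .tree_build import RelationshipTree

__all__ = [
    "CutParams",
    "CutResult",
    "refill",
    "node_alignments",
    "cut",
    "write_cut_report",
]


@dataclass(frozen=True)
class CutParams:
    """Parameters of the tree-cutting stage.

    ``distance_ceiling`` (optional) rejects any merge above it outright —
    the distance-based gate layered on top of the DCP test.  The default is
    DCP-only.  ``min_funfam_size`` below which a family is folded into its
    nearest relative; the default 1 disables the floor.
    """

    conservation: ConservationParams = field(default_factory=ConservationParams)
    distance_ceiling: Optional[float] = None
    min_funfam_size: int = 1

    def __post_init__(self) -> None:
        if self.distance_ceiling is not None and self.distance_ceiling < 0:
            raise ValueError("distance_ceiling must be None or >= 0")
        if self.min_funfam_size < 1:
            raise ValueError("min_funfam_size must be >= 1")


@dataclass
class CutResult:
    funfams: List[FunFam]
    accepted_nodes: Set[str]
    rejected_nodes: Set[str]
    params_used: CutParams
    dcp_counts: Dict[str, int] = field(default_factory=dict)


def refill(tree: RelationshipTree, clusters: Sequence[StartingCluster]) -> RelationshipTree:
    """Attach full member sets to every node (leaf clusters, then unions).

    Tree leaves and cluster ids must correspond one-to-one.
    """
    by_id = {c.cluster_id: c for c in clusters}
    if len(by_id) != len(clusters):
        raise ValueError("duplicate cluster ids")
    missing = [leaf for leaf in tree.leaves if leaf not in by_id]
    if missing:
        raise ValueError(f"tree leaves without a matching cluster: {sorted(missing)[:5]}")
    extra = set(by_id) - set(tree.leaves)
    if extra:
        raise ValueError(f"clusters without a matching leaf: {sorted(extra)[:5]}")
    members: Dict[str, FrozenSet[str]] = {
        leaf: frozenset(by_id[leaf].member_ids) for leaf in tree.leaves
    }
    for rec in tree.merges:
        left, right = members[rec.left_id], members[rec.right_id]
        if left & right:
            raise ValueError(f"merge {rec.new_id}: children share members")
        members[rec.new_id] = left | right
    return RelationshipTree(
        leaves=list(tree.leaves),
        merges=list(tree.merges),
        root_id=tree.root_id,
        node_members=members,
    )


def node_alignments(
    tree: RelationshipTree,
    clusters: Sequence[StartingCluster],
    sequences: Mapping[str, DomainSequence],
    scheme: Optional[ScoringScheme] = None,
) -> Dict[str, Alignment]:
    """MSA for every node: leaf clusters aligned, internal nodes merged bottom-up.

    A leaf cluster that already carries an MSA (e.g. a pooled FunFam used
    as a starting cluster in a later iteration) keeps it; otherwise its
    members are progressively aligned.
    """
    scheme = scheme or blosum62_scheme()
    by_id = {c.cluster_id: c for c in clusters}
    alignments: Dict[str, Alignment] = {}
    for leaf in tree.leaves:
        cluster = by_id[leaf]
        alignments[leaf] = cluster.msa if cluster.msa is not None else align_members(
            cluster, sequences, scheme
        )
    for rec in tree.merges:
        alignments[rec.new_id] = profile_align(
            alignments[rec.left_id], alignments[rec.right_id], scheme
        )
    return alignments


def cut(
    tree: RelationshipTree,
    clusters: Sequence[StartingCluster],
    sequences: Mapping[str, DomainSequence],
    params: Optional[CutParams] = None,
    scheme: Optional[ScoringScheme] = None,
) -> CutResult:
    """Post-order acceptance cut of the refilled tree into FunFams.

    Leaves are always accepted.  An internal node is accepted iff both
    children are accepted, its children's alignments have at most ``d_max``
    DCPs between them, and its merge height does not exceed the ceiling
    (when one is set).  A function boundary anywhere below a node poisons
    the node, which is what makes the accepted subtrees maximal coherent
    subsets.
    """
    params = params or CutParams()
    scheme = scheme or blosum62_scheme()
    if tree.node_members is None:
        tree = refill(tree, clusters)
    alignments = node_alignments(tree, clusters, sequences, scheme)
    cons = params.conservation

    accepted: Dict[str, bool] = {leaf: True for leaf in tree.leaves}
    dcp_counts: Dict[str, int] = {}
    for rec in tree.merges:
        merged = alignments[rec.new_id]
        left_ids = list(alignments[rec.left_id].rows)
        right_ids = list(alignments[rec.right_id].rows)
        n_dcp = len(_dcp_from_split(merged.rows, left_ids, right_ids, cons))
        dcp_counts[rec.new_id] = n_dcp
        ok = accepted[rec.left_id] and accepted[rec.right_id]
        ok = ok and n_dcp <= cons.d_max
        if params.distance_ceiling is not None:
            ok = ok and rec.height <= params.distance_ceiling + 1e-12
        accepted[rec.new_id] = ok

    # maximal accepted subtrees: walk down from the root, emit at the first
    # accepted node on each path
    kids = tree.children()
    roots: List[str] = []
    stack = [tree.root_id] if tree.merges else [tree.leaves[0]]
    while stack:
        node = stack.pop()
        if accepted[node]:
            roots.append(node)
        else:
            left, right = kids[node]
            stack.append(right)
            stack.append(left)
    roots.sort(key=lambda n: min(tree.node_members[n]))  # type: ignore[index]

    funfams = [
        FunFam(
            funfam_id=f"FF{i + 1:05d}",
            member_ids=set(tree.node_members[node]),  # type: ignore[index]
            msa=alignments[node],
            metrics={"node_id": node, "size": len(tree.node_members[node])},  # type: ignore[index]
        )
        for i, node in enumerate(roots)
    ]

    if params.min_funfam_size > 1 and len(funfams) > 1:
        funfams = _enforce_size_floor(funfams, roots, tree, scheme, params.min_funfam_size)

    return CutResult(
        funfams=funfams,
        accepted_nodes={n for n, ok in accepted.items() if ok},
        rejected_nodes={n for n, ok in accepted.items() if not ok},
        params_used=params,
        dcp_counts=dcp_counts,
    )


def _enforce_size_floor(
    funfams: List[FunFam],
    roots: List[str],
    tree: RelationshipTree,
    scheme: ScoringScheme,
    floor: int,
) -> List[FunFam]:
    """Fold FunFams below the size floor into their nearest relative.

    Nearest = the FunFam first encountered inside the sibling subtree while
    walking up from the undersized family's node; deterministic via the
    tree's left-to-right leaf order.
    """
    parents = tree.parents()
    node_of = {ff.funfam_id: roots[i] for i, ff in enumerate(funfams)}
    current = {ff.funfam_id: ff for ff in funfams}
    leaf_to_ff: Dict[str, str] = {}
    for ff in funfams:
        for leaf in tree.subtree_leaves(node_of[ff.funfam_id]):
            leaf_to_ff[leaf] = ff.funfam_id

    while True:
        small = sorted(
            (ff for ff in current.values() if ff.size < floor),
            key=lambda f: (f.size, f.funfam_id),
        )
        if not small or len(current) == 1:
            break
        victim = small[0]
        node = node_of[victim.funfam_id]
        target_id: Optional[str] = None
        walker = node
        while walker in parents and target_id is None:
            parent = parents[walker]
            for leaf in tree.subtree_leaves(parent):
                candidate = leaf_to_ff[leaf]
                if candidate != victim.funfam_id:
                    target_id = candidate
                    break
            walker = parent
        if target_id is None:
            break
        target = current.pop(target_id)
        current.pop(victim.funfam_id)
        merged = FunFam(
            funfam_id=min(victim.funfam_id, target_id),
            member_ids=victim.member_ids | target.member_ids,
            msa=profile_align(victim.msa, target.msa, scheme),
            metrics={"size": victim.size + target.size},
        )
        current[merged.funfam_id] = merged
        node_of[merged.funfam_id] = node_of[target_id]
        for leaf, ffid in list(leaf_to_ff.items()):
            if ffid in (victim.funfam_id, target_id):
                leaf_to_ff[leaf] = merged.funfam_id
    return [current[k] for k in sorted(current)]


def write_cut_report(result: CutResult, tree: RelationshipTree, path) -> None:
    """Cut report TSV: node_id, dcp_count, height, accepted (internal nodes)."""
    heights = tree.heights()
    with Path(path).open("w") as fh:
        fh.write("node_id\tdcp_count\theight\taccepted\n")
        for rec in tree.merges:
            fh.write(
                f"{rec.new_id}\t{result.dcp_counts.get(rec.new_id, '')}\t"
                f"{heights[rec.new_id]:.6g}\t{int(rec.new_id in result.accepted_nodes)}\n"
            )
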