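"""Greedy incremental identity clustering (S90 generation) and GO filtering.

Sequences are clustered at a fractional identity threshold (default 0.90)
with greedy incremental semantics: process sequences longest-first and
attach each one to the first existing cluster whose *representative* it
matches, otherwise found a new cluster.  Clusters without at least one
member carrying an experimentally derived GO annotation are then discarded
before tree building.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .alignment import ScoringScheme, global_align, identity_scheme
from .core_model import GAP, AnnotationTable, DomainSequence, StartingCluster

__all__ = [
    "ClusteringParams",
    "pairwise_identity",
    "greedy_cluster",
    "filter_by_go",
    "write_membership",
    "read_membership",
]

#: The six classic experimental GO evidence codes.
EXPERIMENTAL_GO_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


@dataclass(frozen=True)
class ClusteringParams:
    identity_threshold: float = 0.90
    evidence_whitelist: FrozenSet[str] = EXPERIMENTAL_GO_CODES

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must lie in (0, 1]")
        if not self.evidence_whitelist:
            raise ValueError("evidence whitelist must be non-empty")
        object.__setattr__(self, "evidence_whitelist", frozenset(self.evidence_whitelist))


def pairwise_identity(a: DomainSequence, b: DomainSequence, scheme: Optional[ScoringScheme] = None) -> float:
    """Fraction of identical aligned residue pairs over the shorter length.

    The numerator counts columns of the optimal global alignment where both
    symbols are equal non-gap residues; X never counts as a match.  The
    shorter-sequence denominator follows greedy clustering tool convention.
    The pair is canonically ordered before aligning, so the value is
    symmetric even when the optimum is degenerate.
    """
    if not a.residues or not b.residues:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if scheme is None:
        scheme = identity_scheme()
    shorter = min(len(a.residues), len(b.residues))
    if a.residues == b.residues:
        n_x = a.residues.count("X")
        return (len(a.residues) - n_x) / shorter
    ra, rb = a.residues, b.residues
    if (rb, b.seq_id) < (ra, a.seq_id):
        ra, rb = rb, ra
    ga, gb, _ = global_align(ra, rb, scheme)
    matches = sum(
        1 for x, y in zip(ga, gb) if x == y and x != GAP and x != "X"
    )
    return matches / shorter


def greedy_cluster(
    seqs: Sequence[DomainSequence],
    params: Optional[ClusteringParams] = None,
    scheme: Optional[ScoringScheme] = None,
) -> List[StartingCluster]:
    """Greedy incremental clustering at the identity threshold.

    Sequences are processed in length-descending order (ties by id), which
    canonicalizes the result against input-order permutations.  Each
    sequence joins the first cluster, in creation order, whose
    representative it matches at >= threshold identity; otherwise it founds
    a new cluster with itself as representative.  The cluster id is the
    representative's seq_id.
    """
    params = params or ClusteringParams()
    scheme = scheme or identity_scheme()
    ids = [s.seq_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate seq_ids in clustering input")
    order = sorted(seqs, key=lambda s: (-len(s.residues), s.seq_id))
    reps: List[DomainSequence] = []
    members: List[List[str]] = []
    for seq in order:
        for k, rep in enumerate(reps):
            if pairwise_identity(seq, rep, scheme) >= params.identity_threshold:
                members[k].append(seq.seq_id)
                break
        else:
            reps.append(seq)
            members.append([seq.seq_id])
    return [
        StartingCluster(
            cluster_id=rep.seq_id,
            representative_id=rep.seq_id,
            member_ids=set(mem),
        )
        for rep, mem in zip(reps, members)
    ]


def filter_by_go(
    clusters: Sequence[StartingCluster],
    annotations: AnnotationTable,
    params: Optional[ClusteringParams] = None,
) -> Tuple[List[StartingCluster], List[StartingCluster]]:
    """Split clusters into (kept, discarded) by experimental GO evidence.

    A cluster is kept iff at least one member has at least one GO term whose
    evidence code is in the whitelist.  Input order is preserved on both
    sides.
    """
    params = params or ClusteringParams()
    kept: List[StartingCluster] = []
    discarded: List[StartingCluster] = []
    for cluster in clusters:
        ok = any(
            evidence in params.evidence_whitelist
            for sid in cluster.member_ids
            for _, evidence in annotations.go.get(sid, ())
        )
        (kept if ok else discarded).append(cluster)
    return kept, discarded


def write_membership(clusters: Sequence[StartingCluster], path) -> None:
    """Write cluster membership TSV: cluster_id, is_representative (1/0), seq_id."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("cluster_id\tis_representative\tseq_id\n")
        for cluster in clusters:
            for sid in sorted(cluster.member_ids):
                flag = 1 if sid == cluster.representative_id else 0
                fh.write(f"{cluster.cluster_id}\t{flag}\t{sid}\n")


def read_membership(path) -> List[StartingCluster]:
    """Read a membership TSV (same dialect as :func:`write_membership`).

    This is the adapter hook for externally produced clusterings: any tool's
    membership can be converted to this three-column dialect and dropped in
    place of :func:`greedy_cluster`.
    """
    path = Path(path)
    members: Dict[str, List[str]] = {}
    reps: Dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("cluster_id"):
            raise ValueError(f"{path}: expected a membership header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            cid, flag, sid = parts
            members.setdefault(cid, []).append(sid)
            if flag == "1":
                if cid in reps:
                    raise ValueError(f"{path}: cluster {cid} has two representatives")
                reps[cid] = sid
    clusters = []
    for cid in members:
        if cid not in reps:
            raise ValueError(f"{path}: cluster {cid} has no representative")
        clusters.append(
            StartingCluster(cluster_id=cid, representative_id=reps[cid], member_ids=set(members[cid]))
        )
    return clusters
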