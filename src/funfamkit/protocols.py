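"""Orchestration of the three clustering protocols: single-pass, MARC, FRAN.

* ``single``: one pass of the distance-based pipeline — identity
  clustering, GO filtering, representative distance half-matrix,
  agglomerative tree, differential-conservation cut.
* ``marc`` (multi-domain architecture clustering): sequences are first
  partitioned by MDA string; each partition runs the single-pass stages
  independently, and the resulting FunFams are pooled as starting clusters
  (represented by their embedding-space medoid) for one final iteration.
* ``fran`` (random splitting): starting clusters are shuffled with a
  seeded PRNG and dealt into fixed-size projects; each project runs tree
  build + cut, and the pooled iteration-1 FunFams feed a second iteration
  that merges the outliers the randomization scattered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alignment import ScoringScheme, align_members, blosum62_scheme, identity_scheme
from .core_model import AnnotationTable, DomainSequence, FunFam, StartingCluster
from .distance_engine import (
    EmbeddingVector,
    build_half_matrix,
    cosine_distance,
    euclidean_distance,
    manhattan_distance,
)
from .identity_clustering import ClusteringParams, filter_by_go, greedy_cluster
from .tree_build import agglomerate
from .tree_cut import CutParams, cut

__all__ = [
    "ProtocolConfig",
    "RunResult",
    "run",
    "run_single",
    "run_marc",
    "run_fran",
    "partition_by_mda",
    "medoid",
    "result_fingerprint",
]

_SCALAR_METRICS = {
    "cosine": cosine_distance,
    "euclidean": euclidean_distance,
    "manhattan": manhattan_distance,
}


@dataclass
class ProtocolConfig:
    """Configuration shared by the three protocols.

    ``mda_min_size`` is the member count above which an MDA gets its own
    iteration-1 partition in MARC (a scale parameter: production systems
    set it in the millions, desk-scale runs use small values).
    ``fran_project_size`` is the number of starting clusters per FRAN
    project.  ``linkage`` picks the Lance-Williams update for tree
    building; ``centroid`` behavior is approximated by average linkage and
    the medoid representation of pooled families.
    """

    mode: str = "single"
    mda_min_size: int = 5
    fran_project_size: int = 10
    seed: int = 0
    metric: str = "cosine"
    linkage: str = "average"
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    cut: CutParams = field(default_factory=CutParams)
    identity_scheme: ScoringScheme = field(default_factory=identity_scheme)
    msa_scheme: ScoringScheme = field(default_factory=blosum62_scheme)

    def __post_init__(self) -> None:
        if self.mode not in ("single", "marc", "fran"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mda_min_size < 1:
            raise ValueError("mda_min_size must be >= 1")
        if self.fran_project_size < 1:
            raise ValueError("fran_project_size must be >= 1")
        if self.metric not in _SCALAR_METRICS:
            raise ValueError(f"unsupported vector metric {self.metric!r}")

    def provenance(self) -> Dict[str, object]:
        cons = self.cut.conservation
        return {
            "mode": self.mode,
            "metric": self.metric,
            "linkage": self.linkage,
            "seed": self.seed,
            "mda_min_size": self.mda_min_size,
            "fran_project_size": self.fran_project_size,
            "identity_threshold": self.clustering.identity_threshold,
            "evidence_whitelist": sorted(self.clustering.evidence_whitelist),
            "c_high": cons.c_high,
            "c_cons": cons.c_cons,
            "g_max": cons.g_max,
            "d_max": cons.d_max,
            "distance_ceiling": self.cut.distance_ceiling,
            "min_funfam_size": self.cut.min_funfam_size,
        }


@dataclass
class RunResult:
    """Outcome of one protocol run.

    ``funfams_final`` partitions every sequence that survived the GO
    filter; for the two-iteration protocols ``funfams_iter1`` holds the
    pre-pooling families.  ``partitions`` records which starting-cluster
    ids each iteration-1 partition (MDA set or FRAN project) processed.
    """

    funfams_iter1: List[FunFam]
    funfams_final: List[FunFam]
    partitions: Dict[str, List[str]]
    provenance: Dict[str, object]


def medoid(
    member_ids: Sequence[str],
    vectors: Mapping[str, EmbeddingVector],
    metric: str = "cosine",
) -> str:
    """The member minimizing summed distance to co-members in vector space.

    Only members with a vector are candidates (in production runs only
    cluster representatives are embedded).  Ties break lexicographically.
    """
    fn = _SCALAR_METRICS[metric]
    candidates = sorted(sid for sid in member_ids if sid in vectors)
    if not candidates:
        raise ValueError("medoid: no member has an embedding vector")
    if len(candidates) == 1:
        return candidates[0]
    best: Optional[Tuple[float, str]] = None
    for a in candidates:
        total = sum(fn(vectors[a].values, vectors[b].values) for b in candidates if b != a)
        if best is None or (total, a) < best:
            best = (total, a)
    return best[1]


def _stage(
    clusters: Sequence[StartingCluster],
    vectors: Mapping[str, EmbeddingVector],
    sequences: Mapping[str, DomainSequence],
    config: ProtocolConfig,
    label: str = "",
) -> List[FunFam]:
    """One tree-build + cut pass over a set of starting clusters."""
    clusters = sorted(clusters, key=lambda c: c.cluster_id)
    if not clusters:
        return []
    if len(clusters) == 1:
        c = clusters[0]
        msa = c.msa if c.msa is not None else align_members(c, sequences, config.msa_scheme)
        return [FunFam(funfam_id=f"{label}FF00001", member_ids=set(c.member_ids), msa=msa)]
    vecs = []
    for c in clusters:
        if c.representative_id not in vectors:
            raise ValueError(f"no embedding vector for representative {c.representative_id!r}")
        vecs.append(
            EmbeddingVector(seq_id=c.cluster_id, values=vectors[c.representative_id].values)
        )
    matrix = build_half_matrix(vecs, metric=config.metric)
    tree = agglomerate(matrix, linkage=config.linkage)
    result = cut(tree, clusters, sequences, config.cut, config.msa_scheme)
    if label:
        for ff in result.funfams:
            ff.funfam_id = f"{label}{ff.funfam_id}"
    return result.funfams


def _cluster_and_filter(
    seqs: Sequence[DomainSequence],
    annotations: AnnotationTable,
    config: ProtocolConfig,
) -> List[StartingCluster]:
    clusters = greedy_cluster(seqs, config.clustering, config.identity_scheme)
    kept, _ = filter_by_go(clusters, annotations, config.clustering)
    return kept


def _pool_funfams(
    funfams: Sequence[FunFam],
    vectors: Mapping[str, EmbeddingVector],
    metric: str,
) -> List[StartingCluster]:
    """Turn iteration-1 FunFams into starting clusters for the next iteration."""
    return [
        StartingCluster(
            cluster_id=ff.funfam_id,
            representative_id=medoid(sorted(ff.member_ids), vectors, metric),
            member_ids=set(ff.member_ids),
            msa=ff.msa,
        )
        for ff in sorted(funfams, key=lambda f: f.funfam_id)
    ]


def run_single(
    seqs: Sequence[DomainSequence],
    annotations: AnnotationTable,
    vectors: Mapping[str, EmbeddingVector],
    config: Optional[ProtocolConfig] = None,
) -> RunResult:
    """Single-pass protocol: cluster, filter, one tree build and cut."""
    config = config or ProtocolConfig(mode="single")
    sequences = {s.seq_id: s for s in seqs}
    kept = _cluster_and_filter(seqs, annotations, config)
    funfams = _stage(kept, vectors, sequences, config)
    return RunResult(
        funfams_iter1=funfams,
        funfams_final=funfams,
        partitions={"all": sorted(c.cluster_id for c in kept)},
        provenance=config.provenance(),
    )


def partition_by_mda(
    seqs: Sequence[DomainSequence],
    mda_min_size: int,
) -> Dict[str, List[DomainSequence]]:
    """Group sequences by MDA string; small groups pool into a residual set.

    Each MDA with at least ``mda_min_size`` sequences becomes its own
    partition labelled by the MDA string; everything else (including
    sequences without an MDA) forms the ``pooled`` partition.  An empty
    residual is omitted.
    """
    groups: Dict[str, List[DomainSequence]] = {}
    residual: List[DomainSequence] = []
    for seq in seqs:
        key = str(seq.mda) if seq.mda is not None else None
        if key is None:
            residual.append(seq)
        else:
            groups.setdefault(key, []).append(seq)
    partitions: Dict[str, List[DomainSequence]] = {}
    for key in sorted(groups):
        if len(groups[key]) >= mda_min_size:
            partitions[key] = groups[key]
        else:
            residual.extend(groups[key])
    if residual:
        partitions["pooled"] = residual
    return partitions


def run_marc(
    seqs: Sequence[DomainSequence],
    annotations: AnnotationTable,
    vectors: Mapping[str, EmbeddingVector],
    config: Optional[ProtocolConfig] = None,
) -> RunResult:
    """MDA prepartitioning, per-MDA pipelines, pooled final iteration.

    The GO filter applies in iteration 1 only; pooled FunFams inherit their
    eligibility.
    """
    config = config or ProtocolConfig(mode="marc")
    sequences = {s.seq_id: s for s in seqs}
    partitions = partition_by_mda(seqs, config.mda_min_size)
    iter1: List[FunFam] = []
    partition_record: Dict[str, List[str]] = {}
    for idx, label in enumerate(sorted(partitions)):
        kept = _cluster_and_filter(partitions[label], annotations, config)
        partition_record[label] = sorted(c.cluster_id for c in kept)
        iter1.extend(_stage(kept, vectors, sequences, config, label=f"mda{idx:02d}|"))
    pooled = _pool_funfams(iter1, vectors, config.metric)
    final = _stage(pooled, vectors, sequences, config)
    return RunResult(
        funfams_iter1=iter1,
        funfams_final=final,
        partitions=partition_record,
        provenance=config.provenance(),
    )


def run_fran(
    seqs: Sequence[DomainSequence],
    annotations: AnnotationTable,
    vectors: Mapping[str, EmbeddingVector],
    config: Optional[ProtocolConfig] = None,
) -> RunResult:
    """Random splitting into fixed-size projects, then a merging second pass.

    Starting clusters are shuffled with one seeded PRNG permutation and
    dealt into consecutive slices of ``fran_project_size``; the second
    iteration re-clusters the pooled FunFams and can only merge, so its
    family count never exceeds iteration 1's.
    """
    config = config or ProtocolConfig(mode="fran")
    sequences = {s.seq_id: s for s in seqs}
    kept = sorted(_cluster_and_filter(seqs, annotations, config), key=lambda c: c.cluster_id)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(kept))
    shuffled = [kept[i] for i in order]
    size = config.fran_project_size
    projects = [shuffled[i : i + size] for i in range(0, len(shuffled), size)]
    iter1: List[FunFam] = []
    partition_record: Dict[str, List[str]] = {}
    for idx, project in enumerate(projects):
        partition_record[f"project{idx:03d}"] = sorted(c.cluster_id for c in project)
        iter1.extend(_stage(project, vectors, sequences, config, label=f"p{idx:03d}|"))
    pooled = _pool_funfams(iter1, vectors, config.metric)
    final = _stage(pooled, vectors, sequences, config)
    return RunResult(
        funfams_iter1=iter1,
        funfams_final=final,
        partitions=partition_record,
        provenance=config.provenance(),
    )


def run(
    seqs: Sequence[DomainSequence],
    annotations: AnnotationTable,
    vectors: Mapping[str, EmbeddingVector],
    config: ProtocolConfig,
) -> RunResult:
    """Dispatch on ``config.mode``."""
    runner = {"single": run_single, "marc": run_marc, "fran": run_fran}[config.mode]
    return runner(seqs, annotations, vectors, config)


def result_fingerprint(result: RunResult) -> str:
    """Canonical text rendering of a run, for determinism checks and logs."""
    lines: List[str] = []
    for key in sorted(result.provenance):
        lines.append(f"# {key}={result.provenance[key]!r}")
    for label in sorted(result.partitions):
        lines.append(f"@ {label}: {','.join(result.partitions[label])}")
    for tag, funfams in (("iter1", result.funfams_iter1), ("final", result.funfams_final)):
        for ff in sorted(funfams, key=lambda f: f.funfam_id):
            members = ",".join(sorted(ff.member_ids))
            lines.append(f"{tag} {ff.funfam_id} {members}")
            for sid in sorted(ff.msa.rows):
                lines.append(f"  {sid} {ff.msa.rows[sid]}")
    return "\n".join(lines) + "\n"
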