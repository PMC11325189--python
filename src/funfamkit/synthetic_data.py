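"""Seeded generator of synthetic superfamilies with planted functional families.

The generator emulates the test substrate every pipeline stage needs: a
superfamily of K functional families descended from one root ancestor.
Families are separated in three controllable, independent ways:

* planted specificity (SDP) columns where each family conserves a
  distinct residue — the signal the tree-cutting stage must detect;
* background divergence of the family ancestors at non-SDP sites
  (``family_divergence``), which keeps cross-family sequence identity
  below the S90 threshold so identity clustering can separate families;
* planted embedding clusters: one Gaussian center per family with
  between-family spread ``between_sd`` and within-family noise
  ``within_sd``.

Each family carries a distinct EC4 (sharing the EC3 prefix, so EC4 and
EC3 purity behave differently), one experimental GO term, and an MDA
string.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .core_model import (
    AMINO_ACIDS,
    AnnotationTable,
    DomainSequence,
    parse_mda_string,
    write_annotations,
    write_fasta,
)
from .distance_engine import EmbeddingVector, write_embeddings

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_superfamily",
    "generate_embeddings",
    "write_dataset",
    "read_truth",
]

_DEFAULT_MDA = "3.40.50.620"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic superfamily."""

    n_families: int = 6
    seqs_per_family: int = 40
    seq_length: int = 80
    n_sdp: int = 3
    mutation_rate: float = 0.03
    family_divergence: float = 0.30
    embed_dim: int = 16
    within_sd: float = 1.0
    between_sd: float = 6.0
    mda_assignment: Optional[Mapping[int, str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.seqs_per_family < 1:
            raise ValueError("n_families and seqs_per_family must be >= 1")
        if self.n_families > 20:
            raise ValueError("at most 20 families (one distinct SDP residue each)")
        if not (0 <= self.n_sdp < self.seq_length):
            raise ValueError("need seq_length > n_sdp >= 0")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must lie in [0, 1)")
        if not (0.0 <= self.family_divergence < 1.0):
            raise ValueError("family_divergence must lie in [0, 1)")
        if self.within_sd <= 0 or self.between_sd <= 0:
            raise ValueError("within_sd and between_sd must be positive")
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")


@dataclass
class GroundTruth:
    """Planted structure of a generated superfamily."""

    family_of: Dict[str, int]
    sdp_columns: Dict[int, List[Tuple[int, str]]]
    ec_of_family: Dict[int, str]
    go_of_family: Dict[int, str]
    embedding_centers: Dict[int, np.ndarray] = field(default_factory=dict)


def _mutate(rng: np.random.Generator, residues: np.ndarray, rate: float, frozen: np.ndarray) -> np.ndarray:
    """Substitute each non-frozen site with probability ``rate``.

    Substitutions are uniform over the 19 alternative residues.
    """
    out = residues.copy()
    mask = (rng.random(residues.size) < rate) & ~frozen
    if mask.any():
        # offset in 1..19 guarantees a change
        offsets = rng.integers(1, 20, size=int(mask.sum()))
        out[mask] = (out[mask] + offsets) % 20
    return out


def generate_superfamily(
    config: SimConfig,
) -> Tuple[List[DomainSequence], AnnotationTable, GroundTruth]:
    """Generate sequences, annotations, and the planted ground truth.

    All families share one random root ancestor.  Family ancestors diverge
    from the root at non-SDP sites with per-site probability
    ``family_divergence`` and carry the family's planted residue at every
    SDP column; members then mutate non-SDP sites with probability
    ``mutation_rate``.  SDP residues are drawn without replacement per
    column, so any two families differ at every shared SDP column.
    """
    K, n, L = config.n_families, config.seqs_per_family, config.seq_length
    rng = np.random.default_rng([config.seed, 0])
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

    root = rng.integers(0, 20, size=L)
    sdp_cols = np.sort(rng.choice(L, size=config.n_sdp, replace=False)) if config.n_sdp else np.array([], dtype=int)
    frozen = np.zeros(L, dtype=bool)
    frozen[sdp_cols] = True
    # one distinct residue per family at each SDP column
    sdp_residues = np.stack(
        [rng.choice(20, size=K, replace=False) for _ in sdp_cols]
    ) if config.n_sdp else np.empty((0, K), dtype=int)

    seqs: List[DomainSequence] = []
    annotations = AnnotationTable()
    truth = GroundTruth(family_of={}, sdp_columns={}, ec_of_family={}, go_of_family={})
    mda_map = dict(config.mda_assignment or {})

    for f in range(K):
        ancestor = _mutate(rng, root, config.family_divergence, frozen)
        for c, col in enumerate(sdp_cols):
            ancestor[col] = sdp_residues[c, f]
        truth.sdp_columns[f] = [
            (int(col), AMINO_ACIDS[sdp_residues[c, f]]) for c, col in enumerate(sdp_cols)
        ]
        ec = f"1.1.1.{f + 1}"
        go = f"GO:{3824 + f:07d}"
        truth.ec_of_family[f] = ec
        truth.go_of_family[f] = go
        mda = parse_mda_string(mda_map.get(f, _DEFAULT_MDA))
        for m in range(n):
            member = _mutate(rng, ancestor, config.mutation_rate, frozen)
            sid = f"F{f}_s{m:03d}"
            seqs.append(
                DomainSequence(
                    seq_id=sid,
                    residues=aa[member].tobytes().decode(),
                    superfamily_id=_DEFAULT_MDA,
                    mda=mda,
                )
            )
            truth.family_of[sid] = f
            annotations.add_ec(sid, ec)
            annotations.add_go(sid, go, "IDA")
    return seqs, annotations, truth


def generate_embeddings(truth: GroundTruth, config: SimConfig) -> List[EmbeddingVector]:
    """Planted embedding clusters: one Gaussian center per family.

    Centers are drawn with spread ``between_sd``; member vectors add
    isotropic noise with spread ``within_sd``.  Fills
    ``truth.embedding_centers``.  Deterministic given the seed and
    independent of the sequence stream.
    """
    rng = np.random.default_rng([config.seed, 1])
    families = sorted({f for f in truth.family_of.values()})
    centers = {
        f: rng.normal(0.0, config.between_sd, size=config.embed_dim) for f in families
    }
    truth.embedding_centers = centers
    vectors: List[EmbeddingVector] = []
    for sid in sorted(truth.family_of):
        center = centers[truth.family_of[sid]]
        noise = rng.normal(0.0, config.within_sd, size=config.embed_dim)
        vectors.append(EmbeddingVector(seq_id=sid, values=center + noise))
    return vectors


def write_dataset(
    out_dir,
    seqs: List[DomainSequence],
    annotations: AnnotationTable,
    truth: GroundTruth,
    vectors: Optional[List[EmbeddingVector]] = None,
) -> Path:
    """Write the generated superfamily in the formats the pipeline reads.

    Layout: sequences.fasta, annotations.tsv, truth.tsv, mda.tsv and
    (optionally) embeddings.tsv under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(seqs, out_dir / "sequences.fasta")
    write_annotations(annotations, out_dir / "annotations.tsv")
    with (out_dir / "truth.tsv").open("w") as fh:
        fh.write("seq_id\tfamily\n")
        for sid in sorted(truth.family_of):
            fh.write(f"{sid}\t{truth.family_of[sid]}\n")
    with (out_dir / "mda.tsv").open("w") as fh:
        fh.write("seq_id\tmda\n")
        for seq in seqs:
            fh.write(f"{seq.seq_id}\t{seq.mda if seq.mda else ''}\n")
    if vectors is not None:
        write_embeddings(vectors, out_dir / "embeddings.tsv")
    return out_dir


def read_truth(path) -> Dict[str, int]:
    """Read a truth TSV (seq_id, family) back into a labeling."""
    out: Dict[str, int] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("seq_id"):
            raise ValueError(f"{path}: expected a seq_id/family header")
        for line in fh:
            if not line.strip():
                continue
            sid, fam = line.rstrip("\n").split("\t")
            out[sid] = int(fam)
    return out
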