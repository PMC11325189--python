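"""Domain types and file formats for protein functional-family clustering.

The pipeline subdivides a protein domain superfamily into functional
families (FunFams): clusters of homologous domains in which function is
conserved across members.  This module holds the shared vocabulary —
sequences, multi-domain architectures (MDAs), GO/EC annotation tables,
starting clusters (S90), alignments and FunFams — together with readers
and writers for the plain-text formats the pipeline touches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "SEQ_ALPHABET",
    "GAP",
    "GO_EVIDENCE_CODES",
    "FastaFormatError",
    "DomainSequence",
    "MDA",
    "AnnotationTable",
    "StartingCluster",
    "Alignment",
    "FunFam",
    "read_fasta",
    "write_fasta",
    "parse_mda_string",
    "read_annotations",
    "write_annotations",
    "write_funfam_set",
    "check_partition",
]

#: The 20 proteinogenic amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Sequence alphabet: 20 amino acids plus the ambiguity code X.
SEQ_ALPHABET = AMINO_ACIDS + "X"
#: Gap character used in alignments.
GAP = "-"

#: GO evidence-code vocabulary (experimental, phylogenetic, computational,
#: author/curator statement and electronic codes).
GO_EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
        "HTP", "HDA", "HMP", "HGI", "HEP",
        "IBA", "IBD", "IKR", "IRD",
        "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",
        "TAS", "NAS", "IC", "ND", "IEA",
    }
)

_CATH_ID_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
_SEQ_CHARS = frozenset(SEQ_ALPHABET)


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass
class MDA:
    """Multi-domain architecture: the ordered superfamily assignments of a chain."""

    domains: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.domains = tuple(self.domains)
        if not self.domains:
            raise ValueError("MDA must contain at least one domain")
        for d in self.domains:
            if not _CATH_ID_RE.match(d):
                raise ValueError(f"malformed CATH id in MDA: {d!r}")

    def __str__(self) -> str:
        return "-".join(self.domains)


def parse_mda_string(text: str) -> MDA:
    """Parse a hyphen-joined MDA string such as ``3.40.50.300-2.40.60.10-3.40.50.620``.

    En-dash and unicode hyphen separators (as typeset in journals) are
    normalized to the ASCII hyphen before splitting, so ``str(parse_mda_string(s))``
    round-trips to the canonical ASCII form.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty MDA string")
    normalized = text.strip().replace("–", "-").replace("‐", "-").replace("‒", "-")
    tokens = normalized.split("-")
    for tok in tokens:
        if not tok:
            raise ValueError(f"empty token in MDA string {text!r}")
        if not _CATH_ID_RE.match(tok):
            raise ValueError(f"malformed CATH id {tok!r} in MDA string {text!r}")
    return MDA(tuple(tokens))


@dataclass
class DomainSequence:
    """One protein domain sequence with identifiers and optional annotation links."""

    seq_id: str
    residues: str
    superfamily_id: Optional[str] = None
    mda: Optional[MDA] = None
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.seq_id}: residues must be non-empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - _SEQ_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.seq_id}: invalid residue character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AnnotationTable:
    """GO and EC annotations keyed by sequence id.

    GO terms are opaque strings paired with an evidence code; EC numbers are
    4-field dotted strings where ``-`` marks an unknown field.
    """

    go: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    ec: Dict[str, Set[str]] = field(default_factory=dict)

    def add_go(self, seq_id: str, term: str, evidence: str) -> None:
        if evidence not in GO_EVIDENCE_CODES:
            raise ValueError(f"unknown GO evidence code {evidence!r} for {seq_id}")
        self.go.setdefault(seq_id, set()).add((term, evidence))

    def add_ec(self, seq_id: str, ec: str) -> None:
        fields = ec.split(".")
        if len(fields) != 4 or any(not f for f in fields):
            raise ValueError(f"EC number {ec!r} for {seq_id} must have exactly 4 fields")
        self.ec.setdefault(seq_id, set()).add(ec)


@dataclass
class Alignment:
    """A multiple sequence alignment: seq_id -> gapped row.

    All rows share one length and no column is entirely gaps.
    """

    rows: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        n = lengths.pop()
        if n == 0:
            raise ValueError("alignment rows must be non-empty")
        for sid, row in self.rows.items():
            bad = set(row) - _SEQ_CHARS - {GAP}
            if bad:
                raise ValueError(f"row {sid}: invalid character(s) {sorted(bad)}")
        for j in range(n):
            if all(row[j] == GAP for row in self.rows.values()):
                raise ValueError(f"alignment column {j} is entirely gaps")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")


@dataclass
class StartingCluster:
    """A >=90%-identity sequence cluster; the leaf unit of tree building."""

    cluster_id: str
    representative_id: str
    member_ids: Set[str]
    msa: Optional[Alignment] = None

    def __post_init__(self) -> None:
        self.member_ids = set(self.member_ids)
        if not self.member_ids:
            raise ValueError(f"cluster {self.cluster_id}: member set must be non-empty")
        if self.representative_id not in self.member_ids:
            raise ValueError(
                f"cluster {self.cluster_id}: representative {self.representative_id} "
                "is not a member"
            )

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class FunFam:
    """A functional family: a maximal coherent subtree's member set plus its MSA."""

    funfam_id: str
    member_ids: Set[str]
    msa: Alignment
    metrics: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.member_ids = set(self.member_ids)
        if not self.member_ids:
            raise ValueError(f"FunFam {self.funfam_id}: member set must be non-empty")
        if set(self.msa.rows) != self.member_ids:
            raise ValueError(
                f"FunFam {self.funfam_id}: MSA rows do not match the member set"
            )

    @property
    def size(self) -> int:
        return len(self.member_ids)


# ---------------------------------------------------------------------------
# Readers / writers


def read_fasta(path) -> List[DomainSequence]:
    """Read a FASTA file into :class:`DomainSequence` records (order preserved).

    The first whitespace-delimited token of each header is the seq_id.
    Raises :class:`FastaFormatError` if sequence data precedes the first
    header or a seq_id occurs twice.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaFormatError(
                f"{path}: line {lineno}: sequence data before the first header"
            )
        break
    records: List[DomainSequence] = []
    seen: Set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {sid!r}")
        seen.add(sid)
        records.append(DomainSequence(seq_id=sid, residues=str(rec.seq)))
    return records


def write_fasta(records: Sequence[DomainSequence], path, width: int = 60) -> None:
    """Write records as FASTA; inverse of :func:`read_fasta`."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            res = rec.residues
            for i in range(0, len(res), width):
                fh.write(res[i : i + width] + "\n")


def write_aligned_fasta(alignment: Alignment, path, width: int = 60) -> None:
    """Write an alignment as gapped FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for sid in sorted(alignment.rows):
            fh.write(f">{sid}\n")
            row = alignment.rows[sid]
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def read_aligned_fasta(path) -> Alignment:
    """Read a gapped FASTA file back into an :class:`Alignment`."""
    rows: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper()
    return Alignment(rows)


def read_annotations(path) -> AnnotationTable:
    """Read a 4-column annotation TSV: seq_id, kind (GO|EC), value, evidence.

    The evidence column is empty (or absent) for EC rows.  Unknown seq_ids
    are retained; joining against sequence sets happens lazily downstream.
    """
    path = Path(path)
    table = AnnotationTable()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
            seq_id, kind, value = parts[0], parts[1], parts[2]
            evidence = parts[3] if len(parts) > 3 else ""
            try:
                if kind == "GO":
                    table.add_go(seq_id, value, evidence)
                elif kind == "EC":
                    table.add_ec(seq_id, value)
                else:
                    raise ValueError(f"unknown annotation kind {kind!r}")
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return table


def write_annotations(table: AnnotationTable, path) -> None:
    """Write an annotation table in the 4-column TSV dialect of :func:`read_annotations`."""
    path = Path(path)
    with path.open("w") as fh:
        for sid in sorted(table.go):
            for term, evidence in sorted(table.go[sid]):
                fh.write(f"{sid}\tGO\t{term}\t{evidence}\n")
        for sid in sorted(table.ec):
            for ec in sorted(table.ec[sid]):
                fh.write(f"{sid}\tEC\t{ec}\t\n")


def check_partition(funfams: Sequence[FunFam]) -> Set[str]:
    """Verify that FunFam member sets are pairwise disjoint; return their union."""
    seen: Set[str] = set()
    for ff in funfams:
        overlap = seen & ff.member_ids
        if overlap:
            raise ValueError(
                f"FunFams do not partition the input: {sorted(overlap)[:5]} appear twice"
            )
        seen |= ff.member_ids
    return seen


def write_funfam_set(
    funfams: Sequence[FunFam],
    out_dir,
    annotations: Optional[AnnotationTable] = None,
) -> Path:
    """Write one aligned FASTA per FunFam plus a summary table.

    Layout: ``<out>/funfams/<id>.aln.fasta`` and ``<out>/summary.tsv`` with
    columns id, size, ec4_purity, ec3_purity, dops.  Purity cells are left
    empty (undefined, not zero) when no member carries a usable EC number.
    """
    from .benchmark import ec_purity
    from .conservation import dops

    check_partition(funfams)
    out_dir = Path(out_dir)
    ff_dir = out_dir / "funfams"
    ff_dir.mkdir(parents=True, exist_ok=True)

    def fmt(value: Optional[float]) -> str:
        return "" if value is None else f"{value:.6g}"

    with (out_dir / "summary.tsv").open("w") as fh:
        fh.write("funfam_id\tsize\tec4_purity\tec3_purity\tdops\n")
        for ff in sorted(funfams, key=lambda f: f.funfam_id):
            write_aligned_fasta(ff.msa, ff_dir / f"{ff.funfam_id}.aln.fasta")
            p4 = ec_purity(ff, annotations, level=4) if annotations else None
            p3 = ec_purity(ff, annotations, level=3) if annotations else None
            fh.write(
                f"{ff.funfam_id}\t{ff.size}\t{fmt(p4)}\t{fmt(p3)}\t{dops(ff.msa):.6g}\n"
            )
    return out_dir / "summary.tsv"
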