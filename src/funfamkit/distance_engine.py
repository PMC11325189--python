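"""Source-agnostic condensed distance half-matrices over cluster representatives.

The tree-building stage is agnostic to where distances come from: embedding
vectors under a vector metric (cosine / Euclidean / Manhattan), or
precomputed pairwise structural scores (1/bitscore, RMSD).  Everything is
funnelled into one container, :class:`DistanceHalfMatrix`, holding the
condensed upper triangle in scipy's row-major convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_model import AMINO_ACIDS, DomainSequence

__all__ = [
    "METRICS",
    "EmbeddingVector",
    "DistanceHalfMatrix",
    "cosine_distance",
    "euclidean_distance",
    "manhattan_distance",
    "score_to_distance",
    "build_half_matrix",
    "kmer_embed",
    "read_embeddings",
    "write_embeddings",
    "read_pair_table",
]

#: Recognized distance sources.
METRICS = ("cosine", "euclidean", "manhattan", "inv_bitscore", "rmsd")

_VECTOR_METRICS = {"cosine": "cosine", "euclidean": "euclidean", "manhattan": "cityblock"}


@dataclass
class EmbeddingVector:
    """A fixed-length real vector attached to one sequence id."""

    seq_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError(f"embedding for {self.seq_id} must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"embedding for {self.seq_id} contains non-finite values")

    @property
    def dim(self) -> int:
        return int(self.values.size)


@dataclass
class DistanceHalfMatrix:
    """Condensed symmetric pairwise distances over an ordered id list.

    ``condensed`` holds the n(n-1)/2 upper-triangle entries in row-major
    order, the same layout scipy's ``pdist``/``squareform`` use.
    """

    ids: List[str]
    condensed: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("distance matrix ids must be unique")
        n = len(self.ids)
        self.condensed = np.asarray(self.condensed, dtype=float)
        expected = n * (n - 1) // 2
        if self.condensed.shape != (expected,):
            raise ValueError(
                f"condensed length {self.condensed.size} != n(n-1)/2 = {expected} for n={n}"
            )
        if not np.all(np.isfinite(self.condensed)):
            raise ValueError("distances must be finite")
        if (self.condensed < 0).any():
            raise ValueError("distances must be non-negative")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    @staticmethod
    def rank(i: int, j: int, n: int) -> int:
        """Condensed position of unordered pair (i, j), i != j, 0-based."""
        if i == j:
            raise ValueError("diagonal entries are not stored")
        if i > j:
            i, j = j, i
        return n * i - i * (i + 1) // 2 + (j - i - 1)

    @staticmethod
    def unrank(k: int, n: int) -> Tuple[int, int]:
        """Inverse of :meth:`rank`: the (i, j) pair stored at condensed position k."""
        i = int(n - 2 - np.floor(np.sqrt(-8 * k + 4 * n * (n - 1) - 7) / 2.0 - 0.5))
        j = int(k + i + 1 - n * i + i * (i + 1) // 2)
        return i, j

    def lookup(self, a: str, b: str) -> float:
        """Distance between two ids; zero on the diagonal by definition."""
        ia, ib = self._index[a], self._index[b]
        if ia == ib:
            return 0.0
        return float(self.condensed[self.rank(ia, ib, self.n)])

    def to_square(self) -> np.ndarray:
        return squareform(self.condensed)

    @classmethod
    def from_square(cls, ids: Sequence[str], square: np.ndarray) -> "DistanceHalfMatrix":
        square = np.asarray(square, dtype=float)
        if not np.allclose(square, square.T):
            raise ValueError("square distance matrix must be symmetric")
        return cls(ids=list(ids), condensed=squareform(square, checks=False))


# ---------------------------------------------------------------------------
# Scalar metrics


def _check_pair(u: np.ndarray, v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"vectors must share one dimension, got {u.shape} vs {v.shape}")
    return u, v


def cosine_distance(u, v) -> float:
    """1 - cos(u, v), in [0, 2].  Zero vectors are rejected."""
    u, v = _check_pair(u, v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance is undefined for zero vectors")
    if np.array_equal(u, v):
        return 0.0  # exact identity, no float round-off
    return max(0.0, float(1.0 - np.dot(u, v) / (nu * nv)))


def euclidean_distance(u, v) -> float:
    u, v = _check_pair(u, v)
    return float(np.linalg.norm(u - v))


def manhattan_distance(u, v) -> float:
    u, v = _check_pair(u, v)
    return float(np.abs(u - v).sum())


def build_half_matrix(
    vectors: Sequence[EmbeddingVector],
    metric: str = "cosine",
    ids: Optional[Sequence[str]] = None,
) -> DistanceHalfMatrix:
    """All-vs-all condensed distances over embedding vectors (input order kept).

    ``ids`` overrides the labels (e.g. to label entries by cluster id while
    the vectors belong to cluster representatives).
    """
    if len(vectors) < 2:
        raise ValueError("build_half_matrix requires at least 2 vectors")
    if metric not in _VECTOR_METRICS:
        if metric in METRICS:
            raise ValueError(
                f"metric {metric!r} applies to pairwise score tables; use score_to_distance"
            )
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    dims = {v.dim for v in vectors}
    if len(dims) != 1:
        raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
    data = np.stack([v.values for v in vectors])
    if metric == "cosine" and np.any(np.linalg.norm(data, axis=1) == 0.0):
        raise ValueError("cosine distance is undefined for zero vectors")
    condensed = pdist(data, metric=_VECTOR_METRICS[metric])
    condensed = np.maximum(condensed, 0.0)  # clip float noise on identical rows
    labels = list(ids) if ids is not None else [v.seq_id for v in vectors]
    if len(labels) != len(vectors):
        raise ValueError("ids must match the number of vectors")
    return DistanceHalfMatrix(ids=labels, condensed=condensed)


def score_to_distance(
    pairs: Iterable[Tuple[str, str, float]],
    kind: str,
    ids: Optional[Sequence[str]] = None,
    d_max_fill: Optional[float] = None,
) -> DistanceHalfMatrix:
    """Convert a pairwise score table into a distance half-matrix.

    ``inv_bitscore`` maps score s -> 1/s (s must be positive); ``rmsd``
    passes values through unchanged.  Directed pairs are symmetrized by the
    arithmetic mean of the two distances.  Pairs absent from the table get
    ``d_max_fill``, defaulting to 10x the largest observed distance, so
    sparse tables never silently produce zero distances.
    """
    if kind not in ("inv_bitscore", "rmsd"):
        raise ValueError(f"unknown score kind {kind!r}")
    acc: Dict[Tuple[str, str], List[float]] = {}
    seen: List[str] = []
    seen_set = set()
    for query, target, score in pairs:
        for sid in (query, target):
            if sid not in seen_set:
                seen_set.add(sid)
                seen.append(sid)
        if query == target:
            continue
        if kind == "inv_bitscore":
            if score <= 0:
                raise ValueError(f"bitscore must be positive, got {score} for ({query},{target})")
            d = 1.0 / score
        else:
            if score < 0:
                raise ValueError(f"RMSD must be non-negative, got {score} for ({query},{target})")
            d = float(score)
        key = (query, target) if query < target else (target, query)
        acc.setdefault(key, []).append(d)
    if ids is None:
        labels = sorted(seen)
    else:
        labels = list(ids)
        unknown = seen_set - set(labels)
        if unknown:
            raise ValueError(f"pair table references unknown id(s): {sorted(unknown)[:5]}")
    n = len(labels)
    if n < 2:
        raise ValueError("score_to_distance requires at least 2 ids")
    means = {key: sum(vals) / len(vals) for key, vals in acc.items()}
    if d_max_fill is None:
        if not means:
            raise ValueError("pair table contains no usable off-diagonal pairs")
        d_max_fill = 10.0 * max(means.values())
    condensed = np.empty(n * (n - 1) // 2, dtype=float)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            key = (a, b) if a < b else (b, a)
            condensed[k] = means.get(key, d_max_fill)
            k += 1
    return DistanceHalfMatrix(ids=labels, condensed=condensed)


def kmer_embed(seqs: Sequence[DomainSequence], k: int = 2) -> List[EmbeddingVector]:
    """Normalized k-mer frequency profiles: a toy stand-in embedding source.

    Dimension 20**k over the standard amino acids; k-mers containing X are
    skipped.  Identical sequences map to identical vectors, so this is a
    convenient deterministic vector source for tests and demos.
    """
    if not (1 <= k <= 3):
        raise ValueError("k must be in 1..3")
    index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    dim = 20 ** k
    out: List[EmbeddingVector] = []
    for seq in seqs:
        if len(seq.residues) < k:
            raise ValueError(f"sequence {seq.seq_id} is shorter than k={k}")
        counts = np.zeros(dim, dtype=float)
        for i in range(len(seq.residues) - k + 1):
            kmer = seq.residues[i : i + k]
            if "X" in kmer:
                continue
            code = 0
            for c in kmer:
                code = code * 20 + index[c]
            counts[code] += 1.0
        total = counts.sum()
        if total == 0:
            raise ValueError(f"sequence {seq.seq_id} has no X-free {k}-mers")
        out.append(EmbeddingVector(seq_id=seq.seq_id, values=counts / total))
    return out


# ---------------------------------------------------------------------------
# On-disk formats


def write_embeddings(vectors: Sequence[EmbeddingVector], path) -> None:
    """Write embeddings as TSV: id followed by the vector components."""
    with Path(path).open("w") as fh:
        for vec in vectors:
            vals = "\t".join(repr(float(x)) for x in vec.values)
            fh.write(f"{vec.seq_id}\t{vals}\n")


def read_embeddings(path) -> List[EmbeddingVector]:
    vectors: List[EmbeddingVector] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected id + floats")
            vectors.append(
                EmbeddingVector(seq_id=parts[0], values=np.array([float(x) for x in parts[1:]]))
            )
    dims = {v.dim for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"{path}: inconsistent embedding dimensions {sorted(dims)}")
    return vectors


def read_pair_table(path, kind: str = "inv_bitscore") -> List[Tuple[str, str, float]]:
    """Read a structural-aligner pairwise output: query, target, bitscore[, rmsd].

    Extra columns are ignored.  ``kind`` selects column 3 (bitscore) or
    column 4 (rmsd).
    """
    if kind not in ("inv_bitscore", "rmsd"):
        raise ValueError(f"unknown score kind {kind!r}")
    col = 2 if kind == "inv_bitscore" else 3
    rows: List[Tuple[str, str, float]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) <= col:
                raise ValueError(f"{path}: line {lineno}: expected >= {col + 1} columns")
            rows.append((parts[0], parts[1], float(parts[col])))
    return rows


def write_half_matrix(matrix: DistanceHalfMatrix, path) -> None:
    """Write a half-matrix: one header line of ids, then one value per line."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(matrix.ids) + "\n")
        for value in matrix.condensed:
            fh.write(repr(float(value)) + "\n")


def read_half_matrix(path) -> DistanceHalfMatrix:
    with Path(path).open() as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        values = [float(line) for line in fh if line.strip()]
    return DistanceHalfMatrix(ids=ids, condensed=np.asarray(values))
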