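"""Pairwise global alignment and profile-profile alignment.

Starting clusters are aligned into MSAs, and the tree-cutting stage compares
the MSAs of sibling nodes on a common coordinate system.  Both rest on the
two primitives here: a Needleman-Wunsch / Gotoh global aligner with a fixed,
reproducible traceback, and a profile-profile aligner that scores column
pairs by the mean pairwise substitution score of their residues.

Gap convention: a gap run of length L costs ``gap_open + (L-1) * gap_extend``.
With ``gap_open == gap_extend`` this reduces to a linear per-position cost,
which is the exact-arithmetic scheme used throughout the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .core_model import GAP, SEQ_ALPHABET, Alignment, DomainSequence, StartingCluster

__all__ = [
    "ScoringScheme",
    "identity_scheme",
    "blosum62_scheme",
    "global_align",
    "align_members",
    "profile_align",
]

_N_SYMBOLS = len(SEQ_ALPHABET)  # 21: twenty amino acids + X
_SYM_INDEX = {a: i for i, a in enumerate(SEQ_ALPHABET)}
_GAP_INDEX = _N_SYMBOLS  # gaps get the extra slot in count matrices

# byte-value -> symbol index lookup for fast row encoding
_CODE_LUT = np.full(256, -1, dtype=np.int16)
for _a, _i in _SYM_INDEX.items():
    _CODE_LUT[ord(_a)] = _i
_CODE_LUT[ord(GAP)] = _GAP_INDEX

_TOL = 1e-9


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap penalties.

    ``substitution`` is a symmetric (21, 21) array over the alphabet
    ACDEFGHIKLMNPQRSTVWYX.  ``gap_open``/``gap_extend`` are non-negative
    penalties (subtracted from the score); ``mode`` is ``"affine"`` or
    ``"linear"`` (linear implies open == extend).
    """

    substitution: np.ndarray
    gap_open: float
    gap_extend: float
    mode: str = "affine"

    def __post_init__(self) -> None:
        sub = np.asarray(self.substitution, dtype=float)
        if sub.shape != (_N_SYMBOLS, _N_SYMBOLS):
            raise ValueError(f"substitution matrix must be {_N_SYMBOLS}x{_N_SYMBOLS}")
        if not np.allclose(sub, sub.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "substitution", sub)
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.mode not in ("affine", "linear"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "linear" and self.gap_open != self.gap_extend:
            raise ValueError("linear mode requires gap_open == gap_extend")

    def score(self, a: str, b: str) -> float:
        return float(self.substitution[_SYM_INDEX[a], _SYM_INDEX[b]])


def identity_scheme(match: float = 1.0, mismatch: float = -1.0, gap: float = 1.0) -> ScoringScheme:
    """Flat identity scoring (match/mismatch/linear gap) for exact arithmetic.

    X never scores as a match, even against itself.
    """
    sub = np.full((_N_SYMBOLS, _N_SYMBOLS), mismatch, dtype=float)
    np.fill_diagonal(sub, match)
    x = _SYM_INDEX["X"]
    sub[x, :] = mismatch
    sub[:, x] = mismatch
    return ScoringScheme(substitution=sub, gap_open=gap, gap_extend=gap, mode="linear")


def blosum62_scheme(gap_open: float = 11.0, gap_extend: float = 1.0) -> ScoringScheme:
    """BLOSUM62 with affine gaps open 11 / extend 1 (community convention)."""
    blosum = substitution_matrices.load("BLOSUM62")
    sub = np.zeros((_N_SYMBOLS, _N_SYMBOLS), dtype=float)
    for i, a in enumerate(SEQ_ALPHABET):
        for j, b in enumerate(SEQ_ALPHABET):
            sub[i, j] = blosum[a, b]
    return ScoringScheme(substitution=sub, gap_open=gap_open, gap_extend=gap_extend, mode="affine")


def encode(row: str) -> np.ndarray:
    """Encode a (possibly gapped) row as symbol indices; gap -> 21."""
    codes = _CODE_LUT[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({c for c in row if _CODE_LUT[ord(c)] < 0})
        raise ValueError(f"invalid character(s) {bad} in alignment row")
    return codes


def column_counts(rows: Mapping[str, str]) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column symbol counts for a set of equal-length rows.

    Returns ``(residue_counts, gap_counts)`` with shapes (n_cols, 21) and
    (n_cols,).
    """
    n_cols = len(next(iter(rows.values())))
    counts = np.zeros((n_cols, _N_SYMBOLS + 1), dtype=float)
    cols = np.arange(n_cols)
    for row in rows.values():
        counts[cols, encode(row)] += 1.0
    return counts[:, :_N_SYMBOLS], counts[:, _GAP_INDEX]


# ---------------------------------------------------------------------------
# Gotoh dynamic programme on an arbitrary (m, n) score matrix

_NEG = float("-inf")


def _gotoh(S: np.ndarray, gap_open: float, gap_extend: float) -> Tuple[List[str], float]:
    """Optimal global alignment path over score matrix ``S``.

    Returns the traceback path as a list of moves ('D' diagonal, 'U' up =
    consume a row of S's first axis, 'L' left = consume a column) in
    left-to-right order, plus the optimal score.  Tie-break at every step:
    diagonal > up > left, and among gap-state predecessors match > up-gap >
    left-gap, which makes the traceback fully deterministic.
    """
    m, n = S.shape
    go, ge = float(gap_open), float(gap_extend)
    # M: last pair matched; X: gap run consuming rows (up); Y: gap run consuming cols (left)
    M = np.full((m + 1, n + 1), _NEG)
    X = np.full((m + 1, n + 1), _NEG)
    Y = np.full((m + 1, n + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, n + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    for i in range(1, m + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        Si = S[i - 1]
        for j in range(1, n + 1):
            jm = j - 1
            best_prev = Mp[jm]
            if Xp[jm] > best_prev:
                best_prev = Xp[jm]
            if Yp[jm] > best_prev:
                best_prev = Yp[jm]
            Mi[j] = Si[jm] + best_prev if best_prev != _NEG else _NEG
            x = Mp[j] - go
            if Xp[j] - ge > x:
                x = Xp[j] - ge
            if Yp[j] - go > x:
                x = Yp[j] - go
            Xi[j] = x
            y = Mi[jm] - go
            if Xi[jm] - go > y:
                y = Xi[jm] - go
            if Yi[jm] - ge > y:
                y = Yi[jm] - ge
            Yi[j] = y

    # terminal state: prefer M (diagonal) > X (up) > Y (left)
    i, j = m, n
    scores = (M[i, j], X[i, j], Y[i, j])
    best = max(scores)
    state = 0
    for k, s in enumerate(scores):
        if s >= best - _TOL:
            state = k
            break
    path: List[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M: diagonal move into (i, j)
            path.append("D")
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for k, s in enumerate((M[i, j], X[i, j], Y[i, j])):
                if abs(s - target) <= _TOL:
                    state = k
                    break
        elif state == 1:  # X: up move (gap in the second axis)
            path.append("U")
            val = X[i, j]
            i = i - 1
            if abs(M[i, j] - gap_open - val) <= _TOL:
                state = 0
            elif abs(X[i, j] - gap_extend - val) <= _TOL:
                state = 1
            else:
                state = 2
        else:  # Y: left move
            path.append("L")
            val = Y[i, j]
            j = j - 1
            if abs(M[i, j] - gap_open - val) <= _TOL:
                state = 0
            elif abs(X[i, j] - gap_open - val) <= _TOL:
                state = 1
            else:
                state = 2
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    path.reverse()
    return path, float(max(scores))


def global_align(a: str, b: str, scheme: ScoringScheme) -> Tuple[str, str, float]:
    """Optimal global alignment of two residue strings.

    Returns ``(gapped_a, gapped_b, score)``; ungapping either output string
    recovers its input.  Traceback ties resolve diagonal > up > left.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    ia, ib = encode(a), encode(b)
    if (ia == _GAP_INDEX).any() or (ib == _GAP_INDEX).any():
        raise ValueError("input sequences must not contain gap characters")
    S = scheme.substitution[np.ix_(ia, ib)]
    path, score = _gotoh(S, scheme.gap_open, scheme.gap_extend)
    ga: List[str] = []
    gb: List[str] = []
    i = j = 0
    for move in path:
        if move == "D":
            ga.append(a[i]); gb.append(b[j]); i += 1; j += 1
        elif move == "U":
            ga.append(a[i]); gb.append(GAP); i += 1
        else:
            ga.append(GAP); gb.append(b[j]); j += 1
    return "".join(ga), "".join(gb), score


def _profile_scores(A: Alignment, B: Alignment, scheme: ScoringScheme) -> np.ndarray:
    """Column-vs-column score matrix between two alignments.

    Entry (i, j) is the mean over all cross row pairs of: the substitution
    score for residue-residue pairs, ``-gap_extend`` for residue-gap pairs,
    and 0 for gap-gap pairs.
    """
    ra, ga = column_counts(A.rows)
    rb, gb = column_counts(B.rows)
    na, nb = A.n_rows, B.n_rows
    res_a = ra.sum(axis=1)
    res_b = rb.sum(axis=1)
    cross = ra @ scheme.substitution @ rb.T
    cross -= scheme.gap_extend * (np.outer(res_a, gb) + np.outer(ga, res_b))
    return cross / (na * nb)


def profile_align(A: Alignment, B: Alignment, scheme: ScoringScheme) -> Alignment:
    """Align two alignments column-wise; rows of each acquire the same gaps.

    Columns internal to A (or B) are never reordered.  The operand order is
    canonicalized on the smallest seq_id, so the result is symmetric in its
    arguments up to row order.
    """
    if set(A.rows) & set(B.rows):
        raise ValueError("profile_align requires disjoint seq_id sets")
    if min(B.rows) < min(A.rows):
        A, B = B, A
    S = _profile_scores(A, B, scheme)
    path, _ = _gotoh(S, scheme.gap_open, scheme.gap_extend)
    a_take: List[int] = []  # source column of A per merged column, -1 for gap
    b_take: List[int] = []
    i = j = 0
    for move in path:
        if move == "D":
            a_take.append(i); b_take.append(j); i += 1; j += 1
        elif move == "U":
            a_take.append(i); b_take.append(-1); i += 1
        else:
            a_take.append(-1); b_take.append(j); j += 1
    rows: Dict[str, str] = {}
    for sid, row in A.rows.items():
        rows[sid] = "".join(row[k] if k >= 0 else GAP for k in a_take)
    for sid, row in B.rows.items():
        rows[sid] = "".join(row[k] if k >= 0 else GAP for k in b_take)
    return Alignment(rows)


def align_members(
    cluster: StartingCluster,
    sequences: Mapping[str, DomainSequence],
    scheme: ScoringScheme,
) -> Alignment:
    """Progressive MSA of a starting cluster's members.

    Members are inserted in length-descending order (ties broken by id); the
    longest member seeds the profile and each next sequence is
    profile-aligned in.  Starting clusters are >=90% identical, so the
    guide order has negligible influence on the result.
    """
    missing = [sid for sid in cluster.member_ids if sid not in sequences]
    if missing:
        raise KeyError(
            f"cluster {cluster.cluster_id}: no sequence for member(s) {sorted(missing)[:5]}"
        )
    order = sorted(cluster.member_ids, key=lambda sid: (-len(sequences[sid].residues), sid))
    msa = Alignment({order[0]: sequences[order[0]].residues})
    for sid in order[1:]:
        msa = profile_align(msa, Alignment({sid: sequences[sid].residues}), scheme)
    return msa
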