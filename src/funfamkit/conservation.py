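"""Per-column conservation, alignment diversity (DOPS), and DCP detection.

Conservation of an alignment column is scored with an entropy proxy
bounded in [0, 1]: ``score = (1 - H/ln 20) * (1 - g)`` where H is the
Shannon entropy of the non-gap residue frequencies and g the gap fraction.
A fully invariant gap-free column scores 1; a column showing all twenty
residues equally scores 0.  DOPS (diversity of positions score) summarizes
a whole alignment on a 0-100 scale: 0 means no variable columns
(uninformative alignment), 100 means no conserved columns.

A differentially conserved position (DCP) between two alignments is a
column, on the merged coordinate system produced by profile alignment,
that is strongly conserved on *both* sides but around different modal
residues — the operational signature of a functional boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Union

import numpy as np

from .alignment import ScoringScheme, blosum62_scheme, column_counts, profile_align
from .core_model import SEQ_ALPHABET, Alignment

__all__ = [
    "ConservationParams",
    "ConservationProfile",
    "column_conservation",
    "dops",
    "differentially_conserved_positions",
    "write_profile_tsv",
]

_LN20 = math.log(20.0)


@dataclass(frozen=True)
class ConservationParams:
    """Thresholds steering conservation-based decisions.

    c_high: minimum column score for "conserved" in DCP detection.
    c_cons: column score cutoff used by DOPS.
    g_max:  maximum gap fraction for a column to be comparable (exclusive).
    d_max:  DCP count a merge may carry and still be accepted
            (``math.inf`` disables the test).
    """

    c_high: float = 0.8
    c_cons: float = 0.9
    g_max: float = 0.5
    d_max: Union[int, float] = 0

    def __post_init__(self) -> None:
        for name in ("c_high", "c_cons", "g_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.d_max < 0:
            raise ValueError("d_max must be non-negative")


@dataclass
class ConservationProfile:
    """Per-column conservation scores, gap fractions, and modal residues."""

    scores: np.ndarray
    gap_fractions: np.ndarray
    modal_residues: List[Optional[str]]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.gap_fractions = np.asarray(self.gap_fractions, dtype=float)
        if not (len(self.scores) == len(self.gap_fractions) == len(self.modal_residues)):
            raise ValueError("profile lists must share one length")

    @property
    def n_cols(self) -> int:
        return len(self.modal_residues)


def _profile_from_rows(rows: Mapping[str, str]) -> ConservationProfile:
    counts, gaps = column_counts(rows)
    n_rows = len(rows)
    n_cols = counts.shape[0]
    res_tot = counts.sum(axis=1)
    gap_frac = gaps / n_rows
    scores = np.zeros(n_cols)
    modal: List[Optional[str]] = []
    for j in range(n_cols):
        if res_tot[j] == 0:
            scores[j] = 0.0
            modal.append(None)
            continue
        p = counts[j] / res_tot[j]
        nz = p[p > 0]
        entropy = float(-(nz * np.log(nz)).sum())
        scores[j] = (1.0 - entropy / _LN20) * (1.0 - gap_frac[j])
        best = min(
            ((-counts[j, k], SEQ_ALPHABET[k]) for k in np.nonzero(counts[j])[0]),
        )
        modal.append(best[1])
    scores = np.clip(scores, 0.0, 1.0)
    return ConservationProfile(scores=scores, gap_fractions=gap_frac, modal_residues=modal)


def column_conservation(msa: Alignment) -> ConservationProfile:
    """Entropy-based conservation profile of an alignment.

    Modal residue is the most frequent non-gap symbol per column, ties
    broken alphabetically.
    """
    return _profile_from_rows(msa.rows)


def dops(msa: Alignment, params: Optional[ConservationParams] = None) -> float:
    """Diversity of positions score in [0, 100].

    ``100 * (1 - fraction of columns with conservation >= c_cons)``: an
    alignment of identical sequences scores 0 (no variability), and an
    alignment with no conserved column scores 100.
    """
    params = params or ConservationParams()
    profile = _profile_from_rows(msa.rows)
    conserved = int((profile.scores >= params.c_cons - 1e-12).sum())
    return 100.0 * (1.0 - conserved / profile.n_cols)


def _dcp_from_split(
    merged_rows: Mapping[str, str],
    left_ids: Sequence[str],
    right_ids: Sequence[str],
    params: ConservationParams,
) -> List[int]:
    """DCP columns given a merged alignment and the two row subsets."""
    prof_a = _profile_from_rows({sid: merged_rows[sid] for sid in left_ids})
    prof_b = _profile_from_rows({sid: merged_rows[sid] for sid in right_ids})
    out: List[int] = []
    for j in range(prof_a.n_cols):
        ma, mb = prof_a.modal_residues[j], prof_b.modal_residues[j]
        if ma is None or mb is None or ma == mb:
            continue
        if prof_a.scores[j] < params.c_high or prof_b.scores[j] < params.c_high:
            continue
        if prof_a.gap_fractions[j] >= params.g_max or prof_b.gap_fractions[j] >= params.g_max:
            continue
        out.append(j)
    return out


def differentially_conserved_positions(
    A: Alignment,
    B: Alignment,
    params: Optional[ConservationParams] = None,
    scheme: Optional[ScoringScheme] = None,
) -> List[int]:
    """Columns conserved in both alignments but around different residues.

    A and B are first placed on one coordinate system by profile alignment;
    indices refer to the merged alignment's columns (0-based, ascending).
    The result is symmetric in A and B.
    """
    if set(A.rows) & set(B.rows):
        raise ValueError("DCP detection requires disjoint seq_id sets")
    params = params or ConservationParams()
    scheme = scheme or blosum62_scheme()
    merged = profile_align(A, B, scheme)
    return _dcp_from_split(merged.rows, list(A.rows), list(B.rows), params)


def write_profile_tsv(profile: ConservationProfile, path) -> None:
    """Per-column inspection table: column, score, gap_fraction, modal_residue."""
    with Path(path).open("w") as fh:
        fh.write("column\tscore\tgap_fraction\tmodal_residue\n")
        for j in range(profile.n_cols):
            modal = profile.modal_residues[j] or ""
            fh.write(
                f"{j}\t{profile.scores[j]:.6g}\t{profile.gap_fractions[j]:.6g}\t{modal}\n"
            )
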