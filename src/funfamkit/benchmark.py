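"""Benchmarking machinery: EC purity, DOPS summaries, partition agreement.

EC purity asks how functionally homogeneous a FunFam is: among members
with usable EC annotations, the largest weight attributable to one EC
number (at 4-field or 3-field resolution) divided by the total weight.
Members annotated with several ECs are weighted fractionally so
promiscuous members cannot dominate; wildcard fields exclude an EC at the
level where the wildcard appears.  A FunFam with no usable EC is
*undefined*, never zero, and is excluded from averages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .conservation import ConservationParams, dops
from .core_model import AnnotationTable, FunFam

__all__ = [
    "PuritySummary",
    "DopsSummary",
    "ec_purity",
    "purity_summary",
    "adjusted_rand_index",
    "dops_summary",
    "write_benchmark_report",
]

_TOL = 1e-12


@dataclass
class PuritySummary:
    """Threshold proportions and mean purities over a FunFam set.

    Proportions use FunFams with defined EC4 purity as denominator;
    ``*_over_total`` variants divide by all FunFams instead (the two
    readings of "proportion over total").
    """

    prop_ge_80: Optional[float]
    prop_ge_90: Optional[float]
    prop_eq_100: Optional[float]
    mean_ec4: Optional[float]
    mean_ec3: Optional[float]
    n_defined: int
    n_undefined: int
    prop_ge_80_over_total: Optional[float]
    prop_ge_90_over_total: Optional[float]
    prop_eq_100_over_total: Optional[float]


@dataclass
class DopsSummary:
    table: pd.DataFrame  # columns: funfam_id, n_members, dops
    mean_dops: Optional[float]


def _valid_keys(ec: str, level: int) -> Optional[Tuple[str, ...]]:
    fields = tuple(ec.split("."))
    head = fields[:level]
    if "-" in head:
        return None
    return head


def ec_purity(
    funfam: FunFam,
    annotations: AnnotationTable,
    level: int = 4,
) -> Optional[float]:
    """Largest single-EC weight fraction at the given resolution, or None.

    Each member with at least one EC whose first ``level`` fields are all
    concrete contributes total weight 1, split evenly over its distinct
    truncated keys.  Undefined (None) when no member contributes.
    """
    if level not in (3, 4):
        raise ValueError("level must be 3 or 4")
    weights: Counter = Counter()
    total = 0.0
    for sid in sorted(funfam.member_ids):
        keys = {
            key
            for ec in annotations.ec.get(sid, ())
            if (key := _valid_keys(ec, level)) is not None
        }
        if not keys:
            continue
        w = 1.0 / len(keys)
        for key in keys:
            weights[key] += w
        total += 1.0
    if total == 0.0:
        return None
    return max(weights.values()) / total


def purity_summary(
    funfams: Sequence[FunFam],
    annotations: AnnotationTable,
) -> PuritySummary:
    """Figure-style purity summary: proportions over 80/90/100% and means.

    Thresholds are inclusive (>= 0.8, >= 0.9, == 1.0).
    """
    p4 = [p for ff in funfams if (p := ec_purity(ff, annotations, 4)) is not None]
    p3 = [p for ff in funfams if (p := ec_purity(ff, annotations, 3)) is not None]
    n_total = len(funfams)
    n_defined = len(p4)

    def props(denominator: int) -> Tuple[Optional[float], Optional[float], Optional[float]]:
        if denominator == 0:
            return None, None, None
        return (
            sum(1 for p in p4 if p >= 0.8 - _TOL) / denominator,
            sum(1 for p in p4 if p >= 0.9 - _TOL) / denominator,
            sum(1 for p in p4 if p >= 1.0 - _TOL) / denominator,
        )

    ge80, ge90, eq100 = props(n_defined)
    ge80_t, ge90_t, eq100_t = props(n_total)
    return PuritySummary(
        prop_ge_80=ge80,
        prop_ge_90=ge90,
        prop_eq_100=eq100,
        mean_ec4=sum(p4) / len(p4) if p4 else None,
        mean_ec3=sum(p3) / len(p3) if p3 else None,
        n_defined=n_defined,
        n_undefined=n_total - n_defined,
        prop_ge_80_over_total=ge80_t,
        prop_ge_90_over_total=ge90_t,
        prop_eq_100_over_total=eq100_t,
    )


def adjusted_rand_index(
    partition_a: Mapping[str, object],
    partition_b: Mapping[str, object],
) -> float:
    """Chance-corrected pair-counting agreement between two labelings.

    Both arguments map element -> cluster label over the same universe.
    """
    if set(partition_a) != set(partition_b):
        raise ValueError("partitions must label the same element universe")
    elements = sorted(partition_a)
    labels_a = [partition_a[e] for e in elements]
    labels_b = [partition_b[e] for e in elements]
    return float(adjusted_rand_score(labels_a, labels_b))


def funfams_to_labels(funfams: Sequence[FunFam]) -> Dict[str, str]:
    """Flatten a FunFam set into an element -> funfam_id labeling."""
    labels: Dict[str, str] = {}
    for ff in funfams:
        for sid in ff.member_ids:
            labels[sid] = ff.funfam_id
    return labels


def dops_summary(
    funfams: Sequence[FunFam],
    params: Optional[ConservationParams] = None,
) -> DopsSummary:
    """Per-FunFam DOPS table (id, n_members, dops) plus the mean."""
    rows = [
        {
            "funfam_id": ff.funfam_id,
            "n_members": ff.size,
            "dops": dops(ff.msa, params),
        }
        for ff in sorted(funfams, key=lambda f: f.funfam_id)
    ]
    table = pd.DataFrame(rows, columns=["funfam_id", "n_members", "dops"])
    mean = float(table["dops"].mean()) if len(table) else None
    return DopsSummary(table=table, mean_dops=mean)


def write_benchmark_report(
    funfams: Sequence[FunFam],
    annotations: AnnotationTable,
    out_prefix,
) -> Tuple[Path, Path]:
    """Write the per-FunFam report TSV and a key-value summary block."""
    out_prefix = Path(out_prefix)
    report_path = out_prefix.with_suffix(".tsv")
    summary_path = out_prefix.with_suffix(".summary.txt")
    dsum = dops_summary(funfams)
    with report_path.open("w") as fh:
        fh.write("funfam_id\tsize\tec4_purity\tec3_purity\tdops\n")
        dops_by_id = dict(zip(dsum.table["funfam_id"], dsum.table["dops"]))
        for ff in sorted(funfams, key=lambda f: f.funfam_id):
            p4 = ec_purity(ff, annotations, 4)
            p3 = ec_purity(ff, annotations, 3)
            fh.write(
                f"{ff.funfam_id}\t{ff.size}\t"
                f"{'' if p4 is None else f'{p4:.6g}'}\t"
                f"{'' if p3 is None else f'{p3:.6g}'}\t"
                f"{dops_by_id[ff.funfam_id]:.6g}\n"
            )
    psum = purity_summary(funfams, annotations)
    with summary_path.open("w") as fh:
        for name in (
            "prop_ge_80",
            "prop_ge_90",
            "prop_eq_100",
            "mean_ec4",
            "mean_ec3",
            "n_defined",
            "n_undefined",
            "prop_ge_80_over_total",
            "prop_ge_90_over_total",
            "prop_eq_100_over_total",
        ):
            fh.write(f"{name}\t{getattr(psum, name)}\n")
        fh.write(f"mean_dops\t{dsum.mean_dops}\n")
        fh.write(f"n_funfams\t{len(funfams)}\n")
    return report_path, summary_path
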