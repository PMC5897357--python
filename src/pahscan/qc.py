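"""Variant-level quality control via the overall pass rate (OPR).

Each variant of the aggregated multi-sample call set carries two quality
fractions: the pass frequency (proportion of samples carrying an alternate
allele whose call passed the original per-sample variant filters) and the
call rate (proportion of samples with a called genotype).  Their product is
the overall pass rate; variants with OPR >= 0.80 are retained for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QCMetrics", "compute_opr", "filter_by_opr", "annotate_opr"]

DEFAULT_OPR_THRESHOLD = 0.80


@dataclass(frozen=True)
class QCMetrics:
    pass_frequency: float
    call_rate: float
    opr: float


def compute_opr(pass_frequency: float, call_rate: float) -> QCMetrics:
    """OPR = pass frequency x call rate, unrounded.

    A variant with no alternate-allele carriers has no defined pass-frequency
    denominator; by convention such records carry pass_frequency 1.0
    (vacuously passing) and that convention is applied upstream.
    """
    for name, value in (("pass_frequency", pass_frequency), ("call_rate", call_rate)):
        if not np.isfinite(value) or not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return QCMetrics(pass_frequency, call_rate, pass_frequency * call_rate)


def filter_by_opr(variants: pd.DataFrame, threshold: float = DEFAULT_OPR_THRESHOLD):
    """Retain variants with OPR >= threshold (boundary retained).

    ``variants`` needs columns ``pass_frequency`` and ``call_rate``.  Returns
    ``(retained, decisions)``: the retained subset in input order and the
    full decision log with ``opr`` and ``qc_retained`` columns appended.
    Rows with missing QC fields raise, listing the offending variant keys.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold!r}")
    for col in ("pass_frequency", "call_rate"):
        if col not in variants.columns:
            raise ValueError(f"annotation table lacks required column {col!r}")
        bad = variants[col].isna()
        if bad.any():
            keys = _keys(variants.loc[bad])
            raise ValueError(f"missing {col} for variants: {keys}")
        vals = variants[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            keys = _keys(variants.loc[(vals < 0) | (vals > 1)])
            raise ValueError(f"{col} outside [0, 1] for variants: {keys}")
    decisions = variants.copy()
    decisions["opr"] = decisions["pass_frequency"] * decisions["call_rate"]
    decisions["qc_retained"] = decisions["opr"] >= threshold
    retained = decisions.loc[decisions["qc_retained"]].copy()
    return retained, decisions


def annotate_opr(path_in: str, path_out: str, threshold: float = DEFAULT_OPR_THRESHOLD) -> pd.DataFrame:
    """Read an annotation TSV, append opr / qc_retained columns, write back."""
    table = pd.read_csv(path_in, sep="\t")
    _, decisions = filter_by_opr(table, threshold=threshold)
    decisions.to_csv(path_out, sep="\t", index=False)
    return decisions


def _keys(rows: pd.DataFrame, limit: int = 5) -> str:
    cols = [c for c in ("chrom", "pos", "ref", "alt") if c in rows.columns]
    if not cols:
        return f"rows {list(rows.index[:limit])}"
    return "; ".join(
        ":".join(str(v) for v in rec) for rec in rows[cols].head(limit).itertuples(index=False)
    )
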