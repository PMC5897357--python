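"""The rare-deleterious filtering cascade and likely-causative curation.

Four rules, evaluated exhaustively (never short-circuited) so the decision
log supports a full audit:

1. rarity — MAF strictly below 1e-4 in the internal unrelated-control
   subset AND in every external reference set (threshold relaxed to
   1.25e-4 = 1/8000 on the X chromosome, applied uniformly to internal and
   external frequencies); an absent external record counts as frequency 0;
2. CADD — phred-scaled CADD >= 15 (variants lacking a score are routed to a
   pending list rather than silently failed);
3. consequence — protein-truncating or missense on the canonical transcript;
4. SIFT/PolyPhen — missense predicted BOTH "tolerated" (SIFT) and "benign"
   (PolyPhen) is removed; any other combination, including missing
   predictions, is kept; PTVs bypass the rule.

A variant is retained iff no rule failed and CADD is not pending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "FilterThresholds",
    "FilterDecision",
    "filter_rarity",
    "filter_cadd",
    "filter_consequence",
    "filter_sift_polyphen",
    "run_cascade",
    "curate_likely_causal",
]

PTV = "ptv"
MISSENSE = "missense"
CONSEQUENCES = {PTV, MISSENSE, "synonymous", "other"}


@dataclass(frozen=True)
class FilterThresholds:
    autosome_maf: float = 1e-4          # strict <
    x_maf: float = 1.25e-4              # 1/8000, strict <
    min_cadd: float = 15.0              # >= passes


@dataclass
class FilterDecision:
    key: tuple
    retained: bool
    pending: bool
    failed_rules: list = field(default_factory=list)


def _external_cols(variants: pd.DataFrame, external_maf_cols):
    if external_maf_cols is None:
        external_maf_cols = [c for c in variants.columns if c.startswith("maf_ext")]
    missing = [c for c in external_maf_cols if c not in variants.columns]
    if missing:
        raise ValueError(f"external MAF columns absent: {missing}")
    return list(external_maf_cols)


def filter_rarity(
    variants: pd.DataFrame,
    internal_col: str = "maf_unrelated_controls",
    external_maf_cols=None,
    thresholds: FilterThresholds = FilterThresholds(),
) -> np.ndarray:
    """True where the variant passes the rarity rule.

    Undefined internal MAF (all genotypes missing in the subset) does not by
    itself fail the rule; the variant fails only where a defined frequency
    exceeds its threshold.
    """
    ext = _external_cols(variants, external_maf_cols)
    thr = np.where(variants["is_x"].to_numpy(dtype=bool),
                   thresholds.x_maf, thresholds.autosome_maf)
    internal = variants[internal_col].to_numpy(dtype=float)
    ok = ~(internal >= thr)  # NaN-safe: NaN comparison is False -> passes
    for col in ext:
        freq = variants[col].fillna(0.0).to_numpy(dtype=float)
        ok &= freq < thr
    return ok


def filter_cadd(variants: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()):
    """Returns (passes, pending): CADD >= 15 passes; missing scores pend."""
    cadd = variants["cadd"].to_numpy(dtype=float)
    pending = np.isnan(cadd)
    passes = np.where(pending, False, cadd >= thresholds.min_cadd)
    return passes, pending


def filter_consequence(variants: pd.DataFrame) -> np.ndarray:
    """PTV or missense annotated on the canonical transcript."""
    cons = variants["consequence"].astype(str)
    unknown = set(cons.unique()) - CONSEQUENCES
    if unknown:
        raise ValueError(f"unknown consequence categories: {sorted(unknown)}")
    canonical = variants["canonical"].to_numpy(dtype=bool)
    return canonical & cons.isin([PTV, MISSENSE]).to_numpy()


def filter_sift_polyphen(variants: pd.DataFrame) -> np.ndarray:
    """Fails only missense with SIFT tolerated AND PolyPhen benign."""
    cons = variants["consequence"].astype(str)
    sift = variants["sift"].astype(str)
    poly = variants["polyphen"].astype(str)
    both_lowest = (sift == "tolerated") & (poly == "benign")
    return ~((cons == MISSENSE) & both_lowest).to_numpy()


def run_cascade(
    variants: pd.DataFrame,
    internal_col: str = "maf_unrelated_controls",
    external_maf_cols=None,
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Evaluate all four rules for every (QC-retained) variant.

    Returns a copy of the table with boolean ``pass_rarity`` /
    ``pass_cadd`` / ``pass_consequence`` / ``pass_sift_polyphen`` columns,
    ``cadd_pending``, the aggregated ``failed_rules`` string and the final
    ``retained`` flag.  Decisions depend only on row content, so the output
    is invariant to input order.
    """
    out = variants.copy()
    out["pass_rarity"] = filter_rarity(out, internal_col, external_maf_cols, thresholds)
    cadd_pass, pending = filter_cadd(out, thresholds)
    out["pass_cadd"] = cadd_pass
    out["cadd_pending"] = pending
    out["pass_consequence"] = filter_consequence(out)
    out["pass_sift_polyphen"] = filter_sift_polyphen(out)
    failed = []
    for rarity, cadd, pend, conseq, sp in zip(
        out["pass_rarity"], out["pass_cadd"], out["cadd_pending"],
        out["pass_consequence"], out["pass_sift_polyphen"],
    ):
        rules = []
        if not rarity:
            rules.append("rarity")
        if not cadd and not pend:
            rules.append("cadd")
        if not conseq:
            rules.append("consequence")
        if not sp:
            rules.append("sift_polyphen")
        failed.append(",".join(rules))
    out["failed_rules"] = failed
    out["retained"] = (
        out["pass_rarity"] & out["pass_cadd"] & out["pass_consequence"]
        & out["pass_sift_polyphen"] & ~out["cadd_pending"]
    )
    return out


def decisions_from_table(table: pd.DataFrame) -> list[FilterDecision]:
    """FilterDecision records from a run_cascade output table."""
    out = []
    for rec in table.itertuples(index=False):
        failed = [r for r in str(rec.failed_rules).split(",") if r]
        out.append(FilterDecision(
            key=(rec.chrom, rec.pos, rec.ref, rec.alt),
            retained=bool(rec.retained),
            pending=bool(rec.cadd_pending),
            failed_rules=failed,
        ))
    return out


def curate_likely_causal(
    retained: pd.DataFrame,
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    known_genes=(),
    segregation_failures=(),
) -> pd.DataFrame:
    """Curation of cascade survivors down to likely-causative candidates.

    Removes, with a reason column:

    * ``shared_with_controls`` — any variant carried by >= 1 control;
    * ``co_occurs_with_causal`` — a variant of uncertain significance
      (operationalised as missense, since no clinical classification is
      available) in a sample that also carries a retained variant in a
      known disease gene or a retained high-impact PTV;
    * ``fails_segregation`` — caller-supplied keys that failed family
      segregation, when family data exist.

    ``retained`` must carry a ``row`` column with genotype column indices.
    """
    status = samples.set_index("sample_id")["status"]
    id_list = genotypes.sample_ids
    control_rows = np.array([i for i, s in enumerate(id_list) if status.get(s) == "control"])
    known = set(known_genes)
    seg_fail = {tuple(k) for k in segregation_failures}

    causal_carrier_rows: set[int] = set()
    for rec in retained.itertuples(index=False):
        if rec.gene in known or rec.consequence == PTV:
            causal_carrier_rows.update(genotypes.carriers_of(int(rec.row)))

    reasons = []
    for rec in retained.itertuples(index=False):
        carriers = genotypes.carriers_of(int(rec.row))
        reason = ""
        if tuple((rec.chrom, rec.pos, rec.ref, rec.alt)) in seg_fail:
            reason = "fails_segregation"
        elif control_rows.size and np.isin(carriers, control_rows).any():
            reason = "shared_with_controls"
        elif rec.consequence == MISSENSE and rec.gene not in known:
            # uncertain significance: does any carrier also hold a causal hit
            # on a *different* variant?
            for c in carriers:
                if c in causal_carrier_rows:
                    reason = "co_occurs_with_causal"
                    break
        reasons.append(reason)
    out = retained.copy()
    out["curation_excluded"] = [r != "" for r in reasons]
    out["curation_reason"] = reasons
    return out
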