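"""Reusable study-condition experiments on synthetic cohorts.

These runners chain the scan-relevant pipeline stages (QC, subset
frequencies, filtering cascade, burden and SKAT-O scans) on generated
cohorts, and are used both by the validation suite and by the acceptance
script: null-cohort calibration of the family-wise error rate, and
planted-gene recovery (rank and adjusted significance of a known causal
gene).

Cohorts in these experiments carry no pedigrees, so the unrelated-control
subset is the full control set and the relatedness stage is skipped; the
SKAT-O null model corrects for read-length batch and sex (the generator's
background rare variants carry no population stratification, so ancestry
PCs are not informative here and are exercised in the full pipeline
instead).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import burden, filtering, frequencies, qc, skato
from .pipeline import build_gene_variants
from .synthetic import CohortConfig, Cohort, generate_cohort

__all__ = [
    "scan_cohort",
    "null_calibration",
    "planted_recovery",
    "cascade_truth_fixture",
    "CALIBRATION_CONFIG",
]


def cascade_truth_fixture() -> pd.DataFrame:
    """Twenty variants with hand-assigned truth covering every filter-rule
    boundary (exact MAF and CADD threshold values, the X-chromosome rarity
    threshold, the SIFT/PolyPhen conjunction, pending CADD).

    Column ``expect`` holds the truth: "retained", "pending", or the
    comma-joined failed rule set.
    """
    def v(consequence="missense", canonical=True, cadd=20.0, sift="deleterious",
          polyphen="probably_damaging", internal=0.0, ext1=0.0, ext2=0.0,
          is_x=False, expect="retained"):
        return dict(consequence=consequence, canonical=canonical, cadd=cadd,
                    sift=sift, polyphen=polyphen, maf_unrelated_controls=internal,
                    maf_ext1=ext1, maf_ext2=ext2, is_x=is_x, expect=expect)

    rows = [
        v(consequence="ptv", sift="", polyphen="", expect="retained"),
        v(sift="deleterious", polyphen="benign", expect="retained"),
        v(sift="tolerated", polyphen="benign", expect="sift_polyphen"),
        v(sift="tolerated", polyphen="probably_damaging", expect="retained"),
        v(internal=1e-4, expect="rarity"),                      # boundary: strict <
        v(internal=9.9e-5, expect="retained"),
        v(ext1=1e-4, expect="rarity"),                          # external boundary
        v(is_x=True, internal=1.2e-4, expect="retained"),       # below 1/8000
        v(is_x=True, internal=1.25e-4, expect="rarity"),        # X boundary strict
        v(cadd=15.0, expect="retained"),                        # CADD boundary kept
        v(cadd=14.99, expect="cadd"),
        v(cadd=np.nan, expect="pending"),
        v(consequence="synonymous", expect="consequence"),
        v(canonical=False, expect="consequence"),
        v(consequence="ptv", sift="tolerated", polyphen="benign", expect="retained"),
        v(internal=2e-4, cadd=10.0, expect="rarity,cadd"),
        v(sift="", polyphen="benign", expect="retained"),       # missing SIFT passes
        v(internal=np.nan, expect="retained"),                  # undefined MAF kept
        v(ext2=5e-3, expect="rarity"),
        v(consequence="other", expect="consequence"),
    ]
    df = pd.DataFrame(rows)
    df.insert(0, "chrom", np.where(df["is_x"], "chrX", "chr1"))
    df.insert(1, "pos", np.arange(1, len(df) + 1) * 100)
    df.insert(2, "ref", "A")
    df.insert(3, "alt", "T")
    df.insert(4, "gene", [f"G{i:02d}" for i in range(len(df))])
    return df

#: the scaled study conditions for calibration and power experiments
CALIBRATION_CONFIG = dict(
    n_cases=500,
    n_controls=3000,
    n_panel_snps=50,          # relatedness stage is not part of these runs
    n_reference_per_pop=10,
)


def prepare_filtered(cohort: Cohort) -> pd.DataFrame:
    """QC, subset frequencies and filtering cascade for a pedigree-free cohort."""
    retained, _ = qc.filter_by_opr(cohort.variants)
    subsets = frequencies.define_subsets(cohort.samples, family_networks=[],
                                         unrelated_set=None)
    sex = cohort.samples.set_index("sample_id")["sex"]
    annotated = frequencies.annotate_subset_mafs(retained, cohort.genotypes,
                                                 subsets, sex=sex)
    cascade = filtering.run_cascade(annotated)
    return cascade.loc[cascade["retained"]].copy()


def scan_cohort(cohort: Cohort, modes=("combined",), run_skat: bool = True,
                skat_accuracy: float = 1e-6):
    """Burden (and optionally SKAT-O) scans on one cohort.

    Returns dict with "burden" and optionally "skato" DataFrames; Bonferroni
    uses the gene-model convention (all genes in the toy genome).
    """
    filtered = prepare_filtered(cohort)
    out = {"filtered": filtered}
    out["burden"] = burden.run_burden_scan(
        filtered, cohort.genotypes, cohort.samples, cohort.genes,
        modes=modes, m_convention="gene_model")
    if run_skat:
        s = cohort.samples
        phenotype = (s["status"] == "case").astype(float).to_numpy()
        cov = np.column_stack([
            (s["read_batch"] == "150bp").astype(float).to_numpy(),
            (s["sex"] == "male").astype(float).to_numpy(),
        ])
        cov = cov[:, np.ptp(cov, axis=0) > 0]
        null = skato.fit_null(phenotype, cov if cov.shape[1] else None)
        gene_vars = build_gene_variants(filtered, cohort.genotypes, s,
                                        gene_order=list(cohort.genes["gene"]))
        out["skato"] = skato.run_skat_scan(
            gene_vars, null, gene_order=list(cohort.genes["gene"]),
            accuracy=skat_accuracy, m_bonferroni=len(cohort.genes))
    return out


def null_calibration(n_replicates: int = 20, n_genes: int = 1000,
                     seed: int = 0, run_skat: bool = True,
                     config_overrides: dict | None = None) -> pd.DataFrame:
    """Family-wise error of the scans across seeded null cohorts.

    One row per replicate with the minimum adjusted p per scan and the
    fraction of raw burden p-values below 0.05 among tested genes.
    """
    rows = []
    for r in range(n_replicates):
        cfg = CohortConfig(**{
            **CALIBRATION_CONFIG, "n_genes": n_genes,
            "seed": (seed + r) % 2**31, **(config_overrides or {}),
        })
        cohort = generate_cohort(cfg)
        res = scan_cohort(cohort, modes=("combined",), run_skat=run_skat)
        b = res["burden"]
        row = {
            "replicate": r,
            "burden_tested": len(b),
            "burden_min_p_adj": float(b["p_adjusted"].min()) if len(b) else 1.0,
            "burden_frac_raw_lt_05": float((b["p_raw"] < 0.05).mean()) if len(b) else 0.0,
        }
        if run_skat:
            sk = res["skato"]
            row["skato_tested"] = len(sk)
            row["skato_min_p_adj"] = float(sk["p_adjusted"].min()) if len(sk) else 1.0
        rows.append(row)
    return pd.DataFrame(rows)


def planted_recovery(n_replicates: int = 20, seed: int = 0,
                     case_carrier_freq: float = 0.04,
                     control_carrier_freq: float = 2e-4,
                     n_genes: int = 100,
                     planted_gene: str = "CAUSAL1",
                     run_skat: bool = True,
                     config_overrides: dict | None = None) -> pd.DataFrame:
    """Rank and adjusted p of a planted causal gene across seeds.

    The planted architecture is dispersed: qualifying variants spread over
    several sites with carriers assigned one site each.
    """
    from .synthetic import PlantedGene

    rows = []
    for r in range(n_replicates):
        cfg = CohortConfig(**{
            **CALIBRATION_CONFIG, "n_genes": n_genes,
            "planted_genes": (PlantedGene(planted_gene, case_carrier_freq,
                                          control_carrier_freq),),
            "seed": (seed + r) % 2**31, **(config_overrides or {}),
        })
        cohort = generate_cohort(cfg)
        res = scan_cohort(cohort, modes=("combined",), run_skat=run_skat)
        b = res["burden"].sort_values("p_raw", kind="stable").reset_index(drop=True)
        b_rank = (b.index[b["gene"] == planted_gene][0] + 1
                  if (b["gene"] == planted_gene).any() else np.nan)
        row = {
            "replicate": r,
            "burden_rank": b_rank,
            "burden_p_adj": float(b.loc[b["gene"] == planted_gene, "p_adjusted"].iloc[0])
            if (b["gene"] == planted_gene).any() else np.nan,
        }
        if run_skat:
            sk = res["skato"].sort_values("p_skato", kind="stable").reset_index(drop=True)
            row["skato_rank"] = (sk.index[sk["gene"] == planted_gene][0] + 1
                                 if (sk["gene"] == planted_gene).any() else np.nan)
            row["skato_p_adj"] = (
                float(sk.loc[sk["gene"] == planted_gene, "p_adjusted"].iloc[0])
                if (sk["gene"] == planted_gene).any() else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
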