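"""Gene-collapsed carrier counts and one-tailed Fisher burden tests.

Filtered variants are grouped per gene and consequence class; subjects with
at least one qualifying variant count once per gene (no double counting),
and the resulting 2x2 carrier table (case carriers / non-carriers vs
control carriers / non-carriers) is tested one-tailed (greater: excess in
cases) by Fisher's exact test, with post-hoc Bonferroni correction.

Test modes: ``ptv`` (protein-truncating only), ``missense``, ``combined``
(either class), and ``biallelic`` (subjects with >= 2 qualifying variant
alleles in the gene: the recessive model; homozygotes count two alleles and
hemizygous male X genotypes count as biallelic-equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .filtering import MISSENSE, PTV
from .genotypes import GenotypeMatrix

__all__ = [
    "CarrierTable",
    "collapse_carriers",
    "fisher_one_tailed",
    "bonferroni",
    "exclude_known_gene_carriers",
    "run_burden_scan",
    "MODES",
]

MODES = ("ptv", "missense", "combined", "biallelic")


@dataclass(frozen=True)
class CarrierTable:
    gene: str
    mode: str
    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int

    def __post_init__(self):
        cells = (self.case_carriers, self.case_noncarriers,
                 self.control_carriers, self.control_noncarriers)
        if any(c < 0 for c in cells):
            raise ValueError(f"negative cell in carrier table for {self.gene}")


def _mode_mask(variants: pd.DataFrame, mode: str) -> np.ndarray:
    cons = variants["consequence"].astype(str)
    if mode == "ptv":
        return (cons == PTV).to_numpy()
    if mode == "missense":
        return (cons == MISSENSE).to_numpy()
    if mode in ("combined", "biallelic"):
        return cons.isin([PTV, MISSENSE]).to_numpy()
    raise ValueError(f"unknown test mode {mode!r}")


def collapse_carriers(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    mode: str,
    sample_subset=None,
) -> dict[str, CarrierTable]:
    """Per-gene carrier tables for one test mode.

    ``variants`` holds the qualifying (filtered) variants with a ``row``
    column of genotype column indices and a ``gene`` column; rows with no
    gene assignment are skipped.  ``sample_subset`` restricts the analysed
    samples (e.g. after known-gene carrier exclusion).
    """
    status = samples.set_index("sample_id")["status"]
    ids = genotypes.sample_ids
    if sample_subset is not None:
        allowed = set(sample_subset)
        analysed = [i for i, s in enumerate(ids) if s in allowed]
    else:
        analysed = list(range(len(ids)))
    is_case = np.array([status.get(ids[i]) == "case" for i in analysed])
    row_of = {r: k for k, r in enumerate(analysed)}
    n_case = int(is_case.sum())
    n_control = len(analysed) - n_case

    mask = _mode_mask(variants, mode)
    tables: dict[str, CarrierTable] = {}
    for gene, group in variants.loc[mask].groupby("gene", sort=False):
        if not isinstance(gene, str) or gene == "":
            continue
        alleles = np.zeros(len(analysed), dtype=np.int32)
        for rec in group.itertuples(index=False):
            j = int(rec.row)
            col = genotypes.column(j)
            for r in genotypes.carriers_of(j):
                k = row_of.get(int(r))
                if k is None:
                    continue
                dose = int(col[r])
                if dose <= 0:
                    continue
                if mode == "biallelic" and bool(getattr(rec, "is_x", False)) and dose == 1:
                    # hemizygous male: single allele acts as two copies
                    sex = samples.set_index("sample_id")["sex"].get(ids[int(r)])
                    if sex == "male":
                        dose = 2
                alleles[k] += dose
        if mode == "biallelic":
            carrier = alleles >= 2
        else:
            carrier = alleles >= 1
        a = int((carrier & is_case).sum())
        c = int((carrier & ~is_case).sum())
        if a + c == 0:
            continue
        tables[gene] = CarrierTable(gene, mode, a, n_case - a, c, n_control - c)
    return tables


def fisher_one_tailed(table: CarrierTable) -> float:
    """Upper-tail Fisher p: probability of >= observed case carriers given
    the margins (hypergeometric survival function)."""
    a, b = table.case_carriers, table.case_noncarriers
    c, d = table.control_carriers, table.control_noncarriers
    n_total = a + b + c + d
    return float(hypergeom.sf(a - 1, n_total, a + c, a + b))


def bonferroni(p_values, m: int):
    """p_adjusted = min(1, m * p); requires m >= number of tests."""
    p = np.asarray(p_values, dtype=float)
    if m <= 0:
        raise ValueError("Bonferroni denominator must be positive")
    if m < p.size:
        raise ValueError(f"m = {m} smaller than number of results ({p.size})")
    return np.minimum(1.0, m * p)


def exclude_known_gene_carriers(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    known_genes,
    deletion_carriers: dict | None = None,
):
    """Drop subjects carrying a qualifying variant or deletion in a known gene.

    ``deletion_carriers`` maps gene -> iterable of carrier sample ids from
    the structural-variant consensus.  Unknown gene symbols are ignored with
    a warning entry in the returned manifest.  Returns
    ``(retained sample-id list, manifest DataFrame)``.
    """
    known = list(dict.fromkeys(known_genes))
    genes_seen = set(variants["gene"].unique())
    if deletion_carriers:
        genes_seen |= set(deletion_carriers)
    removed: dict[str, set] = {}
    warnings = []
    ids = genotypes.sample_ids
    for gene in known:
        hit: set = set()
        sub = variants.loc[variants["gene"] == gene]
        for rec in sub.itertuples(index=False):
            hit.update(ids[int(r)] for r in genotypes.carriers_of(int(rec.row)))
        if deletion_carriers and gene in deletion_carriers:
            hit.update(deletion_carriers[gene])
        if not sub.shape[0] and not (deletion_carriers and gene in deletion_carriers) \
                and gene not in genes_seen:
            warnings.append(gene)
        for s in hit:
            removed.setdefault(s, set()).add(gene)
    retained = [s for s in samples["sample_id"] if s not in removed]
    manifest = pd.DataFrame(
        [{"sample_id": s, "genes": ",".join(sorted(g))} for s, g in sorted(removed.items())]
    )
    manifest.attrs["unknown_genes"] = warnings
    return retained, manifest


def run_burden_scan(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    gene_models: pd.DataFrame,
    modes=("ptv", "missense", "combined"),
    known_genes=(),
    deletion_carriers: dict | None = None,
    m_convention: str = "gene_model",
) -> pd.DataFrame:
    """Fisher burden tests per gene and mode over the filtered variant set.

    ``m_convention`` selects the Bonferroni denominator: ``"gene_model"``
    (all genes in the supplied gene model — the genome-wide convention,
    default) or ``"tested"`` (genes with >= 1 carrier in the mode).  Both
    m values are recorded per row.  Genes are ordered by chromosome and
    position of the gene model; only genes with >= 1 carrier appear.
    """
    if known_genes:
        retained_ids, manifest = exclude_known_gene_carriers(
            samples, variants, genotypes, known_genes, deletion_carriers
        )
    else:
        retained_ids, manifest = list(samples["sample_id"]), pd.DataFrame()

    order = {g: i for i, g in enumerate(gene_models["gene"])}
    rows = []
    for mode in modes:
        tables = collapse_carriers(variants, genotypes, samples, mode,
                                   sample_subset=retained_ids)
        genes = sorted(tables, key=lambda g: order.get(g, len(order)))
        m_tested = len(genes)
        m = len(gene_models) if m_convention == "gene_model" else m_tested
        for gene in genes:
            t = tables[gene]
            p = fisher_one_tailed(t)
            rows.append({
                "gene": gene, "mode": mode,
                "case_carriers": t.case_carriers,
                "case_noncarriers": t.case_noncarriers,
                "control_carriers": t.control_carriers,
                "control_noncarriers": t.control_noncarriers,
                "p_raw": p,
                "p_adjusted": min(1.0, m * p) if m > 0 else np.nan,
                "m_bonferroni": m,
                "m_tested": m_tested,
                "excluded_subjects": len(manifest),
            })
    return pd.DataFrame(rows, columns=[
        "gene", "mode", "case_carriers", "case_noncarriers", "control_carriers",
        "control_noncarriers", "p_raw", "p_adjusted", "m_bonferroni", "m_tested",
        "excluded_subjects",
    ])
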