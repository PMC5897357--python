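"""Seeded synthetic case-control WGS cohorts with planted causal genes.

The generator emulates the statistical structure the downstream analysis
assumes, at a configurable (by default desk-top) scale:

* a toy genome of a few autosomes plus one X chromosome, with gene models
  (exon intervals) on which variant positions live;
* rare background variants (mostly ultra-rare heterozygotes), a slice of
  common variants to exercise the rarity filter, annotation scores (CADD /
  SIFT / PolyPhen) generated conditional on a latent pathogenicity label,
  external reference MAFs, and per-variant QC fractions (pass frequency,
  call rate) with genuine low-quality outliers;
* planted causal genes realising configured case/control carrier
  frequencies through qualifying (rare, deleterious, canonical) variants;
* pedigrees (trio / sib pair / avuncular templates) whose members share
  transmitted alleles Mendelian-consistently, with latent founders where a
  template needs unsequenced individuals;
* population structure on a common-SNP marker panel via per-population
  allele-frequency divergence from shared ancestral frequencies
  (Balding-Nichols model), plus a labelled reference panel for PCA;
* two noisy deletion call sets derived from one shared set of true
  deletions (per-caller breakpoint jitter, false negatives, false
  positives, QC flags) and a benign-region catalogue.

Identical seed and configuration give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .genotypes import GenotypeMatrix

__all__ = [
    "PlantedGene",
    "PlantedDeletion",
    "PopulationSpec",
    "PedigreeSpec",
    "DeletionModel",
    "QCModel",
    "ScoreModel",
    "ExternalMafModel",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "generate_null_cohort",
    "write_bundle",
    "read_bundle",
]


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class PlantedGene:
    gene: str
    case_carrier_freq: float
    control_carrier_freq: float
    class_mix: tuple = (("ptv", 0.5), ("missense", 0.5))
    n_variants: int = 10


@dataclass(frozen=True)
class PlantedDeletion:
    gene: str
    case_carrier_freq: float
    control_carrier_freq: float


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    fraction: float
    divergence: float = 0.15   # Balding-Nichols F_ST against ancestral freqs


@dataclass(frozen=True)
class PedigreeSpec:
    kind: str                  # "trio" | "sib_pair" | "avuncular"
    count: int = 1


@dataclass(frozen=True)
class DeletionModel:
    planted: tuple = ()
    n_random: int = 4
    random_max_carriers: int = 3
    n_benign: int = 3
    benign_carrier_freq: float = 0.01
    jitter_bp: tuple = (("canvas", 300), ("manta", 30))
    fn_rate: tuple = (("canvas", 0.10), ("manta", 0.10))
    fp_per_sample: float = 0.001
    qc_fail_rate: float = 0.05
    length_range: tuple = (8_000, 60_000)


@dataclass(frozen=True)
class QCModel:
    # high-quality variants: pass frequency and call rate near 1
    pass_frequency_beta: tuple = (40.0, 1.2)
    call_rate_beta: tuple = (200.0, 1.0)
    low_quality_fraction: float = 0.06
    low_pass_frequency_range: tuple = (0.2, 0.85)
    low_call_rate_range: tuple = (0.5, 0.98)


@dataclass(frozen=True)
class ScoreModel:
    # CADD concentrated above / below the 15 threshold with genuine overlap
    cadd_deleterious: tuple = (27.0, 5.0)
    cadd_benign: tuple = (7.0, 4.5)
    cadd_missing_rate: float = 0.02
    sift_deleterious_rate: float = 0.90   # P(SIFT "deleterious" | deleterious)
    sift_benign_tolerated_rate: float = 0.85
    polyphen_damaging_rate: float = 0.88
    polyphen_benign_rate: float = 0.85
    prediction_missing_rate: float = 0.03


@dataclass(frozen=True)
class ExternalMafModel:
    zero_fraction: float = 0.7            # absent from reference sets
    rare_log10_range: tuple = (-6.0, -4.3)
    common_external_fraction: float = 0.05
    common_log10_range: tuple = (-3.5, -2.0)


@dataclass(frozen=True)
class CohortConfig:
    n_cases: int = 500
    n_controls: int = 3000
    n_genes: int = 100
    variants_per_gene_mean: float = 8.0
    planted_genes: tuple = ()
    background_rare_carrier_freq: float = 1e-5
    common_variant_fraction: float = 0.15
    common_carrier_freq_range: tuple = (5e-3, 0.05)
    deleterious_fraction: float = 0.35
    external_maf_model: ExternalMafModel = ExternalMafModel()
    score_model: ScoreModel = ScoreModel()
    qc_model: QCModel = QCModel()
    deletion_model: DeletionModel = DeletionModel()
    populations: tuple = (
        PopulationSpec("EUR", 0.85),
        PopulationSpec("SAS", 0.08),
        PopulationSpec("AFR", 0.07),
    )
    n_reference_per_pop: int = 60
    n_panel_snps: int = 10000
    pedigrees: tuple = ()
    male_fraction: float = 0.45
    autosomes: tuple = ("chr1", "chr2", "chr3", "chr4")
    x_chromosome: str = "chrX"
    chrom_length: int = 5_000_000
    x_gene_fraction: float = 0.05
    seed: int = 0


@dataclass
class Cohort:
    config: CohortConfig
    samples: pd.DataFrame
    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    genes: pd.DataFrame
    exons: pd.DataFrame
    panel_keys: pd.DataFrame
    panel: np.ndarray                 # study samples x panel SNPs
    reference: np.ndarray             # reference samples x panel SNPs
    reference_labels: list
    deletions: pd.DataFrame
    benign_regions: pd.DataFrame
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check(cond: bool, fieldname: str, msg: str):
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


def validate_config(cfg: CohortConfig):
    _check(cfg.n_cases > 0, "n_cases", "must be positive")
    _check(cfg.n_controls > 0, "n_controls", "must be positive")
    _check(cfg.n_genes > 0, "n_genes", "must be positive")
    _check(cfg.variants_per_gene_mean >= 1, "variants_per_gene_mean", "must be >= 1")
    _check(0 <= cfg.background_rare_carrier_freq <= 1,
           "background_rare_carrier_freq", "must be a probability")
    _check(0 <= cfg.common_variant_fraction <= 1,
           "common_variant_fraction", "must be a probability")
    _check(0 <= cfg.deleterious_fraction <= 1,
           "deleterious_fraction", "must be a probability")
    _check(0 <= cfg.male_fraction <= 1, "male_fraction", "must be a probability")
    frac = sum(p.fraction for p in cfg.populations)
    _check(abs(frac - 1.0) < 1e-9, "populations", f"fractions sum to {frac}, not 1")
    for p in cfg.populations:
        _check(0 < p.divergence < 1, "populations", f"divergence {p.divergence} not in (0,1)")
    names = set()
    for pg in cfg.planted_genes:
        _check(0 <= pg.case_carrier_freq <= 1, "planted_genes",
               f"{pg.gene}: case carrier frequency not a probability")
        _check(0 <= pg.control_carrier_freq <= 1, "planted_genes",
               f"{pg.gene}: control carrier frequency not a probability")
        _check(pg.n_variants >= 1, "planted_genes", f"{pg.gene}: n_variants must be >= 1")
        _check(pg.gene not in names, "planted_genes", f"duplicate gene {pg.gene}")
        names.add(pg.gene)
    _check(len(cfg.planted_genes) <= cfg.n_genes, "planted_genes",
           "more planted genes than genes")
    for ped in cfg.pedigrees:
        _check(ped.kind in ("trio", "sib_pair", "avuncular"), "pedigrees",
               f"unknown template {ped.kind!r}")
        _check(ped.count >= 0, "pedigrees", "count must be non-negative")
    dm = cfg.deletion_model
    _check(0 <= dm.fp_per_sample <= 1, "deletion_model.fp_per_sample", "must be a probability")
    _check(0 <= dm.qc_fail_rate <= 1, "deletion_model.qc_fail_rate", "must be a probability")
    for pd_ in dm.planted:
        _check(0 <= pd_.case_carrier_freq <= 1, "deletion_model.planted",
               f"{pd_.gene}: case carrier frequency not a probability")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _build_genes(cfg: CohortConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    n_x = int(round(cfg.n_genes * cfg.x_gene_fraction))
    chrom_of = []
    for i in range(cfg.n_genes - n_x):
        chrom_of.append(cfg.autosomes[i % len(cfg.autosomes)])
    chrom_of += [cfg.x_chromosome] * n_x
    per_chrom: dict[str, int] = {}
    genes, exons = [], []
    planted_names = [pg.gene for pg in cfg.planted_genes]
    spacing_cache: dict[str, int] = {}
    counts: dict[str, int] = {}
    for c in chrom_of:
        counts[c] = counts.get(c, 0) + 1
    for c, k in counts.items():
        spacing_cache[c] = cfg.chrom_length // (k + 1)
    for dp in cfg.deletion_model.planted:
        if dp.gene not in planted_names:
            planted_names.append(dp.gene)
    n_exons, exon_len, intron_len = 8, 150, 1850
    for i, chrom in enumerate(chrom_of):
        idx = per_chrom.get(chrom, 0)
        per_chrom[chrom] = idx + 1
        start = spacing_cache[chrom] * (idx + 1)
        name = f"G{i + 1:04d}"
        gene_exons = []
        for e in range(n_exons):
            es = start + e * (exon_len + intron_len)
            gene_exons.append((es, es + exon_len))
        genes.append({
            "gene": name, "chrom": chrom,
            "start": gene_exons[0][0], "end": gene_exons[-1][1],
            "is_x": chrom == cfg.x_chromosome,
        })
        for es, ee in gene_exons:
            exons.append({"gene": name, "chrom": chrom, "start": es, "end": ee})
    genes = pd.DataFrame(genes)
    exons = pd.DataFrame(exons)
    # planted genes take evenly spaced slots and adopt the configured labels
    if planted_names:
        step = max(1, cfg.n_genes // len(planted_names))
        rename = {}
        used = set()
        for k, label in enumerate(planted_names):
            slot = (k * step) % cfg.n_genes
            while genes.loc[slot, "gene"] in rename or slot in used:
                slot = (slot + 1) % cfg.n_genes
            used.add(slot)
            rename[genes.loc[slot, "gene"]] = label
        genes["gene"] = genes["gene"].map(lambda g: rename.get(g, g))
        exons["gene"] = exons["gene"].map(lambda g: rename.get(g, g))
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genes, exons


_PED_TEMPLATES = {
    # member: (status, emitted, father, mother)  — None parent = founder
    "trio": {
        "fa": ("control", True, None, None),
        "mo": ("control", True, None, None),
        "ch": ("case", True, "fa", "mo"),
    },
    "sib_pair": {
        "fa": ("control", False, None, None),
        "mo": ("control", False, None, None),
        "s1": ("case", True, "fa", "mo"),
        "s2": ("case", True, "fa", "mo"),
    },
    "avuncular": {
        "gf": ("control", False, None, None),
        "gm": ("control", False, None, None),
        "un": ("case", True, "gf", "gm"),
        "pa": ("control", False, "gf", "gm"),
        "sp": ("control", False, None, None),
        "ne": ("case", True, "pa", "sp"),
    },
}


def _build_samples(cfg: CohortConfig, rng):
    """Sample sheet plus pedigree bookkeeping.

    Returns (samples DataFrame incl. latent rows, list of (child, father,
    mother) transmissions in topological order).  Pedigree cases replace
    ordinary case slots; pedigree control parents are additional to the
    configured controls (they are sequenced relatives, not cohort
    controls), but counted inside n_controls to keep totals exact.
    """
    rows = []
    transmissions = []
    fam_no = 0
    ped_case, ped_ctrl = 0, 0
    for ped in cfg.pedigrees:
        for _ in range(ped.count):
            fam_no += 1
            fam = f"FAM{fam_no:03d}"
            template = _PED_TEMPLATES[ped.kind]
            for member, (status, emitted, fa, mo) in template.items():
                sid = f"{fam}_{member}"
                rows.append({
                    "sample_id": sid, "status": status,
                    "family_id": fam, "emitted": emitted,
                })
                if fa is not None:
                    transmissions.append((sid, f"{fam}_{fa}", f"{fam}_{mo}"))
                if emitted:
                    if status == "case":
                        ped_case += 1
                    else:
                        ped_ctrl += 1
    _check(ped_case <= cfg.n_cases, "pedigrees", "more pedigree cases than n_cases")
    _check(ped_ctrl <= cfg.n_controls, "pedigrees", "more pedigree controls than n_controls")
    for i in range(cfg.n_cases - ped_case):
        rows.append({"sample_id": f"case{i + 1:05d}", "status": "case",
                     "family_id": "", "emitted": True})
    for i in range(cfg.n_controls - ped_ctrl):
        rows.append({"sample_id": f"ctrl{i + 1:05d}", "status": "control",
                     "family_id": "", "emitted": True})
    samples = pd.DataFrame(rows)
    n = len(samples)
    samples["sex"] = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    samples["read_batch"] = np.where(rng.random(n) < 0.5, "100bp", "150bp")
    # population per family is shared (drawn once per family)
    fracs = np.array([p.fraction for p in cfg.populations])
    labels = [p.label for p in cfg.populations]
    pop = np.array(labels, dtype=object)[rng.choice(len(labels), size=n, p=fracs)]
    for fam, grp in samples.groupby("family_id"):
        if fam:
            pop[grp.index] = pop[grp.index[0]]
    samples["population"] = pop
    # pedigree parents get opposite sexes for coherent transmission
    for child, fa, mo in transmissions:
        samples.loc[samples["sample_id"] == fa, "sex"] = "male"
        samples.loc[samples["sample_id"] == mo, "sex"] = "female"
    return samples, transmissions


def _population_freqs(cfg: CohortConfig, rng, n_snps: int):
    """Ancestral and per-population panel allele frequencies."""
    p0 = rng.uniform(0.35, 0.5, size=n_snps)
    freqs = {}
    for pop in cfg.populations:
        f = pop.divergence
        a = p0 * (1 - f) / f
        b = (1 - p0) * (1 - f) / f
        freqs[pop.label] = np.clip(rng.beta(a, b), 0.01, 0.99)
    return p0, freqs


def _transmit_dose(dose_f: np.ndarray, dose_m: np.ndarray, rng):
    """Autosomal child dosage: one random allele per parent."""
    allele_f = np.where(dose_f == 1, rng.integers(0, 2, dose_f.size), dose_f // 2)
    allele_m = np.where(dose_m == 1, rng.integers(0, 2, dose_m.size), dose_m // 2)
    return allele_f + allele_m


def _build_panel(cfg: CohortConfig, rng, samples, transmissions):
    """Marker-panel genotypes for study and reference samples (autosomal)."""
    n_snps = cfg.n_panel_snps
    p0, freqs = _population_freqs(cfg, rng, n_snps)
    id_to_row = {s: i for i, s in enumerate(samples["sample_id"])}
    n = len(samples)
    panel = np.zeros((n, n_snps), dtype=np.int8)
    children = {c for c, _, _ in transmissions}
    for i in range(n):
        if samples["sample_id"].iloc[i] in children:
            continue
        panel[i] = rng.binomial(2, freqs[samples["population"].iloc[i]])
    for child, fa, mo in transmissions:  # topological order by construction
        ci, fi, mi = id_to_row[child], id_to_row[fa], id_to_row[mo]
        panel[ci] = _transmit_dose(panel[fi], panel[mi], rng)
    ref_rows, ref_labels = [], []
    for pop in cfg.populations:
        g = rng.binomial(2, np.tile(freqs[pop.label], (cfg.n_reference_per_pop, 1)))
        ref_rows.append(g.astype(np.int8))
        ref_labels += [pop.label] * cfg.n_reference_per_pop
    reference = np.vstack(ref_rows)
    chrom = cfg.autosomes[0]
    panel_keys = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(1, n_snps + 1) * 50 + 4_000_000,
        "ref": "A", "alt": "G",
    })
    return panel_keys, panel, reference, ref_labels


_BASES = np.array(list("ACGT"))


def _build_variants(cfg: CohortConfig, rng, samples, genes, exons, transmissions):
    """Annotation table plus sparse genotypes for the rare-variant stream."""
    sm = cfg.score_model
    em = cfg.external_maf_model
    qm = cfg.qc_model
    id_to_row = {s: i for i, s in enumerate(samples["sample_id"])}
    emitted = samples["emitted"].to_numpy(dtype=bool)
    status = samples["status"].to_numpy()
    sex = samples["sex"].to_numpy()
    children = {c for c, _, _ in transmissions}
    child_rows = np.array(sorted(id_to_row[c] for c in children), dtype=int)
    founder_pool = np.array([
        i for i in range(len(samples)) if samples["sample_id"].iloc[i] not in children
    ])
    case_pool = np.array([
        i for i in range(len(samples))
        if emitted[i] and status[i] == "case"
        and samples["family_id"].iloc[i] == ""
    ])
    control_pool = np.array([
        i for i in range(len(samples))
        if emitted[i] and status[i] == "control"
        and samples["family_id"].iloc[i] == ""
    ])

    exons_by_gene = {g: grp[["start", "end"]].to_numpy()
                     for g, grp in exons.groupby("gene")}
    gene_info = genes.set_index("gene")
    planted_by_gene = {pg.gene: pg for pg in cfg.planted_genes}

    records = []       # annotation dicts
    entries = []       # (row, col, dose)
    col = 0

    def _position(gene: str) -> int:
        ivs = exons_by_gene[gene]
        e = int(rng.integers(0, len(ivs)))
        return int(rng.integers(ivs[e][0], ivs[e][1]))

    def _alleles():
        ref, alt = rng.choice(4, size=2, replace=False)
        return _BASES[ref], _BASES[alt]

    def _scores(deleterious: bool, consequence: str, force_damaging=False):
        if rng.random() < sm.cadd_missing_rate and not force_damaging:
            cadd = np.nan
        elif deleterious:
            cadd = max(0.0, rng.normal(*sm.cadd_deleterious))
        else:
            cadd = max(0.0, rng.normal(*sm.cadd_benign))
        sift = polyphen = ""
        if consequence == "missense":
            if force_damaging:
                sift, polyphen = "deleterious", "probably_damaging"
            else:
                if rng.random() >= sm.prediction_missing_rate:
                    if deleterious:
                        sift = "deleterious" if rng.random() < sm.sift_deleterious_rate else "tolerated"
                    else:
                        sift = "tolerated" if rng.random() < sm.sift_benign_tolerated_rate else "deleterious"
                if rng.random() >= sm.prediction_missing_rate:
                    if deleterious:
                        polyphen = "probably_damaging" if rng.random() < sm.polyphen_damaging_rate else "possibly_damaging"
                    else:
                        polyphen = "benign" if rng.random() < sm.polyphen_benign_rate else "possibly_damaging"
        if force_damaging:
            cadd = max(16.0, rng.normal(30.0, 4.0))
        return cadd, sift, polyphen

    def _qc(good: bool):
        if good:
            pf = min(1.0, rng.beta(*qm.pass_frequency_beta))
            cr = min(1.0, rng.beta(*qm.call_rate_beta))
        else:
            pf = rng.uniform(*qm.low_pass_frequency_range)
            cr = rng.uniform(*qm.low_call_rate_range)
        return pf, cr

    def _external(kind: str):
        if kind == "common":
            return 10.0 ** rng.uniform(*em.common_log10_range)
        if kind == "zero":
            return 0.0
        return 10.0 ** rng.uniform(*em.rare_log10_range)

    def _add_carriers(col_idx: int, rows: np.ndarray, is_x: bool):
        for r in rows:
            if is_x and sex[r] == "male":
                entries.append((r, col_idx, 1))
            else:
                entries.append((r, col_idx, 1))

    # --- background variants per gene -------------------------------------
    for gene in genes["gene"]:
        is_x = bool(gene_info.loc[gene, "is_x"])
        n_var = 1 + int(rng.poisson(cfg.variants_per_gene_mean - 1))
        for _ in range(n_var):
            deleterious = rng.random() < cfg.deleterious_fraction
            if deleterious:
                consequence = "ptv" if rng.random() < 0.3 else "missense"
            else:
                u = rng.random()
                consequence = "synonymous" if u < 0.5 else ("missense" if u < 0.8 else "other")
            canonical = rng.random() < 0.97
            common = rng.random() < cfg.common_variant_fraction
            if common:
                lo, hi = cfg.common_carrier_freq_range
                f = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
                ext_kind = "common"
            else:
                f = cfg.background_rare_carrier_freq
                u = rng.random()
                if u < em.zero_fraction:
                    ext_kind = "zero"
                elif u < em.zero_fraction + em.common_external_fraction:
                    ext_kind = "common"
                else:
                    ext_kind = "rare"
            k = rng.binomial(founder_pool.size, f)
            carriers = rng.choice(founder_pool, size=min(k, founder_pool.size),
                                  replace=False) if k else np.empty(0, dtype=int)
            cadd, sift, poly = _scores(deleterious, consequence)
            pf, cr = _qc(rng.random() >= qm.low_quality_fraction)
            ref, alt = _alleles()
            records.append({
                "chrom": gene_info.loc[gene, "chrom"], "pos": _position(gene),
                "ref": ref, "alt": alt, "gene": gene, "is_x": is_x,
                "consequence": consequence, "canonical": canonical,
                "cadd": cadd, "sift": sift, "polyphen": poly,
                "maf_ext1": _external(ext_kind), "maf_ext2": _external(ext_kind),
                "pass_frequency": pf, "call_rate": cr,
                "planted": False,
            })
            _add_carriers(col, carriers, is_x)
            col += 1

    # --- planted qualifying variants --------------------------------------
    truth_planted = {}
    fam_assignments = []
    for pg in cfg.planted_genes:
        is_x = bool(gene_info.loc[pg.gene, "is_x"])
        mix = dict(pg.class_mix)
        slots = []
        for _ in range(pg.n_variants):
            consequence = rng.choice(list(mix), p=np.array(list(mix.values())) / sum(mix.values()))
            cadd, sift, poly = _scores(True, consequence, force_damaging=True)
            pf = rng.uniform(0.9, 1.0)
            cr = rng.uniform(0.97, 1.0)
            ref, alt = _alleles()
            records.append({
                "chrom": gene_info.loc[pg.gene, "chrom"], "pos": _position(pg.gene),
                "ref": ref, "alt": alt, "gene": pg.gene, "is_x": is_x,
                "consequence": str(consequence), "canonical": True,
                "cadd": cadd, "sift": sift, "polyphen": poly,
                "maf_ext1": 0.0, "maf_ext2": 0.0,
                "pass_frequency": pf, "call_rate": cr,
                "planted": True,
            })
            slots.append(col)
            col += 1
        n_case_carriers = rng.binomial(case_pool.size, pg.case_carrier_freq)
        n_ctrl_carriers = rng.binomial(control_pool.size, pg.control_carrier_freq)
        case_carriers = rng.choice(case_pool, size=n_case_carriers, replace=False)
        ctrl_carriers = rng.choice(control_pool, size=n_ctrl_carriers, replace=False)
        for r in case_carriers:
            entries.append((int(r), int(rng.choice(slots)), 1))
        for r in ctrl_carriers:
            entries.append((int(r), int(rng.choice(slots)), 1))
        truth_planted[pg.gene] = {
            "case_carriers": sorted(samples["sample_id"].iloc[r] for r in case_carriers),
            "control_carriers": sorted(samples["sample_id"].iloc[r] for r in ctrl_carriers),
            "variant_cols": slots,
        }
    # each pedigree shares one family-private qualifying variant in the first
    # planted gene (transmitted consistently through the template)
    if cfg.planted_genes and cfg.pedigrees:
        pg = cfg.planted_genes[0]
        for fam, grp in samples.groupby("family_id"):
            if not fam:
                continue
            cadd, sift, poly = _scores(True, "missense", force_damaging=True)
            ref, alt = _alleles()
            records.append({
                "chrom": gene_info.loc[pg.gene, "chrom"], "pos": _position(pg.gene),
                "ref": ref, "alt": alt, "gene": pg.gene,
                "is_x": bool(gene_info.loc[pg.gene, "is_x"]),
                "consequence": "missense", "canonical": True,
                "cadd": cadd, "sift": sift, "polyphen": poly,
                "maf_ext1": 0.0, "maf_ext2": 0.0,
                "pass_frequency": rng.uniform(0.9, 1.0), "call_rate": rng.uniform(0.97, 1.0),
                "planted": True,
            })
            # carrier path: founder "fa"/"gf" down to every affected member
            members = set(grp["sample_id"])
            path = [s for s in members if s.endswith(("_fa", "_gf"))]
            affected = [s for s in members if
                        samples.set_index("sample_id").loc[s, "status"] == "case"]
            linking = [s for s in members if s.endswith(("_pa",))]
            for s in set(path + affected + linking):
                entries.append((id_to_row[s], col, 1))
            fam_assignments.append({"family_id": fam, "gene": pg.gene, "col": col})
            col += 1

    variants = pd.DataFrame.from_records(records)
    variants["pos"] = variants["pos"].astype(int)

    # --- transmission of background variants to pedigree children ---------
    n_all = len(samples)
    dose = sparse.coo_matrix(
        (
            [d for _, _, d in entries],
            ([r for r, _, _ in entries], [c for _, c, _ in entries]),
        ),
        shape=(n_all, col), dtype=np.int8,
    ).tocsc()
    dose.sum_duplicates()
    dose.data = np.minimum(dose.data, 2)
    if transmissions:
        family_cols = {a["col"] for a in fam_assignments}
        dose = dose.tolil()
        for child, fa, mo in transmissions:
            ci, fi, mi = id_to_row[child], id_to_row[fa], id_to_row[mo]
            carried = sorted(set(dose.rows[fi]) | set(dose.rows[mi]))
            for c in carried:
                if c in family_cols:
                    continue  # family variants assigned explicitly above
                df_, dm_ = int(dose[fi, c]), int(dose[mi, c])
                is_x = bool(variants["is_x"].iloc[c])
                if is_x:
                    # father passes his X to daughters only
                    fa_allele = (df_ > 0) if sex[ci] == "female" else 0
                    mo_allele = int(rng.integers(0, 2)) if dm_ == 1 else dm_ // 2
                    d = int(fa_allele) + int(mo_allele)
                    if sex[ci] == "male":
                        d = min(d, 1)
                else:
                    d = int(_transmit_dose(np.array([df_]), np.array([dm_]), rng)[0])
                dose[ci, c] = d
        dose = dose.tocsc()

    # --- missingness driven by call rate ----------------------------------
    miss_rows, miss_cols = [], []
    call_rates = variants["call_rate"].to_numpy()
    for j, cr in enumerate(call_rates):
        n_miss = rng.binomial(n_all, 1.0 - cr)
        if n_miss:
            rows = rng.choice(n_all, size=n_miss, replace=False)
            miss_rows.extend(int(r) for r in rows)
            miss_cols.extend([j] * n_miss)
    missing = sparse.coo_matrix(
        (np.ones(len(miss_rows), dtype=bool), (miss_rows, miss_cols)),
        shape=(n_all, col),
    ).tocsc()

    variants["row"] = np.arange(len(variants))
    truth = {"planted": truth_planted, "family_variants": fam_assignments}
    return variants, dose, missing, truth


def _build_deletions(cfg: CohortConfig, rng, samples, genes, exons):
    dm = cfg.deletion_model
    emitted = samples["emitted"].to_numpy(dtype=bool)
    status = samples["status"].to_numpy()
    ids = samples["sample_id"].to_numpy()
    case_rows = np.where(emitted & (status == "case"))[0]
    ctrl_rows = np.where(emitted & (status == "control"))[0]
    all_rows = np.where(emitted)[0]
    exons_by_gene = {g: grp[["start", "end"]].to_numpy() for g, grp in exons.groupby("gene")}
    gene_info = genes.set_index("gene")
    autosomes = list(cfg.autosomes)

    truth_events = []  # (chrom, start, end, carrier rows, label)

    for p in dm.planted:
        ivs = exons_by_gene[p.gene]
        n_ex = len(ivs)
        first = int(rng.integers(0, max(1, n_ex - 3)))
        last = min(n_ex - 1, first + int(rng.integers(2, 4)))
        start = int(ivs[first][0] - rng.integers(200, 1500))
        end = int(ivs[last][1] + rng.integers(200, 1500))
        carriers = np.concatenate([
            rng.choice(case_rows, rng.binomial(case_rows.size, p.case_carrier_freq),
                       replace=False),
            rng.choice(ctrl_rows, rng.binomial(ctrl_rows.size, p.control_carrier_freq),
                       replace=False),
        ])
        truth_events.append((str(gene_info.loc[p.gene, "chrom"]), start, end,
                             carriers.astype(int), f"planted:{p.gene}"))

    benign = []
    for b in range(dm.n_benign):
        chrom = autosomes[int(rng.integers(0, len(autosomes)))]
        length = int(rng.integers(*dm.length_range))
        start = int(rng.integers(0, cfg.chrom_length - length))
        benign.append({"chrom": chrom, "start": start, "end": start + length})
        carriers = rng.choice(all_rows, rng.binomial(all_rows.size, dm.benign_carrier_freq),
                              replace=False)
        truth_events.append((chrom, start, start + length, carriers.astype(int),
                             f"benign:{b}"))
    benign = pd.DataFrame(benign, columns=["chrom", "start", "end"])

    for k in range(dm.n_random):
        chrom = autosomes[int(rng.integers(0, len(autosomes)))]
        length = int(rng.integers(*dm.length_range))
        start = int(rng.integers(0, cfg.chrom_length - length))
        n_carr = int(rng.integers(1, dm.random_max_carriers + 1))
        carriers = rng.choice(all_rows, n_carr, replace=False)
        truth_events.append((chrom, start, start + length, carriers.astype(int),
                             f"random:{k}"))

    jitter = dict(dm.jitter_bp)
    fn = dict(dm.fn_rate)
    calls = []
    for chrom, start, end, carriers, label in truth_events:
        for r in carriers:
            for caller in jitter:
                if rng.random() < fn[caller]:
                    continue
                j = jitter[caller]
                s = start + int(rng.integers(-j, j + 1))
                e = end + int(rng.integers(-j, j + 1))
                if e <= s:
                    e = s + 1
                calls.append({
                    "sample": ids[r], "caller": caller, "chrom": chrom,
                    "start": max(0, s), "end": e,
                    "qc_pass": bool(rng.random() >= dm.qc_fail_rate),
                })
    for caller in jitter:
        n_fp = rng.poisson(dm.fp_per_sample * all_rows.size)
        for _ in range(n_fp):
            r = int(rng.choice(all_rows))
            chrom = autosomes[int(rng.integers(0, len(autosomes)))]
            length = int(rng.integers(*dm.length_range))
            start = int(rng.integers(0, cfg.chrom_length - length))
            calls.append({
                "sample": ids[r], "caller": caller, "chrom": chrom,
                "start": start, "end": start + length,
                "qc_pass": bool(rng.random() >= dm.qc_fail_rate),
            })
    deletions = pd.DataFrame(
        calls, columns=["sample", "caller", "chrom", "start", "end", "qc_pass"]
    ).sort_values(["caller", "sample", "chrom", "start"], kind="stable").reset_index(drop=True)
    truth = [
        {"chrom": c, "start": s, "end": e, "label": lbl,
         "carriers": sorted(ids[r] for r in carr)}
        for c, s, e, carr, lbl in truth_events
    ]
    return deletions, benign, truth


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort bundle (in memory).

    Deterministic: same config (incl. seed) gives identical output; use
    :func:`write_bundle` / :func:`read_bundle` for the on-disk formats.
    """
    validate_config(config)
    rng = np.random.default_rng(config.seed)
    genes, exons = _build_genes(config, rng)
    samples, transmissions = _build_samples(config, rng)
    panel_keys, panel, reference, ref_labels = _build_panel(
        config, rng, samples, transmissions)
    variants, dose, missing, truth_v = _build_variants(
        config, rng, samples, genes, exons, transmissions)
    deletions, benign, truth_d = _build_deletions(config, rng, samples, genes, exons)

    emitted_mask = samples["emitted"].to_numpy(dtype=bool)
    emitted_rows = np.where(emitted_mask)[0]
    samples_out = samples.loc[emitted_mask].drop(columns=["emitted"]).reset_index(drop=True)
    gmat = GenotypeMatrix(
        dosage=dose[emitted_rows, :],
        missing=missing[emitted_rows, :],
        sample_ids=list(samples_out["sample_id"]),
    )
    return Cohort(
        config=config,
        samples=samples_out,
        variants=variants,
        genotypes=gmat,
        genes=genes,
        exons=exons,
        panel_keys=panel_keys,
        panel=panel[emitted_rows, :],
        reference=reference,
        reference_labels=ref_labels,
        deletions=deletions,
        benign_regions=benign,
        truth={"variants": truth_v, "deletions": truth_d,
               "transmissions": [t for t in transmissions]},
    )


def generate_null_cohort(config: CohortConfig) -> Cohort:
    """A cohort with no planted effects: case and control carrier
    probabilities are identical at every gene."""
    if config.planted_genes:
        raise ConfigError("planted_genes: must be empty for a null cohort")
    if config.deletion_model.planted:
        raise ConfigError("deletion_model.planted: must be empty for a null cohort")
    return generate_cohort(config)


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

def _write_vcf(path, variants_df, gmat_dose, gmat_missing, sample_ids,
               contigs, sex=None, is_x=None):
    """Minimal VCF v4.2 writer (GT only); hemizygous male X written haploid."""
    n = len(sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in contigs:
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        dose = gmat_dose.tocsc()
        miss = gmat_missing.tocsc()
        order = np.lexsort((variants_df["pos"].to_numpy(),
                            variants_df["chrom"].to_numpy()))
        for j in order:
            rec = variants_df.iloc[j]
            gts = np.full(n, "0/0", dtype=object)
            x_site = bool(is_x[j]) if is_x is not None else False
            if x_site and sex is not None:
                gts[np.asarray(sex) == "male"] = "0"
            start, stop = dose.indptr[j], dose.indptr[j + 1]
            for r, d in zip(dose.indices[start:stop], dose.data[start:stop]):
                if x_site and sex is not None and sex[r] == "male":
                    gts[r] = "1"
                else:
                    gts[r] = "0/1" if d == 1 else "1/1"
            start, stop = miss.indptr[j], miss.indptr[j + 1]
            for r in miss.indices[start:stop]:
                if x_site and sex is not None and sex[r] == "male":
                    gts[r] = "."
                else:
                    gts[r] = "./."
            fh.write(f"{rec['chrom']}\t{int(rec['pos'])}\tv{j}\t{rec['ref']}\t"
                     f"{rec['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_bundle(cohort: Cohort, outdir) -> dict:
    """Write the cohort as the plain-text file bundle the pipeline consumes.

    Returns a dict of paths.  Files: genotype VCF, annotation TSV, sample
    sheet TSV, gene model TSV + exon BED, two per-caller deletion TSVs,
    benign-region BED, marker-panel VCF for study samples, reference-panel
    VCF and population labels TSV.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    cfg = cohort.config
    contigs = [(c, cfg.chrom_length) for c in list(cfg.autosomes) + [cfg.x_chromosome]]
    paths = {}

    sex = cohort.samples["sex"].to_numpy()
    paths["genotypes"] = os.path.join(outdir, "genotypes.vcf")
    _write_vcf(paths["genotypes"], cohort.variants, cohort.genotypes.dosage,
               cohort.genotypes.missing, list(cohort.samples["sample_id"]),
               contigs, sex=sex, is_x=cohort.variants["is_x"].to_numpy())

    paths["annotations"] = os.path.join(outdir, "annotations.tsv")
    cohort.variants.to_csv(paths["annotations"], sep="\t", index=False)

    paths["samples"] = os.path.join(outdir, "samples.tsv")
    cohort.samples.to_csv(paths["samples"], sep="\t", index=False)

    paths["genes"] = os.path.join(outdir, "genes.tsv")
    cohort.genes.to_csv(paths["genes"], sep="\t", index=False)
    paths["exons"] = os.path.join(outdir, "exons.bed")
    cohort.exons[["chrom", "start", "end", "gene"]].to_csv(
        paths["exons"], sep="\t", index=False, header=False)

    for caller in sorted(cohort.deletions["caller"].unique()):
        p = os.path.join(outdir, f"deletions_{caller}.tsv")
        cohort.deletions.loc[cohort.deletions["caller"] == caller].to_csv(
            p, sep="\t", index=False)
        paths[f"deletions_{caller}"] = p

    paths["benign"] = os.path.join(outdir, "benign.bed")
    cohort.benign_regions.to_csv(paths["benign"], sep="\t", index=False, header=False)

    paths["panel"] = os.path.join(outdir, "panel.vcf")
    panel_sp = sparse.csc_matrix(cohort.panel)
    _write_vcf(paths["panel"], cohort.panel_keys, panel_sp,
               sparse.csc_matrix(panel_sp.shape, dtype=bool),
               list(cohort.samples["sample_id"]), contigs)

    paths["reference_panel"] = os.path.join(outdir, "reference_panel.vcf")
    ref_ids = [f"ref{i + 1:04d}" for i in range(cohort.reference.shape[0])]
    _write_vcf(paths["reference_panel"], cohort.panel_keys,
               sparse.csc_matrix(cohort.reference),
               sparse.csc_matrix(cohort.reference.shape, dtype=bool),
               ref_ids, contigs)
    paths["reference_labels"] = os.path.join(outdir, "reference_labels.tsv")
    pd.DataFrame({"sample_id": ref_ids, "population": cohort.reference_labels}).to_csv(
        paths["reference_labels"], sep="\t", index=False)
    return paths


def _read_vcf(path, sample_ids=None):
    """Read a GT-only VCF back into (variant key DataFrame, dosage, missing)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = vcf.samples
    recs, data, rows, cols, mrows, mcols = [], [], [], [], [], []
    j = 0
    for v in vcf:
        recs.append({"chrom": v.CHROM, "pos": v.POS, "ref": v.REF,
                     "alt": v.ALT[0] if v.ALT else ""})
        for i, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1] if a is not None]
            if any(a == -1 for a in alleles):
                mrows.append(i)
                mcols.append(j)
                continue
            d = sum(1 for a in alleles if a > 0)
            if d:
                rows.append(i)
                cols.append(j)
                data.append(d)
        j += 1
    vcf.close()
    n = len(samples)
    dose = sparse.coo_matrix((data, (rows, cols)), shape=(n, j), dtype=np.int8).tocsc()
    missing = sparse.coo_matrix(
        (np.ones(len(mrows), dtype=bool), (mrows, mcols)), shape=(n, j)).tocsc()
    return pd.DataFrame(recs), dose, missing, samples


def read_bundle(indir) -> Cohort:
    """Read a written bundle back (truth metadata is not persisted)."""
    import os

    samples = pd.read_csv(os.path.join(indir, "samples.tsv"), sep="\t",
                          keep_default_na=False)
    variants = pd.read_csv(os.path.join(indir, "annotations.tsv"), sep="\t",
                           keep_default_na=False,
                           na_values={"cadd": ""})
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t")
    exons = pd.read_csv(os.path.join(indir, "exons.bed"), sep="\t",
                        names=["chrom", "start", "end", "gene"])
    keys, dose, missing, vcf_samples = _read_vcf(os.path.join(indir, "genotypes.vcf"))
    # genotype columns are VCF-ordered; realign to annotation order
    key_index = {}
    for i, k in enumerate(zip(keys["chrom"], keys["pos"], keys["ref"], keys["alt"])):
        key_index[k] = i
    order = [key_index[k] for k in zip(variants["chrom"], variants["pos"],
                                       variants["ref"], variants["alt"])]
    gmat = GenotypeMatrix(dosage=dose[:, order], missing=missing[:, order],
                          sample_ids=list(vcf_samples))
    variants = variants.copy()
    variants["row"] = np.arange(len(variants))

    panel_keys, pdose, _, _ = _read_vcf(os.path.join(indir, "panel.vcf"))
    panel = np.asarray(pdose.todense())
    rkeys, rdose, _, _ = _read_vcf(os.path.join(indir, "reference_panel.vcf"))
    reference = np.asarray(rdose.todense())
    ref_labels = list(pd.read_csv(os.path.join(indir, "reference_labels.tsv"),
                                  sep="\t")["population"])
    dels = []
    for f in sorted(os.listdir(indir)):
        if f.startswith("deletions_") and f.endswith(".tsv"):
            dels.append(pd.read_csv(os.path.join(indir, f), sep="\t"))
    deletions = pd.concat(dels, ignore_index=True) if dels else pd.DataFrame(
        columns=["sample", "caller", "chrom", "start", "end", "qc_pass"])
    benign = pd.read_csv(os.path.join(indir, "benign.bed"), sep="\t",
                         names=["chrom", "start", "end"])
    # reconstruct the config scale actually present in the files
    cfg = CohortConfig(
        n_cases=int((samples["status"] == "case").sum()),
        n_controls=int((samples["status"] == "control").sum()),
        n_genes=len(genes),
    )
    return Cohort(
        config=cfg, samples=samples, variants=variants, genotypes=gmat,
        genes=genes, exons=exons, panel_keys=panel_keys, panel=panel,
        reference=reference, reference_labels=ref_labels,
        deletions=deletions, benign_regions=benign, truth={},
    )
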