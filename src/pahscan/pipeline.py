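"""End-to-end orchestration, carrier-fraction reporting and plot tables.

Stage order: variant QC (OPR) -> ancestry / relatedness -> analysis subsets
and internal allele frequencies -> rare-deleterious filtering cascade ->
association scans (Fisher burden per mode, SKAT-O, deletion consensus
burden), each optionally re-run after excluding carriers of variants in
previously reported disease genes.  Every output table is written as TSV
and the run manifest records configuration, thresholds, seeds and a config
hash so identical configs give identical result bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import ancestry, burden, filtering, frequencies, qc, skato, sv
from .synthetic import Cohort

__all__ = [
    "RunConfig",
    "CohortSummary",
    "run_pipeline",
    "carrier_fraction_report",
    "manhattan_table",
    "build_gene_variants",
]


@dataclass
class RunConfig:
    input_dir: str | None = None          # bundle directory (None: simulate)
    output_dir: str = "pahscan_out"
    opr_threshold: float = qc.DEFAULT_OPR_THRESHOLD
    filter_thresholds: filtering.FilterThresholds = field(
        default_factory=filtering.FilterThresholds)
    kinship_threshold: float = ancestry.KINSHIP_THRESHOLD_3RD_DEGREE
    ambiguity_margin: float = ancestry.DEFAULT_AMBIGUITY_MARGIN
    known_genes: tuple = ()
    burden_modes: tuple = ("ptv", "missense", "combined")
    m_convention: str = "gene_model"
    sv_caller_ro: float = 0.20
    sv_merge_ro: float = 0.50
    sv_max_freq: float = 1e-3
    skat_accuracy: float = 1e-6
    n_pcs: int = 5
    seed: int = 0
    simulate: dict = field(default_factory=dict)   # CohortConfig overrides

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter_thresholds"] = dataclasses.asdict(self.filter_thresholds)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ft = raw.pop("filter_thresholds", None)
        cfg = cls(**raw)
        if ft:
            cfg.filter_thresholds = filtering.FilterThresholds(**ft)
        return cfg


@dataclass
class CohortSummary:
    rows: pd.DataFrame    # category, count, denominator, fraction, percent

    def percent(self, category: str) -> str:
        rec = self.rows.loc[self.rows["category"] == category]
        if rec.empty:
            raise KeyError(category)
        return rec["percent"].iloc[0]


def _round_half_up_1dp(x: float) -> str:
    return str(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def carrier_fraction_report(counts: dict) -> CohortSummary:
    """Percentage summaries from carrier counts.

    ``counts`` maps category -> (count, denominator).  Display percentages
    are rounded half-up to one decimal (the convention of the cohort
    literature); unrounded fractions are kept alongside.
    """
    rows = []
    for category, (count, denom) in counts.items():
        if denom <= 0:
            raise ValueError(f"zero denominator for category {category!r}")
        if count < 0:
            raise ValueError(f"negative count for category {category!r}")
        frac = count / denom
        rows.append({
            "category": category, "count": int(count), "denominator": int(denom),
            "fraction": frac, "percent": _round_half_up_1dp(100.0 * frac),
        })
    return CohortSummary(pd.DataFrame(
        rows, columns=["category", "count", "denominator", "fraction", "percent"]))


def manhattan_table(results: pd.DataFrame, gene_models: pd.DataFrame,
                    adjusted_threshold: float = 0.05,
                    extra_thresholds: dict | None = None) -> pd.DataFrame:
    """Plot-ready table: -log10 raw and adjusted p against gene midpoints.

    Genes absent from the gene model are skipped (logged in ``attrs``).
    The returned frame's ``attrs["thresholds"]`` holds the significance
    lines (-log10 scale): the Bonferroni-adjusted 0.05 line plus any extras
    (for instance the 5e-8 genome-wide line used for the deletion scan).
    """
    if results.empty:
        raise ValueError("no results to plot")
    gm = gene_models.set_index("gene")
    rows, skipped = [], []
    for rec in results.itertuples(index=False):
        if rec.gene not in gm.index:
            skipped.append(rec.gene)
            continue
        info = gm.loc[rec.gene]
        rows.append({
            "gene": rec.gene,
            "chrom": info["chrom"],
            "midpoint": int((info["start"] + info["end"]) // 2),
            "mode": getattr(rec, "mode", ""),
            "p_raw": rec.p_raw if hasattr(rec, "p_raw") else rec.p_skato,
            "p_adjusted": rec.p_adjusted,
            "neglog10_p_raw": float(-np.log10(rec.p_raw if hasattr(rec, "p_raw")
                                              else rec.p_skato)),
            "neglog10_p_adjusted": float(-np.log10(max(rec.p_adjusted, 5e-324))),
        })
    out = pd.DataFrame(rows).sort_values(["chrom", "midpoint"], kind="stable")
    out = out.reset_index(drop=True)
    thresholds = {"adjusted_0.05": float(-np.log10(adjusted_threshold))}
    for name, value in (extra_thresholds or {}).items():
        thresholds[name] = float(-np.log10(value))
    out.attrs["thresholds"] = thresholds
    out.attrs["skipped_genes"] = skipped
    return out


def build_gene_variants(variants: pd.DataFrame, genotypes, samples: pd.DataFrame,
                        sample_subset=None, gene_order=None):
    """Per-gene dense genotype blocks and sample MAFs for the SKAT-O scan.

    Restricted to the analysed samples; monomorphic columns are dropped.
    Returns dict gene -> (G, mafs).
    """
    ids = genotypes.sample_ids
    if sample_subset is not None:
        allowed = set(sample_subset)
        rows = [i for i, s in enumerate(ids) if s in allowed]
    else:
        rows = list(range(len(ids)))
    rows = np.array(rows)
    out = {}
    genes = gene_order if gene_order is not None else list(
        dict.fromkeys(variants["gene"]))
    by_gene = dict(tuple(variants.groupby("gene", sort=False)))
    for gene in genes:
        grp = by_gene.get(gene)
        if grp is None:
            continue
        cols = grp["row"].to_numpy(dtype=int)
        g = genotypes.dense(rows=rows, cols=cols, missing_as=0)
        af = g.sum(axis=0) / (2.0 * g.shape[0])
        keep = (af > 0) & (af < 1)
        if not keep.any():
            continue
        g = g[:, keep]
        mafs = np.minimum(af[keep], 1.0 - af[keep])
        out[gene] = (g, mafs)
    return out


def _log(lines: list, stage: str, **fields):
    entry = {"stage": stage, **fields}
    lines.append(json.dumps(entry, sort_keys=True))
    return entry


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Run every stage on a bundle directory or an in-memory cohort.

    Returns a dict of result objects; all tables are also written under
    ``config.output_dir`` together with ``run_manifest.json``.
    """
    from . import synthetic

    log: list[str] = []
    if cohort is None:
        if config.input_dir:
            cohort = synthetic.read_bundle(config.input_dir)
        else:
            sim_cfg = synthetic.CohortConfig(**{"seed": config.seed, **config.simulate})
            cohort = synthetic.generate_cohort(sim_cfg)
    _log(log, "load", samples=len(cohort.samples), variants=len(cohort.variants))

    # --- variant QC -------------------------------------------------------
    qc_retained, qc_decisions = qc.filter_by_opr(cohort.variants,
                                                 threshold=config.opr_threshold)
    _log(log, "qc", input=len(qc_decisions), retained=len(qc_retained))

    # --- ancestry & relatedness ------------------------------------------
    sex = cohort.samples.set_index("sample_id")["sex"]
    pca = ancestry.fit_reference_pca(cohort.reference, cohort.reference_labels,
                                     n_pcs=config.n_pcs)
    labels, scores, _ll = ancestry.assign_population(
        cohort.panel, pca, ambiguity_margin=config.ambiguity_margin)
    kinship = ancestry.estimate_kinship(cohort.panel,
                                        sample_ids=list(cohort.samples["sample_id"]))
    unrelated, networks = ancestry.max_unrelated_set(
        kinship, threshold=config.kinship_threshold,
        samples=list(cohort.samples["sample_id"]))
    ancestry_table = pd.DataFrame({
        "sample_id": cohort.samples["sample_id"],
        "population": labels,
        **{f"PC{k + 1}": scores[:, k] for k in range(scores.shape[1])},
        "unrelated": [s in set(unrelated) for s in cohort.samples["sample_id"]],
    })
    _log(log, "ancestry", populations=len(set(labels)),
         unrelated=len(unrelated), family_networks=len(networks))

    # --- subsets and internal frequencies ---------------------------------
    subsets = frequencies.define_subsets(cohort.samples, networks, unrelated)
    annotated = frequencies.annotate_subset_mafs(qc_retained, cohort.genotypes,
                                                 subsets, sex=sex)
    _log(log, "frequencies", subsets={s.name: len(s.members) for s in subsets})

    # --- filtering cascade -------------------------------------------------
    cascade = filtering.run_cascade(annotated, thresholds=config.filter_thresholds)
    filtered = cascade.loc[cascade["retained"]].copy()
    _log(log, "filter", input=len(cascade), retained=len(filtered),
         pending_cadd=int(cascade["cadd_pending"].sum()))

    # --- structural variants ----------------------------------------------
    calls = [sv.DeletionCall(r.sample, r.caller, r.chrom, int(r.start), int(r.end),
                             bool(r.qc_pass))
             for r in cohort.deletions.itertuples(index=False)]
    consensus = sv.intersect_callers(calls, min_ro=config.sv_caller_ro)
    consensus = sv.exclude_benign(
        consensus,
        [(r.chrom, int(r.start), int(r.end))
         for r in cohort.benign_regions.itertuples(index=False)],
        min_ro=config.sv_caller_ro,
    )
    merged = sv.merge_across_samples(consensus, min_ro=config.sv_merge_ro,
                                     cohort_size=len(cohort.samples))
    events = sv.filter_frequency_and_exons(merged, len(cohort.samples),
                                           cohort.exons, max_freq=config.sv_max_freq)
    sv_results = sv.deletion_burden(events, cohort.samples,
                                    m_bonferroni=len(cohort.genes))
    deletion_carriers = {}
    for ev in events:
        for gene in ev.genes:
            deletion_carriers.setdefault(gene, set()).update(ev.carriers)
    _log(log, "sv", calls=len(calls), consensus=len(consensus),
         merged=len(merged), exonic_rare=len(events))

    # --- burden scans -------------------------------------------------------
    results = {}
    results["burden"] = burden.run_burden_scan(
        filtered, cohort.genotypes, cohort.samples, cohort.genes,
        modes=config.burden_modes, m_convention=config.m_convention)
    if config.known_genes:
        results["burden_excl_known"] = burden.run_burden_scan(
            filtered, cohort.genotypes, cohort.samples, cohort.genes,
            modes=config.burden_modes, known_genes=config.known_genes,
            deletion_carriers=deletion_carriers, m_convention=config.m_convention)
    _log(log, "burden", rows=len(results["burden"]))

    # --- SKAT-O -------------------------------------------------------------
    covariates, phenotype, analysed_ids = _skat_covariates(cohort, ancestry_table)
    null = skato.fit_null(phenotype, covariates)
    gene_vars = build_gene_variants(filtered, cohort.genotypes, cohort.samples,
                                    sample_subset=analysed_ids,
                                    gene_order=list(cohort.genes["gene"]))
    m_bonf = (len(cohort.genes) if config.m_convention == "gene_model" else None)
    results["skato"] = skato.run_skat_scan(gene_vars, null,
                                           gene_order=list(cohort.genes["gene"]),
                                           accuracy=config.skat_accuracy,
                                           m_bonferroni=m_bonf)
    _log(log, "skato", rows=len(results["skato"]))
    results["sv"] = sv_results

    # --- reporting -----------------------------------------------------------
    n_cases = int((cohort.samples["status"] == "case").sum())
    counts = {}
    for gene, carrier_ids in _case_carriers_per_gene(filtered, cohort).items():
        counts[gene] = (len(carrier_ids), n_cases)
    summary = carrier_fraction_report(counts) if counts else CohortSummary(
        pd.DataFrame(columns=["category", "count", "denominator", "fraction", "percent"]))

    manhattans = {}
    for name in ("burden", "skato", "sv"):
        table = results.get(name)
        if table is None or table.empty:
            continue
        extra = {"genomewide_5e-8": 5e-8} if name == "sv" else None
        manhattans[name] = manhattan_table(table, cohort.genes,
                                           extra_thresholds=extra)

    out = {
        "qc": qc_decisions,
        "ancestry": ancestry_table,
        "kinship": kinship,
        "subsets": subsets,
        "cascade": cascade,
        "filtered": filtered,
        "sv_events": events,
        "results": results,
        "summary": summary,
        "manhattan": manhattans,
        "log": log,
    }
    _write_outputs(config, out)
    return out


def _skat_covariates(cohort: Cohort, ancestry_table: pd.DataFrame):
    """Read-length batch, sex and leading PCs; phenotype 0/1."""
    s = cohort.samples
    phenotype = (s["status"] == "case").astype(float).to_numpy()
    batch = (s["read_batch"].astype(str) == "150bp").astype(float).to_numpy()
    sexnum = (s["sex"].astype(str) == "male").astype(float).to_numpy()
    pcs = ancestry_table[[c for c in ancestry_table.columns
                          if c.startswith("PC")]].to_numpy()
    cols = [batch, sexnum] + [pcs[:, k] for k in range(pcs.shape[1])]
    cov = np.column_stack([c for c in cols if np.ptp(c) > 0])
    if cov.shape[1] == 0:
        cov = None
    return cov, phenotype, list(s["sample_id"])


def _case_carriers_per_gene(filtered: pd.DataFrame, cohort: Cohort) -> dict:
    status = cohort.samples.set_index("sample_id")["status"]
    ids = cohort.genotypes.sample_ids
    out: dict[str, set] = {}
    for rec in filtered.itertuples(index=False):
        for r in cohort.genotypes.carriers_of(int(rec.row)):
            if status.get(ids[r]) == "case":
                out.setdefault(rec.gene, set()).add(ids[r])
    return out


def _write_outputs(config: RunConfig, out: dict):
    os.makedirs(config.output_dir, exist_ok=True)
    cfg_dict = config.to_dict()
    hashed = {k: v for k, v in cfg_dict.items() if k != "output_dir"}
    cfg_json = json.dumps(hashed, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]

    def _save(df: pd.DataFrame, name: str):
        path = os.path.join(config.output_dir, name)
        with open(path, "w") as fh:
            fh.write(f"# config_hash={cfg_hash}\n")
            if isinstance(df, pd.DataFrame) and df.attrs.get("thresholds"):
                fh.write(f"# thresholds={json.dumps(df.attrs['thresholds'], sort_keys=True)}\n")
            df.to_csv(fh, sep="\t", index=False)

    _save(out["qc"], "qc_decisions.tsv")
    _save(out["ancestry"], "ancestry.tsv")
    _save(out["kinship"].loc[out["kinship"]["kinship"] >= 0.02], "kinship.tsv")
    _save(out["cascade"], "filter_decisions.tsv")
    for name, table in out["results"].items():
        _save(table, f"results_{name}.tsv")
    for name, table in out["manhattan"].items():
        _save(table, f"manhattan_{name}.tsv")
    _save(out["summary"].rows, "carrier_fractions.tsv")
    manifest = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "log": [json.loads(entry) for entry in out["log"]],
        "versions": _versions(),
    }
    with open(os.path.join(config.output_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _versions() -> dict:
    import importlib.metadata as md

    out = {}
    for pkg in ("pahscan", "numpy", "scipy", "pandas", "statsmodels", "networkx"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
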