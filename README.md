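# pahscan

Rare-variant case-control gene discovery for whole-genome-sequenced disease
cohorts, built around the analysis design used for pulmonary arterial
hypertension (PAH): a rare disease in which heterozygous loss-of-function
variation in BMP-pathway genes (most prominently *BMPR2*) explains only part
of the heritability, so discovery proceeds by comparing rare, predicted
deleterious coding variation between ~10³ cases and ~10³–10⁴ rare-disease
controls, gene by gene.

The package is aimed at statistical geneticists who want the whole chain —
from a multi-sample VCF with annotations to gene-level association tables —
as tested, composable Python, plus a synthetic-cohort generator so every
stage can be validated end-to-end without access to managed patient data.

## What it computes

* **Variant QC** — the overall pass rate OPR = pass frequency × call rate;
  variants with OPR ≥ 0.80 are retained.
* **Ancestry & relatedness** — marker-SNP selection (MAF ≥ 0.3, sliding-window
  VIF ≤ 2 pruning), reference-panel PCA with projection of study samples,
  per-population multivariate-Gaussian assignment (ambiguous samples →
  "other"), KING-robust kinship
  φ̂ = (N₁₁ − 2·N₀₂)/(Nₕᵉᵗ(i) + Nₕᵉᵗ(j)), family networks as connected
  components at φ̂ ≥ 0.0442, and a maximum unrelated sample set (exact
  maximum independent set on small components).
* **Cohort frequencies** — folded MAF per analysis subset (unrelated
  controls, all affected, unrelated index cases), with missing genotypes out
  of the denominator and single-allele male X genotypes.
* **Filtering cascade** — (1) MAF < 1e-4 in internal controls and every
  external reference (1/8000 on X); (2) CADD ≥ 15 (missing scores pend);
  (3) PTV or missense on the canonical transcript; (4) missense that is both
  SIFT-tolerated and PolyPhen-benign is removed. Plus likely-causative
  curation (control-shared variants, co-occurrence with known causal hits,
  family segregation).
* **Burden tests** — per-gene carrier collapse without double counting
  (dominant PTV / missense / combined modes and a biallelic recessive mode),
  one-tailed Fisher's exact test p = P(X ≥ a | margins) with Bonferroni
  correction, and re-runs after excluding carriers in previously reported
  disease genes.
* **SKAT-O** — logistic null model with covariates (read-length batch, sex,
  leading PCs), Beta(1,25) MAF weights, the statistic family
  Q<sub>ρ</sub> = (1−ρ) Σⱼ (wⱼSⱼ)² + ρ (Σⱼ wⱼSⱼ)² over the standard ρ grid,
  per-ρ p-values from mixture-of-chi-square tails (Imhof inversion with
  saddlepoint/Liu fallbacks), the min-p combination by one-dimensional
  integration, and a seeded permutation-calibrated p-value path for small
  cohorts.
* **Deletion consensus burden** — two-caller reciprocal-overlap (≥ 0.20)
  consensus per sample, benign-region exclusion, cross-sample single-linkage
  merging at RO ≥ 0.50, frequency (< 1/1000) and exon-overlap filters, and
  gene-level deletion burden tests.
* **Synthetic cohorts** — seeded generation of the full input bundle
  (genotype VCF, annotation TSV, sample sheet, gene/exon models, two noisy
  deletion call sets, labelled reference panel) with planted causal genes,
  Mendelian pedigrees and Balding–Nichols population structure.

## Worked example

Generate a scaled cohort (500 cases / 3000 controls, 100 genes) with one
planted causal gene at 4% case and 0.02% control carrier frequency, then run
the burden and SKAT-O scans:

```python
from pahscan.synthetic import CohortConfig, PlantedGene, generate_cohort
from pahscan.experiments import scan_cohort

cfg = CohortConfig(
    n_cases=500, n_controls=3000, n_genes=100,
    planted_genes=(PlantedGene("GENE_X", case_carrier_freq=0.04,
                               control_carrier_freq=2e-4),),
    seed=7,
)
cohort = generate_cohort(cfg)
res = scan_cohort(cohort, modes=("combined",), run_skat=True)
print(res["burden"].sort_values("p_raw").head(2)[
    ["gene", "case_carriers", "control_carriers", "p_raw", "p_adjusted"]
].to_string(index=False))
print(res["skato"].sort_values("p_skato").head(2)[
    ["gene", "n_variants", "p_skat", "p_burden", "p_skato", "p_adjusted"]
].to_string(index=False))
```

```
  gene  case_carriers  control_carriers        p_raw   p_adjusted
GENE_X             16                 0 2.443536e-14 2.443536e-12

  gene  n_variants       p_skat     p_burden      p_skato   p_adjusted
GENE_X           7 3.625248e-15 9.197872e-23 7.358298e-22 7.358298e-20
```

Sixteen of the ~20 planted case carriers survive the filtering cascade
(carriers whose variant also acquires a control carrier are removed by the
strict internal MAF < 1e-4 rule); with zero control carriers the one-tailed
Fisher p is ~2e-14 and the gene stays genome-wide significant after
Bonferroni over the 100-gene model (`p_adjusted`). SKAT-O concentrates the
same signal through its weighted burden component (its `p_burden`, the
ρ = 1 member of the statistic family, drives the combined p), and no
background gene reaches the table at all in this draw — ultra-rare
background variants rarely leave a case-only carrier behind the cascade.

The same analysis is available from the shell:

```bash
pahscan simulate --output-dir cohort/ --seed 7 --cases 500 --controls 3000
pahscan all --input-dir cohort/ --output-dir run/
```

which writes per-stage TSVs (QC decisions, ancestry and kinship tables,
filter decisions, per-gene results, Manhattan plot tables, carrier-fraction
summaries) plus a `run_manifest.json` with configuration, seeds and a config
hash.

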