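# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic cohorts do and do not emulate, and the numerical
choices that matter. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Analysis model

The pipeline implements gene-level case-control discovery for rare,
predicted-deleterious coding variation:

1. **Variant QC.** Each variant carries a pass frequency (fraction of
   alternate-allele samples whose original call passed filtering) and a call
   rate (fraction of samples with a called genotype). Their product, the
   overall pass rate (OPR), must be ≥ 0.80; the comparison is an exact ≥ on
   unrounded floats. A variant with no alternate carriers has no defined
   pass-frequency denominator and is assigned pass frequency 1.0 (vacuously
   passing), flagged in the decision log.

2. **Ancestry and relatedness.** Marker SNPs are common (MAF ≥ 0.3),
   complete, and LD-pruned with sliding windows of 50 variants shifting by 5
   at a variance-inflation-factor threshold of 2 (windows are counted in
   variants, the semantics of the pruning tool the window sizes come from).
   PCA is fitted on a labelled reference panel only; study genotypes are
   standardised with the *reference* means/scales and projected onto the
   reference loadings, never refitted. Each population's scores on the
   leading 5 PCs are modelled as a multivariate Gaussian; a sample takes the
   maximum-likelihood label unless the top two log-likelihoods differ by
   less than 4.6 nats (likelihood ratio 100), in which case it is "other".
   The margin is configurable; 4.6 is a conventional strong-evidence cut
   and is recorded in run metadata.

   Kinship uses the KING-robust within-cohort estimator
   φ̂ = (N_het,het − 2·N_opposite-hom) / (N_het(i) + N_het(j)).
   This is a deliberate substitution for the PC-based relatedness estimator
   used by the original workflow: the downstream contract depends only on
   thresholded kinship, KING-robust needs no ancestry adjustment at the
   divergence levels simulated, and self/parent-offspring/unrelated levels
   (≈ 0.5 / 0.25 / 0) are recovered within sampling error (tested). The
   relatedness threshold is 0.0442 (3rd-degree cutoff, standard choice).
   Family networks are connected components of the thresholded graph; the
   maximum unrelated set is solved exactly (branch-and-bound maximum clique
   on the complement) for components of ≤ 15 samples and by minimum-degree
   greedy above — the cutoff is configurable, and exactness on small
   components is verified against subset enumeration.

3. **Subset frequencies.** Internal MAFs are computed on the unrelated
   controls (the filter reference), on all affected cases, and on unrelated
   index cases (one per family network). Missing genotypes leave the
   denominator; called male X genotypes contribute one allele; frequencies
   are folded to the minor allele. Sites with no called genotype in a
   subset get an undefined MAF and are flagged, never dropped.

4. **Filtering cascade.** Four rules evaluated exhaustively (no
   short-circuit) so every decision is auditable: rarity (MAF < 1e-4,
   strict, in internal controls and in every external reference set, with
   1/8000 on the X chromosome applied uniformly to internal and external
   frequencies — the source protocol does not say whether the X adjustment
   covers external references; uniformity is the simpler reading);
   CADD ≥ 15 (boundary passes; missing scores go to a pending list,
   mirroring the protocol of scoring unscored variants before use);
   PTV-or-missense on the canonical transcript; and removal of missense
   that both SIFT calls tolerated and PolyPhen calls benign (a missing
   prediction cannot satisfy the conjunction, so it passes). Curation of
   likely-causative variants removes control-shared variants, variants of
   uncertain significance (operationalised as missense not previously
   reported causal) co-occurring in a sample with a known-gene variant or a
   high-impact PTV, and variants failing supplied family segregation.

5. **Burden tests.** Carriers collapse per gene and mode without double
   counting; the biallelic mode requires ≥ 2 qualifying alleles
   (homozygotes count 2; a hemizygous male X genotype acts as
   biallelic-equivalent). The test is the one-tailed (greater) Fisher exact
   test — the upper hypergeometric tail given the margins — with Bonferroni
   correction. The Bonferroni denominator defaults to the number of genes
   in the supplied gene model (the "genome-wide significance" convention);
   the carriers-only denominator remains available
   (`m_convention="tested"`) and both values are written per row. The
   genome-wide default matters at scaled cohort sizes: with 3000 controls
   the internal MAF < 1e-4 rule can only retain variants with zero control
   carriers (one control allele is already 1/6000), a selection that makes
   tiny tested-gene counts anti-conservative for the asymptotic SKAT-O
   null; correcting over the whole gene model keeps both scans inside
   their family-wise error budget, and this is verified by simulation in
   the acceptance suite.

6. **SKAT-O.** Logistic null model fitted by IRLS to tolerance 1e-8 with
   intercept, read-length batch (two-level indicator for 100 bp vs 150 bp
   libraries), sex, and the leading 5 ancestry PCs when the full pipeline
   runs. With per-variant scores S = Gᵀ(y − μ̂) and Beta(1,25) weights
   evaluated at the sample MAF,
   Q_ρ = (1−ρ)Σ(wⱼSⱼ)² + ρ(ΣwⱼSⱼ)², over the grid
   ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}. Per-ρ null distributions
   are chi-square mixtures with eigenvalues of
   R_ρ^½ W (GᵀPG) W R_ρ^½, P the null-model projection. The combined p
   takes the minimum per-ρ p and corrects for the grid search by
   integrating the joint null over the shared burden chi-square (quantiles
   of each Q_ρ at the minimum p via Liu moment matching; the remainder
   mixture via vectorised Imhof inversion with a variance adjustment for
   the neglected cross term; Gauss–Legendre after the x = t² substitution
   that removes the χ²₁ density singularity). The result is clamped into
   [min-p, grid-size × min-p], the structural bounds of the construction.

   *Accuracy.* The per-ρ mixture tails agree with Monte Carlo of the
   asymptotic Gaussian null to within Monte-Carlo error (tested). The
   published min-p integration itself carries ~1–2% absolute error even
   under its own asymptotic null, and for binary traits at n ≈ 200 the
   asymptotic null deviates from the exact permutation distribution by up
   to several percent (sparse carrier counts are far from Gaussian). The
   package therefore provides `skat_o_resampling_pvalue`, a seeded
   residual-permutation calibration of the min-p statistic (per-ρ p-values
   and the final p are permutation ranks), recommended for cohorts up to a
   few thousand samples when individual p-values matter; the asymptotic
   path is the default for scans, where n is large and ranking/thresholding
   behaviour is what counts. The suite checks the resampling path against
   an independently coded phenotype-label permutation oracle; oracle
   fixtures use intercept-only nulls because label permutation with a
   refitted covariate null is a genuinely different null scheme from
   residual permutation at finite n.

   The mixture engine (`pahscan.quadform`) uses an exact chi-square closed
   form when eigenvalues are numerically equal, Imhof characteristic-
   function inversion (scipy adaptive quadrature, truncation point from an
   alternating-series envelope bound) at configurable absolute accuracy,
   the Kuonen saddlepoint for the far tail (where absolute-accuracy
   inversion returns noise), and Liu's skewness-corrected moment matching
   as the final fallback; every result records which method ran.
   Eigenvalues below 1e-10 of the largest are truncated.

7. **Deletions.** Calls from two callers intersect per sample at reciprocal
   overlap ≥ 0.20 (RO = overlap divided by the longer-of-the-two
   normalisations, min of the two fractions); pairs where both members fail
   caller QC are dropped; the representative interval is the union of the
   pair (conservative for exon annotation — the protocol is silent here).
   Benign-region exclusion reuses the RO ≥ 0.20 criterion (configurable to
   any-overlap). Cross-sample merging is single-linkage at RO ≥ 0.50
   (clusters report min/max member coordinates); merged events must have
   cohort carrier frequency strictly below 1/1000 and intersect at least
   one exon. Gene-level deletion burden reuses the Fisher/Bonferroni
   machinery, with an optional re-run after removing carriers of deletions
   over a named dominant locus. All intervals are 0-based half-open.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
sequencing itself. Defaults are the scaled study conditions used throughout
the validation suite: 500 cases / 3000 controls (a ~1:6 case:control ratio
as in the source cohort, scaled to desktop runtimes), 100 genes (1000 in
the null-calibration runs) of 8 exons each on a toy genome of four
autosomes plus an X, and about 8 variants per gene (Poisson).

Key generator choices, fixed a priori:

* **Background qualifying variants** have per-sample carrier frequency
  1e-5. Rationale: variants that can survive an internal MAF < 1e-4 filter
  have expected cohort carrier counts below ~0.7 at n = 3500, i.e. they are
  dominated by singletons; 1e-5 puts the per-variant expected carrier count
  at 0.035 and the per-gene qualifying carrier count at the sub-one level
  that the post-filter world of the real analysis occupies. A configurable
  slice (15%) of variants is common (carrier frequency 0.5–5%) so the
  rarity rule is genuinely exercised, and 5% of rare variants carry a
  common external-reference frequency so the external rule fires too.
* **Scores.** CADD is drawn from N(27, 5) for latently deleterious variants
  and N(7, 4.5) for benign ones (clipped at 0), giving genuine overlap at
  the 15 threshold; SIFT/PolyPhen labels are drawn conditional on the same
  latent pathogenicity with 10–15% discordance and a small missing rate.
  Only threshold-crossing behaviour matters downstream, so only it is
  calibrated.
* **Planted genes** realise configured case/control carrier frequencies by
  assigning each carrier one of ~10 qualifying variant slots (rare,
  damaging, canonical, external MAF 0; QC good — planted carrier
  frequencies are post-QC conditions). Planted case carriers whose variant
  also acquires a control carrier are subsequently removed by the strict
  internal-MAF rule; this attenuation is part of the emulated design, not
  a bug.
* **Pedigrees** (trio, sib pair, avuncular) are built from explicit founder
  draws and Mendelian transmission, including X-chromosome rules; latent
  (unsequenced) founders exist where templates need them, and each family
  shares one family-private qualifying variant in the first planted gene
  when both pedigrees and planted genes are configured.
* **Population structure** uses the Balding–Nichols model: per-population
  panel allele frequencies drawn around shared ancestral frequencies with
  divergence (F_ST) 0.15 by default. PC-space separation is emergent and
  measured (the acceptance suite requires ≥ 6 SD between population means);
  background rare variants are *not* stratified by population, so scans on
  generated cohorts are valid without PC covariates — the full pipeline
  still fits and uses them.
* **Marker panel**: 10,000 SNPs by default. At this size the KING-robust
  kinship noise SD is ≈ 0.009, far enough below the 0.0442 threshold that
  spurious relatedness edges are negligible at cohort scale (at 2,000 SNPs
  the pair false-positive rate is ~1%, which visibly corrupts family
  networks — measured during development).
* **Deletions** derive from one shared truth set (planted recurrent events
  over configured genes, benign common regions, rare random events) with
  per-caller breakpoint jitter (±300 bp / ±30 bp), 10% false-negative
  rates, Poisson false positives and a 5% QC-fail rate.

What the generator does **not** emulate: linkage disequilibrium among rare
variants, mutation-rate heterogeneity along genes, sequencing reads,
population-stratified rare-variant sharing, duplications/inversions, and
pseudo-autosomal X regions. Passing tests therefore demonstrate the
correctness and calibration of the analysis machinery under the assumed
statistical structure, not robustness to confounding patterns absent from
that structure.

## Problem sizes in the validation suite

Null calibration runs 20 seeded null cohorts of 500/3000 with 1000 genes;
planted-gene recovery runs 20 seeds of 500/3000 with 100 genes and a gene
at 4% vs 0.02% carrier frequency; the permutation-oracle comparison uses 20
fixtures of 200 samples and 5–15 variants against a 100,000-permutation
oracle (the implementation path uses 800,000 resamples so its own Monte
Carlo noise is small against the oracle's); the Fisher oracle covers all
2×2 tables with margins ≤ 12 exhaustively plus 2000 random tables with
margins ≤ 200; the mixture engine is checked against 10⁶-draw Monte Carlo
tails. These sizes keep the full suite within minutes on one core.

## Known limitations

* The asymptotic SKAT-O p is the published approximation; its min-p
  combination step is accurate to ~1–2% absolute in the moderate-p range.
  Use the resampling path when exact small-cohort p-values matter.
* Kinship is KING-robust, not a PC-adjusted estimator; under strong recent
  admixture the two can disagree near the 3rd-degree threshold.
* The curation step's "uncertain significance" is a structural proxy
  (missense outside the known-gene list), not a clinical classification.
* Deletion consensus consumes caller QC as a boolean; no re-derivation of
  caller-internal quality metrics is attempted.
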