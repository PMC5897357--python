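"""The synthetic-cohort generator: determinism, planted effects, pedigrees."""

import hashlib
import os

import numpy as np
import pytest
from scipy.stats import binom

from pahscan.synthetic import (
    CohortConfig,
    ConfigError,
    PedigreeSpec,
    PlantedGene,
    PopulationSpec,
    generate_cohort,
    generate_null_cohort,
    read_bundle,
    write_bundle,
)

SMALL = dict(n_genes=10, n_panel_snps=100, n_reference_per_pop=10)


def _hashes(outdir):
    return {f: hashlib.sha256(open(os.path.join(outdir, f), "rb").read()).hexdigest()
            for f in sorted(os.listdir(outdir))}


def test_identical_seed_gives_identical_files(tmp_path):
    cfg = CohortConfig(n_cases=20, n_controls=50, seed=3, **SMALL)
    write_bundle(generate_cohort(cfg), tmp_path / "a")
    write_bundle(generate_cohort(cfg), tmp_path / "b")
    assert _hashes(tmp_path / "a") == _hashes(tmp_path / "b")


def test_different_seeds_differ():
    a = generate_cohort(CohortConfig(n_cases=20, n_controls=50, seed=7, **SMALL))
    b = generate_cohort(CohortConfig(n_cases=20, n_controls=50, seed=8, **SMALL))
    assert not np.array_equal(a.variants["pos"].to_numpy(),
                              b.variants["pos"].to_numpy())


def test_planted_carrier_counts_within_binomial_band():
    cfg = CohortConfig(
        n_cases=500, n_controls=3000,
        planted_genes=(PlantedGene("PG", 0.05, 0.0005),),
        seed=1, **SMALL)
    co = generate_cohort(cfg)
    realised = len(co.truth["variants"]["planted"]["PG"]["case_carriers"])
    lo, hi = binom.ppf([0.005, 0.995], 500, 0.05)
    assert lo <= realised <= hi


def test_trio_offspring_mendelian_consistent():
    cfg = CohortConfig(n_cases=20, n_controls=50, seed=5,
                       pedigrees=(PedigreeSpec("trio", 2),),
                       planted_genes=(PlantedGene("PG", 0.2, 0.01),),
                       **SMALL)
    co = generate_cohort(cfg)
    sidx = {s: i for i, s in enumerate(co.genotypes.sample_ids)}
    sex = co.samples.set_index("sample_id")["sex"]
    for child, fa, mo in co.truth["transmissions"]:
        if not all(x in sidx for x in (child, fa, mo)):
            continue
        g = co.genotypes.dense(rows=[sidx[child], sidx[fa], sidx[mo]],
                               missing_as=np.nan)
        for j in range(g.shape[1]):
            c, f, m = g[:, j]
            if np.isnan([c, f, m]).any():
                continue
            if co.variants["is_x"].iloc[j]:
                mo_alleles = {0} if m == 0 else ({1} if m == 2 else {0, 1})
                if sex[child] == "male":
                    assert c in mo_alleles
                else:
                    fa_allele = 1 if f > 0 else 0
                    assert c in {fa_allele + a for a in mo_alleles}
            else:
                fa_alleles = {0} if f == 0 else ({1} if f == 2 else {0, 1})
                mo_alleles = {0} if m == 0 else ({1} if m == 2 else {0, 1})
                assert c in {a + b for a in fa_alleles for b in mo_alleles}
        # panel SNPs transmit too
        pc, pf, pm = (co.panel[sidx[x]] for x in (child, fa, mo))
        assert np.all(pc <= pf // 2 + (pf == 1) + pm // 2 + (pm == 1))
        assert np.all(pc >= pf // 2 + pm // 2)


def test_annotation_completeness():
    co = generate_cohort(CohortConfig(n_cases=20, n_controls=50, seed=2, **SMALL))
    v = co.variants
    for col in ("pass_frequency", "call_rate", "consequence", "canonical",
                "maf_ext1", "maf_ext2", "sift", "polyphen"):
        assert col in v.columns and not v[col].isna().any() or col == "cadd"
    assert v["cadd"].isna().mean() < 0.2
    assert set(v["consequence"]) <= {"ptv", "missense", "synonymous", "other"}


def test_invalid_configs_name_the_field():
    with pytest.raises(ConfigError, match="n_cases"):
        generate_cohort(CohortConfig(n_cases=0))
    with pytest.raises(ConfigError, match="populations"):
        generate_cohort(CohortConfig(populations=(PopulationSpec("A", 0.7),)))
    with pytest.raises(ConfigError, match="planted_genes"):
        generate_cohort(CohortConfig(planted_genes=(PlantedGene("X", 1.5, 0.0),)))


def test_null_cohort_rejects_planted_genes():
    with pytest.raises(ConfigError, match="planted_genes"):
        generate_null_cohort(CohortConfig(
            planted_genes=(PlantedGene("X", 0.1, 0.1),)))


def test_bundle_round_trip_lossless(tmp_path, small_cohort):
    write_bundle(small_cohort, tmp_path / "bundle")
    back = read_bundle(tmp_path / "bundle")
    assert (back.genotypes.dosage != small_cohort.genotypes.dosage).nnz == 0
    assert (back.genotypes.missing != small_cohort.genotypes.missing).nnz == 0
    assert np.array_equal(back.panel, small_cohort.panel)
    assert np.array_equal(back.reference, small_cohort.reference)
    assert back.reference_labels == small_cohort.reference_labels
    assert list(back.samples["sample_id"]) == list(small_cohort.samples["sample_id"])
    assert len(back.deletions) == len(small_cohort.deletions)
    assert np.allclose(back.variants["cadd"].fillna(-1),
                       small_cohort.variants["cadd"].fillna(-1))


def test_deletion_calls_derive_from_shared_truth(small_cohort):
    co = small_cohort
    truth = co.truth["deletions"]
    jitter = dict(co.config.deletion_model.jitter_bp)
    for rec in co.deletions.itertuples(index=False):
        near = [t for t in truth
                if t["chrom"] == rec.chrom
                and abs(t["start"] - rec.start) <= jitter[rec.caller]
                and abs(t["end"] - rec.end) <= jitter[rec.caller]
                and rec.sample in t["carriers"]]
        if not near:
            # must be a configured false positive: not near any truth event
            assert all(rec.sample not in t["carriers"]
                       or abs(t["start"] - rec.start) > jitter[rec.caller]
                       for t in truth)
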