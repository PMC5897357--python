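"""Carrier collapsing, one-tailed Fisher tests, Bonferroni, known-gene exclusion."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from pahscan.burden import (
    CarrierTable,
    bonferroni,
    collapse_carriers,
    exclude_known_gene_carriers,
    fisher_one_tailed,
    run_burden_scan,
)
from pahscan.genotypes import GenotypeMatrix


def exact_fisher_upper_tail(a, b, c, d):
    """Independent oracle: exact integer-arithmetic hypergeometric tail."""
    n = a + b + c + d
    k_total = a + c
    row1 = a + b
    num = sum(comb(row1, k) * comb(n - row1, k_total - k)
              for k in range(a, min(k_total, row1) + 1)
              if 0 <= k_total - k <= n - row1)
    return num / comb(n, k_total)


def test_fisher_matches_exact_enumeration_spot():
    t = CarrierTable("g", "ptv", 3, 7, 1, 99)
    assert fisher_one_tailed(t) == pytest.approx(
        exact_fisher_upper_tail(3, 7, 1, 99), rel=1e-12)


def test_fisher_zero_case_carriers_is_one():
    assert fisher_one_tailed(CarrierTable("g", "ptv", 0, 10, 3, 97)) == 1.0


def test_fisher_monotone_in_control_carriers():
    p1 = fisher_one_tailed(CarrierTable("g", "ptv", 4, 96, 2, 398))
    p2 = fisher_one_tailed(CarrierTable("g", "ptv", 4, 96, 4, 396))
    assert p2 > p1


def test_fisher_random_tables_vs_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        r1, r2 = rng.integers(1, 201, size=2)
        a = int(rng.integers(0, r1 + 1))
        c = int(rng.integers(0, r2 + 1))
        t = CarrierTable("g", "ptv", a, int(r1) - a, c, int(r2) - c)
        expect = exact_fisher_upper_tail(a, r1 - a, c, r2 - c)
        assert fisher_one_tailed(t) == pytest.approx(expect, rel=1e-12, abs=1e-300)


def test_negative_cell_rejected():
    with pytest.raises(ValueError):
        CarrierTable("g", "ptv", -1, 2, 0, 3)


@pytest.mark.parametrize("p,m,expected", [
    (0.001, 100, 0.1),
    (0.5, 10, 1.0),
    (0.123, 1, 0.123),
])
def test_bonferroni(p, m, expected):
    assert bonferroni([p], m)[0] == pytest.approx(expected)


def test_bonferroni_rejects_bad_m():
    with pytest.raises(ValueError):
        bonferroni([0.1], 0)
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], 1)


def _toy():
    variants = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(4) + 1, "ref": "A", "alt": "T",
        "gene": ["G1", "G1", "G1", "G2"],
        "consequence": ["ptv", "ptv", "missense", "missense"],
        "is_x": False,
        "row": np.arange(4),
    })
    dense = np.array([
        [1, 1, 0, 0],   # case1: two PTVs in G1 -> one carrier
        [0, 0, 1, 0],   # case2: missense in G1
        [2, 0, 0, 0],   # case3: hom PTV in G1 (biallelic)
        [0, 0, 0, 1],   # ctrl1: missense G2
        [0, 0, 0, 0],   # ctrl2
    ], dtype=np.int8)
    g = GenotypeMatrix(sparse.csc_matrix(dense),
                       sample_ids=["case1", "case2", "case3", "ctrl1", "ctrl2"])
    samples = pd.DataFrame({
        "sample_id": g.sample_ids,
        "status": ["case", "case", "case", "control", "control"],
        "sex": ["female"] * 5,
    })
    return variants, g, samples


def test_no_double_counting_and_modes():
    variants, g, samples = _toy()
    ptv = collapse_carriers(variants, g, samples, "ptv")
    assert ptv["G1"].case_carriers == 2          # case1 once despite 2 PTVs
    mis = collapse_carriers(variants, g, samples, "missense")
    assert mis["G1"].case_carriers == 1
    assert mis["G2"].control_carriers == 1
    combined = collapse_carriers(variants, g, samples, "combined")
    assert combined["G1"].case_carriers == 3
    assert combined["G1"].case_noncarriers == 0


def test_biallelic_counts_alleles():
    variants, g, samples = _toy()
    bi = collapse_carriers(variants, g, samples, "biallelic")
    # case1 has 2 het alleles, case3 is hom (2 alleles); case2 has one
    assert bi["G1"].case_carriers == 2


def test_duplicated_variant_rows_do_not_change_carriers():
    variants, g, samples = _toy()
    dup = pd.concat([variants, variants.iloc[[0]]], ignore_index=True)
    base = collapse_carriers(variants, g, samples, "combined")
    dupd = collapse_carriers(dup, g, samples, "combined")
    assert base["G1"].case_carriers == dupd["G1"].case_carriers


def test_known_gene_exclusion():
    variants, g, samples = _toy()
    retained, manifest = exclude_known_gene_carriers(samples, variants, g, ["G1"])
    assert retained == ["ctrl1", "ctrl2"]
    assert set(manifest["sample_id"]) == {"case1", "case2", "case3"}
    # empty list leaves the cohort unchanged
    retained2, m2 = exclude_known_gene_carriers(samples, variants, g, [])
    assert retained2 == list(samples["sample_id"]) and m2.empty
    # unknown symbol warned, not fatal
    _, m3 = exclude_known_gene_carriers(samples, variants, g, ["NOPE"])
    assert m3.attrs["unknown_genes"] == ["NOPE"]


def test_scan_output_shape_and_zero_carrier_genes_absent():
    variants, g, samples = _toy()
    genes = pd.DataFrame({"gene": ["G1", "G2", "G3"], "chrom": "chr1",
                          "start": [0, 100, 200], "end": [50, 150, 250]})
    res = run_burden_scan(variants, g, samples, genes, modes=("combined",))
    assert set(res["gene"]) == {"G1", "G2"}        # G3 has no carriers
    assert (res["m_bonferroni"] == 3).all()        # gene-model convention
    assert (res["p_adjusted"] >= res["p_raw"]).all()
    tested = run_burden_scan(variants, g, samples, genes, modes=("combined",),
                             m_convention="tested")
    assert (tested["m_bonferroni"] == 2).all()


def test_scan_on_planted_cohort_ranks_causal_gene_first(small_cohort):
    from pahscan.experiments import scan_cohort

    res = scan_cohort(small_cohort, modes=("combined",), run_skat=False)
    b = res["burden"].sort_values("p_raw")
    assert b.iloc[0]["gene"] == "CAUSAL1"
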