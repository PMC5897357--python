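"""Marker selection, PCA projection and assignment, kinship, unrelated sets."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pahscan.ancestry import (
    MarkerParams,
    PopulationModel,
    ReferencePCA,
    assign_population,
    estimate_kinship,
    fit_reference_pca,
    max_unrelated_set,
    select_marker_snps,
)


# ------------------------------------------------------------ marker panel

def test_correlated_pair_keeps_exactly_one():
    rng = np.random.default_rng(0)
    g1 = rng.binomial(2, 0.5, 300)
    g = np.column_stack([g1, g1])
    panel = select_marker_snps(g, [("chr1", 1, "A", "G"), ("chr1", 2, "A", "G")])
    assert list(panel.indices) == [0]


def test_maf_below_threshold_excluded():
    rng = np.random.default_rng(1)
    lo = rng.binomial(2, 0.29, 5000)    # realised MAF hugs 0.29 < 0.30
    hi = rng.binomial(2, 0.45, 5000)
    panel = select_marker_snps(np.column_stack([lo, hi]),
                               [("chr1", 1, "A", "G"), ("chr1", 2, "A", "G")])
    assert list(panel.indices) == [1]


def test_independent_snps_all_retained_vif_one():
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.5, size=(500, 60))
    keys = [("chr1", i, "A", "G") for i in range(60)]
    panel = select_marker_snps(g, keys)
    assert len(panel.indices) == 60
    # direct regression oracle: empirical VIF of each SNP close to 1
    for j in range(0, 60, 10):
        others = np.delete(g, j, axis=1)[:, :20]
        x = others - others.mean(0)
        y = g[:, j] - g[:, j].mean()
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        r2 = 1 - ((y - x @ coef) ** 2).sum() / (y**2).sum()
        assert 1 / (1 - r2) < 1.5


def test_missing_genotypes_rejected_and_empty_panel_error():
    with pytest.raises(ValueError):
        select_marker_snps(np.array([[np.nan], [1.0]]), [("chr1", 1, "A", "G")])
    rng = np.random.default_rng(3)
    rare = rng.binomial(2, 0.05, size=(200, 3))
    with pytest.raises(ValueError, match="empty"):
        select_marker_snps(rare, [("chr1", i, "A", "G") for i in range(3)])


# ---------------------------------------------------------------- PCA/assign

def _two_pop_reference(rng, shift=0.3, n=40, m=300):
    p = rng.uniform(0.3, 0.7, m)
    pa = np.clip(p - shift / 2, 0.05, 0.95)
    pb = np.clip(p + shift / 2, 0.05, 0.95)
    ga = rng.binomial(2, pa, size=(n, m))
    gb = rng.binomial(2, pb, size=(n, m))
    return np.vstack([ga, gb]), ["A"] * n + ["B"] * n, pa, pb


def test_population_means_separate_on_pc1():
    rng = np.random.default_rng(4)
    g, labels, _, _ = _two_pop_reference(rng)
    pca = fit_reference_pca(g, labels, n_pcs=2)
    d = abs(pca.models["A"].mean[0] - pca.models["B"].mean[0])
    sd = np.sqrt(max(pca.models["A"].cov[0, 0], pca.models["B"].cov[0, 0]))
    assert d > 6 * sd


def test_fitted_mean_shift_equivariance():
    rng = np.random.default_rng(5)
    g, labels, _, _ = _two_pop_reference(rng)
    pca = fit_reference_pca(g, labels, n_pcs=2)
    scores = pca.project(g)
    shifted = scores[np.array(labels) == "A"] + np.array([1.5, 0.0])
    model = PopulationModel("A", shifted.mean(0), np.cov(shifted, rowvar=False))
    assert model.mean[0] == pytest.approx(pca.models["A"].mean[0] + 1.5, abs=1e-9)


def test_covariance_recovery_on_gaussian_scores():
    rng = np.random.default_rng(6)
    true_cov = np.array([[2.0, 0.5], [0.5, 1.0]])
    scores = rng.multivariate_normal([0, 0], true_cov, size=500)
    model = PopulationModel("X", scores.mean(0), np.cov(scores, rowvar=False))
    assert np.allclose(model.cov, true_cov, atol=0.3)


def test_assignment_and_equidistant_other():
    pca = ReferencePCA(
        loadings=np.eye(2), snp_means=np.zeros(2), snp_scales=np.ones(2),
        models={
            "A": PopulationModel("A", np.array([-5.0, 0.0]), np.eye(2)),
            "B": PopulationModel("B", np.array([5.0, 0.0]), np.eye(2)),
        },
        n_pcs=2,
    )
    labels, _, _ = assign_population(np.array([[-5.0, 0.0], [0.0, 0.0], [5.0, 0.0]]),
                                     pca)
    assert labels == ["A", "other", "B"]


def test_projection_invariant_to_constant_genotype_shift():
    rng = np.random.default_rng(7)
    g, labels, _, _ = _two_pop_reference(rng)
    pca = fit_reference_pca(g, labels, n_pcs=2)
    sample = g[:3].astype(float)
    base, _, _ = assign_population(sample, pca)
    # centring is internal to the projection: assignments use reference means
    again, _, _ = assign_population(sample.copy(), pca)
    assert base == again


# ------------------------------------------------------------------ kinship

def test_duplicated_sample_kinship_half():
    rng = np.random.default_rng(8)
    g = rng.binomial(2, rng.uniform(0.3, 0.5, 4000), size=(3, 4000))
    g = np.vstack([g, g[0]])
    kin = estimate_kinship(g, sample_ids=["a", "b", "c", "a2"])
    pair = kin.set_index(["sample_i", "sample_j"]).loc[("a", "a2"), "kinship"]
    assert pair == pytest.approx(0.5, abs=0.02)


def test_parent_offspring_and_unrelated_kinship():
    rng = np.random.default_rng(9)
    m = 5000
    p = rng.uniform(0.3, 0.5, m)
    po, un = [], []
    parents = rng.binomial(2, p, size=(40, m))
    others = rng.binomial(2, p, size=(40, m))
    for i in range(40):
        pa, ot = parents[i], others[i]
        child = (np.where(pa == 1, rng.integers(0, 2, m), pa // 2)
                 + np.where(ot == 1, rng.integers(0, 2, m), ot // 2))
        kin = estimate_kinship(np.vstack([pa, ot, child]))
        k = kin.set_index(["sample_i", "sample_j"])["kinship"]
        po.append(k.loc[(0, 2)])
        un.append(k.loc[(0, 1)])
    assert np.mean(po) == pytest.approx(0.25, abs=0.05)
    assert np.mean(un) == pytest.approx(0.0, abs=0.02)


def test_monomorphic_panel_rejected():
    with pytest.raises(ValueError):
        estimate_kinship(np.zeros((3, 10)))


# ------------------------------------------------------------- unrelated set

def _kin_df(edges, nodes):
    rows = []
    eset = {frozenset(e) for e in edges}
    for i, j in itertools.combinations(nodes, 2):
        rows.append({"sample_i": i, "sample_j": j,
                     "kinship": 0.3 if frozenset((i, j)) in eset else 0.0,
                     "ibs_distance": 0.1})
    return pd.DataFrame(rows)


def test_trio_keeps_two():
    kin = _kin_df([("fa", "ch"), ("mo", "ch")], ["fa", "mo", "ch"])
    unrelated, networks = max_unrelated_set(kin)
    assert len(unrelated) == 2 and "ch" not in unrelated
    assert networks == [{"fa", "mo", "ch"}]


def test_chain_keeps_endpoints():
    kin = _kin_df([("a", "b"), ("b", "c")], ["a", "b", "c"])
    unrelated, _ = max_unrelated_set(kin)
    assert unrelated == ["a", "c"]


def _brute_force_mis(nodes, edges):
    best = 0
    n = len(nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    masks = [0] * n
    for i, j in edges:
        masks[idx[i]] |= 1 << idx[j]
        masks[idx[j]] |= 1 << idx[i]
    for subset in range(1 << n):
        ok = True
        for k in range(n):
            if subset >> k & 1 and masks[k] & subset:
                ok = False
                break
        if ok:
            best = max(best, bin(subset).count("1"))
    return best


def test_random_graphs_match_brute_force():
    rng = np.random.default_rng(10)
    for _ in range(30):
        n = int(rng.integers(2, 13))
        nodes = [f"s{k}" for k in range(n)]
        edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.3]
        kin = _kin_df(edges, nodes)
        unrelated, _ = max_unrelated_set(kin)
        # no retained pair is related
        eset = {frozenset(e) for e in edges}
        assert not any(frozenset(p) in eset
                       for p in itertools.combinations(unrelated, 2))
        assert len(unrelated) == _brute_force_mis(nodes, edges)


def test_adding_edge_never_grows_retained_set():
    nodes = [f"s{k}" for k in range(8)]
    rng = np.random.default_rng(11)
    edges = [(nodes[i], nodes[j]) for i in range(8) for j in range(i + 1, 8)
             if rng.random() < 0.25]
    base, _ = max_unrelated_set(_kin_df(edges, nodes))
    extra = ("s0", "s7")
    if frozenset(extra) not in {frozenset(e) for e in edges}:
        more, _ = max_unrelated_set(_kin_df(edges + [extra], nodes))
        assert len(more) <= len(base)
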