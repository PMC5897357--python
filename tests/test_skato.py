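"""SKAT / burden-score / SKAT-O statistics, null model and p-values."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

from pahscan.skato import (
    DEFAULT_RHO_GRID,
    beta_weights,
    fit_null,
    skat_o_pvalue,
    skat_o_resampling_pvalue,
    skat_statistics,
    _projected_kernel,
)


def _balanced_fixture(rng, n=200, m=8, maf_lo=0.05, maf_hi=0.35):
    g = rng.binomial(2, rng.uniform(maf_lo, maf_hi, m), size=(n, m)).astype(float)
    y = np.zeros(n)
    y[rng.choice(n, n // 2, replace=False)] = 1
    mafs = g.mean(axis=0) / 2
    keep = (mafs > 0) & (mafs <= 0.5)
    return g[:, keep], mafs[keep], y


# ---------------------------------------------------------------- null model

def test_intercept_only_fit_is_case_fraction():
    y = np.array([1.0] * 20 + [0.0] * 80)
    null = fit_null(y)
    assert np.allclose(null.fitted, 0.2)
    assert abs(null.residuals.sum()) < 1e-8


def test_constant_covariate_rejected():
    y = np.array([0.0, 1.0] * 25)
    with pytest.raises(ValueError, match="column 0"):
        fit_null(y, np.ones((50, 1)))


def test_coefficients_match_direct_likelihood_maximisation():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(50, 2))
    eta = 0.3 + 0.8 * x[:, 0] - 0.5 * x[:, 1]
    y = (rng.random(50) < 1 / (1 + np.exp(-eta))).astype(float)
    null = fit_null(y, x)
    design = np.column_stack([np.ones(50), x])

    def negll(beta):
        z = design @ beta
        return np.sum(np.log1p(np.exp(z)) - y * z)

    opt = minimize(negll, np.zeros(3), method="BFGS", tol=1e-12)
    assert np.allclose(null.coef, opt.x, atol=1e-5)


# ------------------------------------------------------------------- weights

def test_beta_weights_closed_forms():
    assert beta_weights([1e-9])[0] == pytest.approx(25.0, rel=1e-6)
    assert beta_weights([0.5])[0] == pytest.approx(25 * 0.5**24, rel=1e-12)
    w = beta_weights([1e-4, 1e-2])
    assert w[0] > w[1]                       # strictly decreasing
    with pytest.raises(ValueError):
        beta_weights([0.0])


# ---------------------------------------------------------------- statistics

def test_single_variant_gene_q_identical_across_rho():
    rng = np.random.default_rng(3)
    g, mafs, y = _balanced_fixture(rng, m=1)
    null = fit_null(y)
    q = skat_statistics(g, null, beta_weights(mafs))
    vals = list(q.values())
    assert np.allclose(vals, vals[0])


def test_rho_one_equal_weights_is_squared_burden():
    rng = np.random.default_rng(4)
    g, mafs, y = _balanced_fixture(rng, m=5)
    null = fit_null(y)
    w = np.ones(g.shape[1])
    q = skat_statistics(g, null, w, rho_grid=(1.0,))
    burden = g.sum(axis=1) @ null.residuals
    assert q[1.0] == pytest.approx(burden**2, rel=1e-12)


def test_q0_matches_matrix_form_oracle():
    rng = np.random.default_rng(5)
    g, mafs, y = _balanced_fixture(rng, m=5)
    null = fit_null(y)
    w = beta_weights(mafs)
    q = skat_statistics(g, null, w, rho_grid=(0.0,))
    s = g.T @ null.residuals
    oracle = float(s @ np.diag(w**2) @ s)     # S' W^2 S
    assert q[0.0] == pytest.approx(oracle, rel=1e-12)


def test_statistics_invariant_to_column_order():
    rng = np.random.default_rng(6)
    g, mafs, y = _balanced_fixture(rng, m=7)
    null = fit_null(y)
    perm = rng.permutation(g.shape[1])
    r1 = skat_o_pvalue(g, null, mafs=mafs)
    r2 = skat_o_pvalue(g[:, perm], null, mafs=mafs[perm])
    assert r1.p_skato == pytest.approx(r2.p_skato, rel=1e-9)


# ------------------------------------------------------------------ p-values

def test_single_variant_skato_equals_score_test():
    rng = np.random.default_rng(7)
    g, mafs, y = _balanced_fixture(rng, m=1)
    null = fit_null(y)
    res = skat_o_pvalue(g, null, mafs=mafs)
    w = beta_weights(mafs)
    s = float(w[0] * (g[:, 0] @ null.residuals))
    var = float(w[0]**2 * _projected_kernel(g, null)[0, 0])
    assert res.p_skato == pytest.approx(chi2.sf(s**2 / var, 1), rel=1e-9)
    assert res.p_skat == res.p_burden == res.p_skato


def test_skato_bounded_by_grid_extremes():
    rng = np.random.default_rng(8)
    for _ in range(10):
        g, mafs, y = _balanced_fixture(rng, m=int(rng.integers(2, 12)))
        null = fit_null(y)
        res = skat_o_pvalue(g, null, mafs=mafs)
        pmin = min(res.p_rho.values())
        assert pmin - 1e-12 <= res.p_skato <= min(1.0, pmin * len(DEFAULT_RHO_GRID)) + 1e-12


def test_per_rho_p_matches_gaussian_null_monte_carlo():
    """Eigenvalue machinery against Monte Carlo draws from the asymptotic
    null S ~ N(0, Phi) — validates the per-rho mixture distributions."""
    rng = np.random.default_rng(9)
    g, mafs, y = _balanced_fixture(rng, n=300, m=6)
    null = fit_null(y)
    w = beta_weights(mafs)
    res = skat_o_pvalue(g, null, mafs=mafs)
    phi = _projected_kernel(g, null)
    chol = np.linalg.cholesky(phi + 1e-12 * np.eye(len(mafs)) * phi.max())
    draws = rng.normal(size=(200_000, len(mafs))) @ chol.T
    ws = draws * w
    for rho in (0.0, 0.25, 1.0):
        qb = (1 - rho) * (ws**2).sum(1) + rho * ws.sum(1) ** 2
        q_obs = res.q_rho[rho]
        mc = (qb >= q_obs).mean()
        se = max(np.sqrt(mc * (1 - mc) / draws.shape[0]), 1e-6)
        assert res.p_rho[rho] == pytest.approx(mc, abs=4 * se)


def test_resampling_path_agrees_with_asymptotic_at_moderate_p():
    rng = np.random.default_rng(10)
    g, mafs, y = _balanced_fixture(rng, n=400, m=10, maf_lo=0.1, maf_hi=0.4)
    null = fit_null(y)
    asym = skat_o_pvalue(g, null, mafs=mafs)
    resa = skat_o_resampling_pvalue(g, null, mafs=mafs, n_resamples=50_000, seed=1)
    assert resa.p_skato == pytest.approx(asym.p_skato, abs=0.03)


def test_scan_is_deterministic(small_cohort):
    from pahscan.experiments import scan_cohort

    a = scan_cohort(small_cohort, run_skat=True)["skato"]
    b = scan_cohort(small_cohort, run_skat=True)["skato"]
    assert a.equals(b)
    assert (a["p_skato"] > 0).all() and (a["p_skato"] <= 1).all()
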