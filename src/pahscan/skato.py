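"""Gene-based variance-component association tests: SKAT, burden score, SKAT-O.

The model: for binary phenotype y with logistic null model
``logit P(y=1) = X beta`` (X = intercept, read-length batch, sex, leading
ancestry PCs), the per-variant score is ``S_j = sum_i G_ij (y_i - mu_i)``.
With MAF-based weights ``w_j`` (Beta(1,25) density by default) the family of
statistics

    Q_rho = (1 - rho) * sum_j (w_j S_j)^2 + rho * (sum_j w_j S_j)^2

interpolates between the variance-component (SKAT, rho=0) and squared
weighted burden (rho=1) statistics.  Each Q_rho is asymptotically a mixture
of chi-squares with eigenvalues from the null-projected weighted genotype
kernel; SKAT-O takes the minimum p over a rho grid and corrects for the
search by one-dimensional integration over the shared burden component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from . import quadform

__all__ = [
    "NullModel",
    "SkatResult",
    "fit_null",
    "beta_weights",
    "skat_statistics",
    "pvalue_mixture_chisq",
    "skat_o_pvalue",
    "run_skat_scan",
    "DEFAULT_RHO_GRID",
]

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass
class NullModel:
    """Fitted logistic null model shared by every gene in a scan."""

    phenotype: np.ndarray
    covariates: np.ndarray
    coef: np.ndarray
    fitted: np.ndarray            # mu_i in (0, 1)
    residuals: np.ndarray         # y_i - mu_i
    variance: np.ndarray          # mu_i (1 - mu_i)

    @property
    def n(self) -> int:
        return self.phenotype.size


def fit_null(phenotypes, covariates=None, tol: float = 1e-8) -> NullModel:
    """Fit the logistic null model by IRLS.

    ``covariates`` excludes the intercept, which is always added.  Constant
    or collinear covariate columns and quasi-separation raise with the
    offending column index named.
    """
    y = np.asarray(phenotypes, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("both phenotype classes must be present")
    if covariates is None:
        x = np.ones((y.size, 1))
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != y.size:
            c = c.T
        if c.shape[0] != y.size:
            raise ValueError("covariate matrix does not match phenotype length")
        if np.isnan(c).any():
            raise ValueError("missing values in covariates")
        x = np.column_stack([np.ones(y.size), c])
        for j in range(1, x.shape[1]):
            if np.ptp(x[:, j]) == 0:
                raise ValueError(f"covariate column {j - 1} is constant")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinear columns)")
    model = sm.GLM(y, x, family=sm.families.Binomial())
    res = model.fit(tol=tol, maxiter=200)
    if not res.converged:
        raise RuntimeError("logistic null model did not converge (separation?)")
    mu = np.asarray(res.fittedvalues)
    if mu.min() < 1e-10 or mu.max() > 1 - 1e-10:
        raise RuntimeError("fitted probabilities at the boundary (separation)")
    return NullModel(
        phenotype=y,
        covariates=x,
        coef=np.asarray(res.params),
        fitted=mu,
        residuals=y - mu,
        variance=mu * (1.0 - mu),
    )


def beta_weights(mafs, a1: float = 1.0, a2: float = 25.0) -> np.ndarray:
    """Beta-density variant weights evaluated at the MAF (default Beta(1,25)).

    Strictly decreasing in MAF for a1 <= 1 < a2, so rarer variants are
    up-weighted; the limit at MAF -> 0 is a2 for Beta(1, a2).
    """
    maf = np.asarray(mafs, dtype=float)
    if np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise ValueError("MAFs must be in (0, 0.5]; drop monomorphic variants first")
    return beta_dist.pdf(maf, a1, a2)


def skat_statistics(genotypes, null: NullModel, weights, rho_grid=DEFAULT_RHO_GRID):
    """Per-rho Q statistics for one gene.

    ``genotypes`` is the n x m dosage matrix (0/1/2).  Returns a dict
    ``rho -> Q``.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[0] != null.n:
        raise ValueError("genotype matrix does not match null model sample count")
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != g.shape[1]:
        raise ValueError("weight vector length does not match variant count")
    ws = w * (g.T @ null.residuals)
    sum_sq = float((ws**2).sum())
    sq_sum = float(ws.sum() ** 2)
    return {float(r): (1.0 - r) * sum_sq + r * sq_sum for r in rho_grid}


def pvalue_mixture_chisq(q: float, eigenvalues, accuracy: float = 1e-9):
    """Tail probability of ``sum_k lambda_k chi2_1`` exceeding ``q``.

    Thin wrapper over the quadratic-form engine; returns ``(p, method)``
    where method records whether exact inversion or a fallback produced p.
    """
    res = quadform.mixture_chisq_sf(q, eigenvalues, accuracy=accuracy)
    return res.p, res.method


@dataclass
class SkatResult:
    gene: str
    n_variants: int
    rho_grid: tuple
    q_rho: dict
    p_rho: dict
    p_skat: float          # rho = 0
    p_burden: float        # rho = 1
    p_skato: float
    rho_opt: float
    methods: dict = field(default_factory=dict)


def _projected_kernel(g: np.ndarray, null: NullModel) -> np.ndarray:
    """Phi = G' P G with P = V - V X (X'V X)^-1 X' V (m x m)."""
    v = null.variance
    x = null.covariates
    gv = g * v[:, None]
    gvg = g.T @ gv
    gvx = gv.T @ x
    xvx = x.T @ (x * v[:, None])
    return gvg - gvx @ np.linalg.solve(xvx, gvx.T)


def _rho_eigenvalues(kernel_w: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of R_rho^(1/2) K R_rho^(1/2) with R = (1-rho)I + rho 11'."""
    m = kernel_w.shape[0]
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt(1.0 - rho + rho * m) - a) / m
    ones = np.ones((m, m))
    sqrt_r = a * np.eye(m) + b * ones
    lam = np.linalg.eigvalsh(sqrt_r @ kernel_w @ sqrt_r)
    lam = lam[lam > quadform.TRUNC_TOL * max(lam.max(), 1e-300)]
    return lam


def _tail_sf(q: float, lam: np.ndarray, accuracy: float):
    p, method = pvalue_mixture_chisq(q, lam, accuracy=accuracy)
    # absolute-accuracy inversion is noise below ~10x accuracy: go saddlepoint
    if method == "imhof" and p < 10 * accuracy:
        sp = quadform.saddlepoint_sf(q, lam)
        if np.isfinite(sp) and 0 < sp <= 1:
            return sp, "saddlepoint"
    return p, method


def skat_o_pvalue(
    genotypes,
    null: NullModel,
    weights=None,
    mafs=None,
    rho_grid=DEFAULT_RHO_GRID,
    gene: str = "",
    accuracy: float = 1e-9,
) -> SkatResult:
    """SKAT-O p-value for one gene.

    Supply either explicit ``weights`` or ``mafs`` (Beta(1,25) weights are
    derived from the latter).  The combined p is the minimum-p statistic over
    the rho grid corrected by integrating the joint null over the shared
    burden direction; it is clamped into [min p over grid, grid-size
    Bonferroni of min p], the sanity bounds of the min-p construction.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if weights is None:
        if mafs is None:
            raise ValueError("supply weights or mafs")
        weights = beta_weights(mafs)
    w = np.asarray(weights, dtype=float).ravel()
    m = g.shape[1]
    rho_grid = tuple(float(r) for r in rho_grid)
    q_rho = skat_statistics(g, null, w, rho_grid)

    phi = _projected_kernel(g, null)
    kernel_w = (w[:, None] * phi) * w[None, :]

    if m == 1:
        # every rho coincides with the single-variant score test
        lam = np.linalg.eigvalsh(kernel_w)[-1:]
        p, method = _tail_sf(q_rho[rho_grid[0]], lam, accuracy)
        p_rho = {r: p for r in rho_grid}
        return SkatResult(
            gene=gene, n_variants=m, rho_grid=rho_grid, q_rho=q_rho, p_rho=p_rho,
            p_skat=p, p_burden=p, p_skato=p, rho_opt=rho_grid[0],
            methods={r: method for r in rho_grid},
        )

    p_rho, methods, lam_rho = {}, {}, {}
    for r in rho_grid:
        lam = _rho_eigenvalues(kernel_w, r)
        lam_rho[r] = lam
        p_rho[r], methods[r] = _tail_sf(q_rho[r], lam, accuracy)

    pmin = min(p_rho.values())
    rho_opt = min(p_rho, key=p_rho.get)
    p_skato = _skato_min_p(kernel_w, p_rho, lam_rho, pmin, rho_grid, accuracy)
    # sanity bounds of the min-p construction
    p_skato = float(np.clip(p_skato, pmin, min(1.0, pmin * len(rho_grid))))
    return SkatResult(
        gene=gene, n_variants=m, rho_grid=rho_grid, q_rho=q_rho, p_rho=p_rho,
        p_skat=p_rho.get(0.0, np.nan), p_burden=p_rho.get(1.0, np.nan),
        p_skato=p_skato, rho_opt=rho_opt, methods=methods,
    )


def _skato_min_p(kernel_w, p_rho, lam_rho, pmin, rho_grid, accuracy) -> float:
    """Correct the minimum per-rho p for the grid search.

    Decomposes the weighted projected kernel into the burden direction plus
    an orthogonal remainder; conditional on the burden chi-square x, each
    Q_rho threshold becomes linear in x and the joint survivor probability is
    a one-dimensional integral over x (the construction of the optimal
    unified test).  The remainder mixture is evaluated by vectorised Imhof
    inversion with a moment correction for the neglected cross-variance.
    """
    m = kernel_w.shape[0]
    ones = np.ones(m)
    k1 = kernel_w @ ones
    zbar2 = float(ones @ k1) / m**2        # |zbar|^2
    if zbar2 <= 0:
        return pmin * len(rho_grid)
    cof = k1 / m / zbar2                   # projection coefficients on zbar
    a2 = kernel_w - zbar2 * np.outer(cof, cof)   # orthogonal remainder kernel
    lam = np.linalg.eigvalsh(a2)
    lam = lam[lam > quadform.TRUNC_TOL * max(lam.max(), 1e-300)]
    if lam.size == 0:
        return pmin * len(rho_grid)
    mu_q = lam.sum()
    var_q = 2.0 * (lam**2).sum() + 4.0 * zbar2 * float(cof @ a2 @ cof)
    var_remain = 4.0 * zbar2 * float(cof @ a2 @ cof)
    sd_ratio = np.sqrt(max(var_q - var_remain, 0.0) / var_q) if var_q > 0 else 1.0

    rr = np.array([min(r, 0.999) for r in rho_grid])
    tau = zbar2 * (m**2 * rr + (1.0 - rr) * float((cof**2).sum()))
    q_pmin = np.array([quadform.liu_quantile(pmin, lam_rho[r]) for r in rho_grid])

    # integrate over x = chi2_1 via x = t^2 (removes the density singularity)
    t_nodes, t_weights = np.polynomial.legendre.leggauss(192)
    t_hi = np.sqrt(60.0)
    t = 0.5 * t_hi * (t_nodes + 1.0)
    wt = 0.5 * t_hi * t_weights
    x = t**2
    qmin_x = np.min((q_pmin[:, None] - tau[:, None] * x[None, :]) / (1.0 - rr[:, None]), axis=0)
    q_std = (qmin_x - mu_q) * sd_ratio + mu_q
    sf = np.ones_like(q_std)
    pos = q_std > 0
    if pos.any():
        sf_pos = quadform._imhof_sf_vec(q_std[pos], lam, epsabs=min(accuracy, 1e-6))
        # far-tail values below inversion accuracy: saddlepoint, keeps ranking
        tiny = sf_pos < 1e-5
        if tiny.any():
            idx = np.where(pos)[0][tiny]
            sf_pos[tiny] = [quadform.saddlepoint_sf(qv, lam) for qv in q_std[idx]]
        sf[pos] = sf_pos
    dens = np.sqrt(2.0 / np.pi) * np.exp(-0.5 * x)
    p = float((sf * dens * wt).sum())
    p += float(chi2.sf(t_hi**2, 1))  # conservative remainder of the x-integral
    return p


def skat_o_resampling_pvalue(
    genotypes,
    null: NullModel,
    weights=None,
    mafs=None,
    rho_grid=DEFAULT_RHO_GRID,
    gene: str = "",
    n_resamples: int = 200_000,
    seed: int | None = 0,
) -> SkatResult:
    """Small-sample SKAT-O p-value by residual-permutation calibration.

    The asymptotic mixture null is inaccurate for binary traits at small n
    (score sums over few carriers are far from Gaussian), so this path
    calibrates the min-p statistic against the exact permutation distribution
    of the null-model residuals: per-rho p-values are permutation ranks and
    the reported p is the permutation rank of the min-p statistic itself.
    Deterministic given ``seed``.  Memory stays bounded by permuting in
    chunks.  Appropriate for n up to a few thousand; the asymptotic path is
    the right tool for large cohorts.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if weights is None:
        if mafs is None:
            raise ValueError("supply weights or mafs")
        weights = beta_weights(mafs)
    w = np.asarray(weights, dtype=float).ravel()
    n, m = g.shape
    rho_grid = tuple(float(r) for r in rho_grid)
    rhos = np.array(rho_grid)
    rng = np.random.default_rng(seed)
    r = null.residuals
    gw = g * w[None, :]

    ws_obs = gw.T @ r
    q_obs = (1.0 - rhos) * (ws_obs**2).sum() + rhos * ws_obs.sum() ** 2

    b_total = int(n_resamples)
    q_parts = []
    chunk = max(1, int(5e7 // max(n, 1)))
    done = 0
    while done < b_total:
        b = min(chunk, b_total - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        ws = r[perms] @ gw                     # b x m
        q_parts.append(
            (1.0 - rhos)[None, :] * (ws**2).sum(axis=1)[:, None]
            + rhos[None, :] * ws.sum(axis=1)[:, None] ** 2
        )
        done += b
    q_b = np.vstack(q_parts)

    p_obs_rho = ((q_b >= q_obs[None, :]).sum(axis=0) + 1) / (b_total + 1)
    p_rank = np.empty_like(q_b)
    for j in range(rhos.size):
        idx = np.argsort(-q_b[:, j], kind="stable")
        p_rank[idx, j] = np.arange(1, b_total + 1) / b_total
    minp_b = p_rank.min(axis=1)
    minp_obs = p_obs_rho.min()
    p = float(((minp_b <= minp_obs).sum() + 1) / (b_total + 1))

    p_rho = {rho_grid[j]: float(p_obs_rho[j]) for j in range(rhos.size)}
    rho_opt = min(p_rho, key=p_rho.get)
    return SkatResult(
        gene=gene, n_variants=m, rho_grid=rho_grid,
        q_rho={rho_grid[j]: float(q_obs[j]) for j in range(rhos.size)},
        p_rho=p_rho, p_skat=p_rho.get(0.0, np.nan), p_burden=p_rho.get(1.0, np.nan),
        p_skato=p, rho_opt=rho_opt,
        methods={rho: "resampling" for rho in rho_grid},
    )


def run_skat_scan(
    gene_variants: dict,
    null: NullModel,
    gene_order=None,
    rho_grid=DEFAULT_RHO_GRID,
    accuracy: float = 1e-6,
    m_bonferroni: int | None = None,
):
    """SKAT-O over a collection of genes.

    ``gene_variants`` maps gene -> (genotype matrix n x m, mafs length m).
    Genes with no polymorphic qualifying variant are skipped.  Returns a
    pandas DataFrame (one row per gene) with per-rho extremes, the SKAT-O p,
    and Bonferroni-adjusted p using ``m_bonferroni`` (default: number of
    genes tested).
    """
    import pandas as pd

    rows = []
    order = gene_order if gene_order is not None else list(gene_variants)
    for gene in order:
        if gene not in gene_variants:
            continue
        g, mafs = gene_variants[gene]
        g = np.asarray(g, dtype=float)
        if g.ndim == 1:
            g = g[:, None]
        mafs = np.asarray(mafs, dtype=float)
        keep = mafs > 0
        if not keep.any():
            continue
        g = g[:, keep]
        mafs = mafs[keep]
        res = skat_o_pvalue(g, null, mafs=mafs, rho_grid=rho_grid, gene=gene,
                            accuracy=accuracy)
        rows.append({
            "gene": gene,
            "n_variants": res.n_variants,
            "p_skat": res.p_skat,
            "p_burden": res.p_burden,
            "p_skato": res.p_skato,
            "rho_opt": res.rho_opt,
            "method": res.methods.get(res.rho_opt, ""),
        })
    df = pd.DataFrame(rows, columns=["gene", "n_variants", "p_skat", "p_burden",
                                     "p_skato", "rho_opt", "method"])
    m = m_bonferroni if m_bonferroni is not None else len(df)
    if len(df):
        df["p_adjusted"] = np.minimum(1.0, df["p_skato"] * max(m, 1))
        df["m_bonferroni"] = max(m, 1)
    else:
        df["p_adjusted"] = []
        df["m_bonferroni"] = []
    return df
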