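"""Tail probabilities of positive linear combinations of chi-square variables.

The gene-based variance-component statistics used in this package are, under
the null, distributed as Q ~ sum_k lambda_k * chi2_1 for non-negative weights
``lambda_k`` (the eigenvalues of the null-projected weighted genotype kernel).
This module computes P(Q > q) by

* an exact closed form when all eigenvalues are (numerically) equal, since
  Q / lambda is then exactly chi-square with ``len(lambda)`` df;
* numerical inversion of the characteristic function (Imhof's formula),
  the "exact method" of Davies-type algorithms;
* the Liu et al. moment-matching approximation (skewness-corrected
  non-central chi-square) as a fallback and for cheap quantiles;
* the Kuonen saddlepoint approximation, which keeps *relative* accuracy in
  the far tail where absolute-accuracy inversion returns noise.

All public functions accept eigenvalues in any order and ignore entries below
``trunc_tol`` times the largest eigenvalue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import chi2, ncx2, norm

__all__ = [
    "MixtureResult",
    "mixture_chisq_sf",
    "imhof_sf",
    "liu_sf",
    "liu_quantile",
    "saddlepoint_sf",
]

#: eigenvalues below this fraction of the largest are discarded
TRUNC_TOL = 1e-10


@dataclass(frozen=True)
class MixtureResult:
    """Tail probability plus the method that produced it."""

    p: float
    method: str  # "exact_chisq" | "imhof" | "saddlepoint" | "liu"


def _clean(lambdas) -> np.ndarray:
    lam = np.asarray(lambdas, dtype=float).ravel()
    if lam.size == 0:
        raise ValueError("eigenvalue list is empty")
    if np.any(lam < -TRUNC_TOL * max(lam.max(), 1.0)):
        raise ValueError("negative eigenvalue in chi-square mixture")
    lam = lam[lam > TRUNC_TOL * lam.max()]
    if lam.size == 0:
        raise ValueError("all eigenvalues are zero")
    return lam


# ---------------------------------------------------------------------------
# Liu et al. (2009) moment matching, with the modified parameterisation that
# matches kurtosis when the skewness inequality allows it.
# ---------------------------------------------------------------------------

def _liu_params(lam: np.ndarray):
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = math.sqrt(2.0 * c2)
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_x = df + delta
    sigma_x = math.sqrt(2.0 * (df + 2.0 * delta))
    return mu_q, sigma_q, df, delta, mu_x, sigma_x


def liu_sf(q: float, lambdas) -> float:
    """Moment-matching tail probability P(Q > q)."""
    lam = _clean(lambdas)
    mu_q, sigma_q, df, delta, mu_x, sigma_x = _liu_params(lam)
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        return float(ncx2.sf(x, df, delta))
    return float(chi2.sf(x, df))


def liu_quantile(p: float, lambdas) -> float:
    """Upper-tail quantile: the q with P(Q > q) = p under moment matching."""
    if not 0.0 < p <= 1.0:
        raise ValueError("tail probability must be in (0, 1]")
    lam = _clean(lambdas)
    mu_q, sigma_q, df, delta, mu_x, sigma_x = _liu_params(lam)
    if delta > 0:
        x = ncx2.isf(p, df, delta)
    else:
        x = chi2.isf(p, df)
    return float((x - mu_x) / sigma_x * sigma_q + mu_q)


# ---------------------------------------------------------------------------
# Imhof characteristic-function inversion
# ---------------------------------------------------------------------------

def _imhof_integrand(u: float, lam: np.ndarray, q: float) -> float:
    theta = 0.5 * (np.arctan(lam * u).sum() - q * u)
    rho = np.exp(0.25 * np.log1p((lam * u) ** 2).sum())
    return math.sin(theta) / (u * rho)


def _imhof_upper(lam: np.ndarray, q: float, epsabs: float) -> float:
    """Truncation point U such that the neglected oscillating tail of the
    Imhof integral is below epsabs.

    Past the first period the integral of the oscillating tail is bounded by
    the envelope at U times one half-period, 2*pi/q (alternating series).
    """
    freq = max(q, lam.sum(), 1e-3) / 2.0
    u = 10.0 / max(lam.max(), 1e-12)
    for _ in range(200):
        envelope = 1.0 / (u * math.exp(0.25 * np.log1p((lam * u) ** 2).sum()))
        tail = envelope * (math.pi / freq) / math.pi
        if tail < 0.5 * epsabs:
            return u
        u *= 1.5
    return u


def imhof_sf(q: float, lambdas, epsabs: float = 1e-9) -> float:
    """P(Q > q) by numerical inversion of the characteristic function.

    Absolute accuracy ~``epsabs``; values at or below the requested accuracy
    are meaningless and callers should fall back to :func:`saddlepoint_sf`.
    """
    lam = _clean(lambdas)
    if q <= 0:
        return 1.0
    upper = _imhof_upper(lam, q, epsabs)
    freq = max(q, lam.sum()) / 2.0
    # enough subdivisions to track the oscillation sin(~freq * u)
    limit = int(min(2e5, max(200, upper * freq / math.pi * 2)))
    val, _err = integrate.quad(
        _imhof_integrand,
        0.0,
        upper,
        args=(lam, q),
        epsabs=epsabs * 0.5,
        epsrel=1e-12,
        limit=limit,
    )
    return 0.5 + val / math.pi


# ---------------------------------------------------------------------------
# Kuonen saddlepoint approximation (Lugannani-Rice form)
# ---------------------------------------------------------------------------

def saddlepoint_sf(q: float, lambdas) -> float:
    """Saddlepoint tail approximation; relative accuracy holds far out in the
    tail, which absolute-accuracy inversion cannot provide."""
    lam = _clean(lambdas)
    mean = lam.sum()
    if q <= 0:
        return 1.0
    if abs(q - mean) < 1e-8 * max(mean, 1.0):
        # K'(0) = mean: saddlepoint at zero, normal-centre limit
        return 0.5
    zmax = 1.0 / (2.0 * lam.max())

    def kprime(z):
        return float((lam / (1.0 - 2.0 * z * lam)).sum())

    lo, hi = -1e3 / max(mean, 1e-12), zmax * (1.0 - 1e-12)
    # K' is increasing; bracket the root of K'(z) = q
    zhat = brentq(lambda z: kprime(z) - q, lo, hi, xtol=1e-14, maxiter=300)
    k = -0.5 * float(np.log1p(-2.0 * zhat * lam).sum())
    kpp = float((2.0 * lam**2 / (1.0 - 2.0 * zhat * lam) ** 2).sum())
    w = math.copysign(math.sqrt(max(2.0 * (zhat * q - k), 0.0)), zhat)
    v = zhat * math.sqrt(kpp)
    if abs(w) < 1e-8:
        return 0.5
    return float(norm.sf(w + math.log(v / w) / w))


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def mixture_chisq_sf(q: float, lambdas, accuracy: float = 1e-9) -> MixtureResult:
    """Tail probability P(sum_k lambda_k chi2_1 > q).

    Equal eigenvalues use the exact chi-square closed form.  Otherwise Imhof
    inversion at absolute accuracy ``accuracy`` is attempted; results within
    noise of zero (or any numerical failure) fall back to the saddlepoint
    (far tail) or Liu approximation, and the method used is reported.
    """
    lam = _clean(lambdas)
    if q <= 0:
        return MixtureResult(1.0, "exact_chisq")
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return MixtureResult(float(chi2.sf(q / lam[0], lam.size)), "exact_chisq")
    try:
        p = imhof_sf(q, lam, epsabs=accuracy)
    except Exception:
        p = math.nan
    if math.isfinite(p) and 10.0 * accuracy < p <= 1.0 + 1e-9:
        return MixtureResult(min(p, 1.0), "imhof")
    try:
        p = saddlepoint_sf(q, lam)
        if math.isfinite(p) and 0.0 < p <= 1.0:
            return MixtureResult(p, "saddlepoint")
    except Exception:
        pass
    return MixtureResult(max(min(liu_sf(q, lam), 1.0), 5e-324), "liu")


def _imhof_sf_vec(qs: np.ndarray, lam: np.ndarray, epsabs: float = 1e-6) -> np.ndarray:
    """Vectorised fixed-grid Imhof inversion sharing one eigenvalue set.

    Used in the SKAT-O outer integral where many tail probabilities with the
    same eigenvalues are needed; composite Simpson on a grid fine enough to
    resolve the oscillation of every q requested.
    """
    qs = np.asarray(qs, dtype=float)
    out = np.ones_like(qs)
    pos = qs > 0
    if not pos.any():
        return out
    qmax = float(qs[pos].max())
    upper = _imhof_upper(lam, qmax, epsabs)
    freq = max(qmax, lam.sum()) / 2.0
    n = int(min(4e5, max(2048, math.ceil(upper * freq / math.pi * 8))))
    if n % 2:
        n += 1
    u = np.linspace(0.0, upper, n + 1)
    u[0] = upper / n * 1e-6  # integrand has a removable singularity at 0
    lam_u = lam[None, :] * u[:, None]
    theta0 = 0.5 * np.arctan(lam_u).sum(axis=1)
    log_rho = 0.25 * np.log1p(lam_u**2).sum(axis=1)
    inv_urho = np.exp(-log_rho) / u
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= (upper / n) / 3.0
    qpos = qs[pos]
    vals = np.sin(theta0[:, None] - 0.5 * u[:, None] * qpos[None, :])
    vals *= inv_urho[:, None]
    integral = w @ vals
    out[pos] = np.clip(0.5 + integral / math.pi, 0.0, 1.0)
    return out
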