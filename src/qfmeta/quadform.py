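"""Distribution of nonnegative quadratic forms in independent normals.

QF = W * Theta' (diag(q) - q q') Theta with independent Theta_i ~ N(0, M2_i)
is distributed as sum_k lambda_k z_k^2 for standard normal z_k, where the
lambda_k are the eigenvalues of S^{1/2} B S^{1/2}, B = W (diag(q) - q q'),
S = diag(M2).  The CDF of such a weighted chi-square sum is evaluated by
Ruben's mixture-of-central-chi-squares series (the Farebrother algorithm);
an Imhof-type numerical inversion of the characteristic function is provided
as an independent cross-check, and a Monte-Carlo fallback guards against
series non-convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammainc, gammaln
from scipy.stats import chi2

from .data import StudySummary, VarianceVariant
from .qstats import q_f, second_moments

__all__ = [
    "EigenSpectrum",
    "qf_spectrum",
    "ruben_cdf",
    "imhof_cdf",
    "qf_cdf",
    "chisq_pvalue_qiv",
]

_EIG_RTOL = 1e-10  # relative cutoff below which an eigenvalue is structural zero
_MAX_TERMS = 10_000
_MC_FALLBACK_DRAWS = 100_000


@dataclass(frozen=True)
class EigenSpectrum:
    """Positive eigenvalues (descending) of the quadratic form's matrix."""

    lambdas: np.ndarray
    n_dropped: int

    def __post_init__(self):
        object.__setattr__(self, "lambdas", np.asarray(self.lambdas, dtype=float))
        if self.lambdas.size == 0:
            raise ValueError("spectrum must retain at least one eigenvalue")
        if np.any(self.lambdas <= 0):
            raise ValueError("retained eigenvalues must be positive")


def qf_spectrum(
    q_norm: Sequence[float], w_total: float, m2: Sequence[float]
) -> EigenSpectrum:
    """Eigenvalues of S^{1/2} B S^{1/2}, dropping the structural zero.

    B = W (diag(q) - q q') annihilates the constant vector, so exactly one
    zero eigenvalue is expected; more indicates degenerate input and raises a
    warning.
    """
    qn = np.asarray(q_norm, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if np.any(m2 <= 0):
        raise ValueError("second moments must be positive")
    if abs(qn.sum() - 1.0) > 1e-8:
        raise ValueError("normalized weights must sum to 1")
    b = w_total * (np.diag(qn) - np.outer(qn, qn))
    s_half = np.sqrt(m2)
    mat = b * np.outer(s_half, s_half)
    lam = np.linalg.eigvalsh(mat)
    cutoff = _EIG_RTOL * lam[-1]
    keep = lam[lam > cutoff][::-1]
    n_dropped = lam.size - keep.size
    if n_dropped > 1:
        warnings.warn(
            f"dropped {n_dropped} near-zero eigenvalues (collinear/degenerate input)",
            RuntimeWarning,
        )
    return EigenSpectrum(lambdas=keep, n_dropped=n_dropped)


def _as_lambdas(spectrum) -> np.ndarray:
    if isinstance(spectrum, EigenSpectrum):
        return spectrum.lambdas
    lam = np.asarray(spectrum, dtype=float)
    if lam.size == 0 or np.any(lam <= 0):
        raise ValueError("eigenvalues must be positive")
    return lam


def ruben_cdf(spectrum, x: float, tol: float = 1e-9) -> float:
    """P(sum_k lambda_k z_k^2 <= x) by Ruben's chi-square series.

    The distribution is expanded as sum_k c_k P(chi^2_{m + 2k} <= x / beta)
    with centering constant beta = 2 lambda_min lambda_max /
    (lambda_min + lambda_max).  The series is truncated once the tail bound
    |1 - sum c_k| * P(chi^2 <= x/beta) and the last terms fall below ``tol``.
    On non-convergence within 10,000 terms a Monte-Carlo estimate (100,000
    draws) is returned with a warning.
    """
    lam = _as_lambdas(spectrum)
    if not (0 < tol <= 1e-4):
        raise ValueError("tol must be in (0, 1e-4]")
    if x <= 0:
        return 0.0
    m = lam.size
    if m == 1:
        return float(chi2.cdf(x / lam[0], 1))
    lmin, lmax = lam.min(), lam.max()
    if lmax / lmin - 1.0 < 1e-12:  # equal eigenvalues: exact chi-square
        return float(chi2.cdf(x / lmin, m))
    beta = 2.0 * lmin * lmax / (lmin + lmax)
    y = x / beta
    ratio = 1.0 - beta / lam  # |ratio| < 1 since beta < 2*lmin

    # chi-square CDF recursion: F_{m+2(k+1)}(y) = F_{m+2k}(y) - t_k,
    # t_k = (y/2)^{m/2+k} e^{-y/2} / Gamma(m/2+k+1)
    half_y = 0.5 * y
    f_chi = float(gammainc(0.5 * m, half_y))
    log_t = 0.5 * m * np.log(half_y) - half_y - gammaln(0.5 * m + 1.0)
    t = np.exp(log_t)

    c = np.empty(_MAX_TERMS)
    g = np.empty(_MAX_TERMS + 1)
    c[0] = float(np.exp(0.5 * np.sum(np.log(beta / lam))))
    pow_ratio = np.ones_like(ratio)
    total = c[0] * f_chi
    csum = c[0]
    small_run = 0
    for k in range(1, _MAX_TERMS):
        pow_ratio *= ratio
        g[k] = 0.5 * float(pow_ratio.sum())
        # c_k = (1/k) * sum_{r=0}^{k-1} g_{k-r} c_r
        c[k] = float(np.dot(g[1 : k + 1][::-1], c[:k])) / k
        f_chi -= t
        t *= half_y / (0.5 * m + k)
        if f_chi < 0.0:  # guard tiny negative from cancellation
            f_chi = 0.0
        term = c[k] * f_chi
        total += term
        csum += c[k]
        if abs(term) < tol:
            small_run += 1
            if small_run >= 3 and abs(1.0 - csum) * f_chi < tol:
                return float(min(max(total, 0.0), 1.0))
        else:
            small_run = 0

    warnings.warn(
        "Ruben series did not converge; falling back to Monte Carlo",
        RuntimeWarning,
    )
    rng = np.random.default_rng(180625)
    draws = rng.chisquare(1, size=(_MC_FALLBACK_DRAWS, m)) @ lam
    return float(np.mean(draws <= x))


def imhof_cdf(spectrum, x: float) -> float:
    """CDF by Imhof's numerical inversion of the characteristic function.

    Slower than the Ruben series; used as an independent cross-check.
    """
    lam = _as_lambdas(spectrum)
    if x <= 0:
        return 0.0
    m = lam.size

    def integrand(u: np.ndarray) -> np.ndarray:
        lu = np.outer(u, lam)
        theta = 0.5 * np.sum(np.arctan(lu), axis=1) - 0.5 * x * u
        log_rho = 0.25 * np.sum(np.log1p(lu**2), axis=1)
        return np.sin(theta) * np.exp(-log_rho) / u

    # Beyond U the integrand oscillates at frequency ~ x/2 with envelope
    # <= U^{-(1+m/2)} / prod(lam)^{1/2}; one integration by parts bounds the
    # discarded tail by envelope * period.  Choose U for a ~1e-9 tail.
    log_prod_half = 0.5 * float(np.sum(np.log(lam)))
    period = 4.0 * np.pi / (x + float(lam.sum()))
    target = np.log(1e-9) + log_prod_half - np.log(period)
    u_max = float(np.exp(-target / (1.0 + 0.5 * m)))
    u_max = max(u_max, 20.0 / float(lam.min()))
    n_panels = int(min(max(np.ceil(u_max / period), 64), 200_000))
    edges = np.linspace(0.0, u_max, n_panels + 1)
    # 16-point Gauss-Legendre per panel, fully vectorized
    nodes, wts = np.polynomial.legendre.leggauss(16)
    a, b = edges[:-1, None], edges[1:, None]
    u = (0.5 * (b - a) * (nodes + 1.0) + a).ravel()
    w = (0.5 * (b - a) * wts).ravel()
    val = float(np.dot(w, integrand(u)))
    return float(min(max(0.5 - val / np.pi, 0.0), 1.0))


def qf_cdf(
    summaries: Sequence[StudySummary],
    x: float,
    tau2: float,
    variant: VarianceVariant = VarianceVariant.CONDITIONAL,
    theta_pooled: float | None = None,
    tol: float = 1e-9,
) -> float:
    """F(x | tau2): CDF of QF with plugged-in second moments at a given tau2.

    Strictly decreasing in tau2 at fixed x > 0 (larger heterogeneity inflates
    the form), which underwrites the median-unbiased estimators and the
    profile confidence intervals built on it.
    """
    qr = q_f(summaries)
    m2 = second_moments(summaries, tau2, variant, theta_pooled)
    spec = qf_spectrum(qr.q_norm, qr.w_total, m2)
    return ruben_cdf(spec, x, tol=tol)


def chisq_pvalue_qiv(q: float, k: int) -> float:
    """Upper-tail chi-square(K-1) p-value for the inverse-variance Q."""
    if k < 2:
        raise ValueError("need at least two studies")
    return float(chi2.sf(q, k - 1))
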