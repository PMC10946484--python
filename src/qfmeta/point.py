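"""Point estimators of the between-study variance tau2 for log-odds-ratio.

Inverse-variance based comparators: DerSimonian-Laird (DL), restricted
maximum likelihood (REML) and Mandel-Paule (MP).  Effective-sample-size
based estimators built on QF: the moment estimators SSC (conditional
variances) and SSU (unconditional, model-based or naive treatment-arm
probability), and their median-unbiased counterparts SMC and SMU, which
solve F(QF_obs | tau2) = 1/2 in the Farebrother approximation to the
distribution of QF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .data import StudySummary, VarianceVariant, ZeroPolicy, uncond_terms
from .qstats import pooled_ssw, q_f, q_iv, second_moments
from .quadform import qf_spectrum, ruben_cdf

__all__ = [
    "Tau2Estimate",
    "tau2_dl",
    "tau2_reml",
    "tau2_mp",
    "tau2_ssc",
    "tau2_ssu",
    "tau2_smc",
    "tau2_smu",
    "POINT_ESTIMATORS",
]

_BISECT_TOL = 1e-8
_BRACKET_START = 5.0
_BRACKET_CAP = 1e4
_REML_TOL = 1e-8
_REML_MAX_ITER = 1000


@dataclass(frozen=True)
class Tau2Estimate:
    """A tau2 estimate with its method label and diagnostic state."""

    value: float  # truncated at 0
    method: str
    raw: float | None = None  # untruncated moment value (absent for median-type)
    converged: bool = True
    iterations: int = 0


def _check_k(summaries: Sequence[StudySummary]) -> None:
    if len(summaries) < 2:
        raise ValueError("tau2 estimation requires at least two studies")


def tau2_dl(summaries: Sequence[StudySummary]) -> Tau2Estimate:
    """DerSimonian-Laird moment estimator from QIV."""
    _check_k(summaries)
    k = len(summaries)
    v2 = np.array([s.v2_cond for s in summaries])
    w = 1.0 / v2
    s1, s2 = w.sum(), (w**2).sum()
    raw = (q_iv(summaries).q - (k - 1)) / (s1 - s2 / s1)
    return Tau2Estimate(value=max(0.0, raw), raw=raw, method="DL")


def tau2_reml(summaries: Sequence[StudySummary]) -> Tau2Estimate:
    """REML under theta_hat_i ~ N(theta, v_i^2 + tau2), fixed-point iteration."""
    _check_k(summaries)
    th = np.array([s.theta_hat for s in summaries])
    v2 = np.array([s.v2_cond for s in summaries])
    tau2 = max(tau2_dl(summaries).value, 0.0)
    converged = False
    it = 0
    for it in range(1, _REML_MAX_ITER + 1):
        w = 1.0 / (v2 + tau2)
        mu = np.sum(w * th) / w.sum()
        new = np.sum(w**2 * ((th - mu) ** 2 - v2)) / np.sum(w**2) + 1.0 / w.sum()
        new = max(new, 0.0)
        if abs(new - tau2) <= _REML_TOL * (1.0 + tau2):
            tau2 = new
            converged = True
            break
        tau2 = new
    return Tau2Estimate(value=tau2, raw=None, method="REML", converged=converged, iterations=it)


def _q_gen(tau2: float, th: np.ndarray, v2: np.ndarray) -> float:
    w = 1.0 / (v2 + tau2)
    mu = np.sum(w * th) / w.sum()
    return float(np.sum(w * (th - mu) ** 2))


def _bisect_decreasing(
    fn: Callable[[float], float], target: float, tol: float = _BISECT_TOL
) -> tuple[float, bool]:
    """Solve fn(x) = target for decreasing fn on x >= 0; fn(0) > target assumed.

    Returns (root, converged); the bracket is doubled from 5 up to 1e4.
    """
    hi = _BRACKET_START
    while fn(hi) > target:
        hi *= 2.0
        if hi > _BRACKET_CAP:
            return _BRACKET_CAP, False
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fn(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), True


def tau2_mp(summaries: Sequence[StudySummary]) -> Tau2Estimate:
    """Mandel-Paule: tau2 solving Q_gen(tau2) = K - 1 with weights 1/(v^2+tau2)."""
    _check_k(summaries)
    k = len(summaries)
    th = np.array([s.theta_hat for s in summaries])
    v2 = np.array([s.v2_cond for s in summaries])
    if _q_gen(0.0, th, v2) <= k - 1:
        return Tau2Estimate(value=0.0, raw=None, method="MP")
    root, ok = _bisect_decreasing(lambda t: _q_gen(t, th, v2), float(k - 1))
    return Tau2Estimate(value=root, raw=None, method="MP", converged=ok)


def _ssw_pieces(summaries: Sequence[StudySummary]):
    qr = q_f(summaries)
    qn = qr.q_norm
    return qr, qn, qn * (1.0 - qn)


def tau2_ssc(summaries: Sequence[StudySummary]) -> Tau2Estimate:
    """Moment estimator from E QF with conditional variances (SSC).

    raw = (QF/W - sum q_i(1-q_i) v_i^2) / sum q_i(1-q_i), truncated at 0.
    """
    _check_k(summaries)
    qr, _, q1q = _ssw_pieces(summaries)
    v2 = np.array([s.v2_cond for s in summaries])
    raw = (qr.q / qr.w_total - float(np.sum(q1q * v2))) / float(np.sum(q1q))
    return Tau2Estimate(value=max(0.0, raw), raw=raw, method="SSC")


def tau2_ssu(
    summaries: Sequence[StudySummary],
    variant: VarianceVariant = VarianceVariant.UNCOND_MODEL,
) -> Tau2Estimate:
    """Moment estimator from E QF with unconditional variances (SSU).

    raw = (QF/W - sum q_i(1-q_i) E v_i^2) / sum q_i(1-q_i) C_i.
    """
    _check_k(summaries)
    if variant is VarianceVariant.CONDITIONAL:
        raise ValueError("SSU requires an unconditional variance variant")
    qr, _, q1q = _ssw_pieces(summaries)
    theta_pooled = pooled_ssw(summaries) if variant is VarianceVariant.UNCOND_MODEL else None
    ev, ci = uncond_terms(summaries, variant, theta_pooled)
    raw = (qr.q / qr.w_total - float(np.sum(q1q * ev))) / float(np.sum(q1q * ci))
    label = "SSU model" if variant is VarianceVariant.UNCOND_MODEL else "SSU naive"
    return Tau2Estimate(value=max(0.0, raw), raw=raw, method=label)


def _median_tau2(
    summaries: Sequence[StudySummary],
    variant: VarianceVariant,
    label: str,
) -> Tau2Estimate:
    qr = q_f(summaries)
    theta_pooled = pooled_ssw(summaries) if variant is VarianceVariant.UNCOND_MODEL else None

    def cdf_at(tau2: float) -> float:
        m2 = second_moments(summaries, tau2, variant, theta_pooled)
        spec = qf_spectrum(qr.q_norm, qr.w_total, m2)
        return ruben_cdf(spec, qr.q)

    if cdf_at(0.0) < 0.5:
        return Tau2Estimate(value=0.0, raw=None, method=label)
    root, ok = _bisect_decreasing(cdf_at, 0.5)
    return Tau2Estimate(value=root, raw=None, method=label, converged=ok)


def tau2_smc(summaries: Sequence[StudySummary]) -> Tau2Estimate:
    """Median-unbiased estimator: F(QF_obs | tau2) = 1/2, conditional moments."""
    _check_k(summaries)
    return _median_tau2(summaries, VarianceVariant.CONDITIONAL, "SMC")


def tau2_smu(
    summaries: Sequence[StudySummary],
    variant: VarianceVariant = VarianceVariant.UNCOND_MODEL,
) -> Tau2Estimate:
    """Median-unbiased estimator with unconditional moments E v^2 + tau2 C."""
    _check_k(summaries)
    if variant is VarianceVariant.CONDITIONAL:
        raise ValueError("SMU requires an unconditional variance variant")
    label = "SMU model" if variant is VarianceVariant.UNCOND_MODEL else "SMU naive"
    return _median_tau2(summaries, variant, label)


#: Method label -> estimator callable on a list of StudySummary.
POINT_ESTIMATORS: dict[str, Callable[[Sequence[StudySummary]], Tau2Estimate]] = {
    "DL": tau2_dl,
    "REML": tau2_reml,
    "MP": tau2_mp,
    "SSC": tau2_ssc,
    "SSU model": lambda s: tau2_ssu(s, VarianceVariant.UNCOND_MODEL),
    "SSU naive": lambda s: tau2_ssu(s, VarianceVariant.UNCOND_NAIVE),
    "SMC": tau2_smc,
    "SMU model": lambda s: tau2_smu(s, VarianceVariant.UNCOND_MODEL),
    "SMU naive": lambda s: tau2_smu(s, VarianceVariant.UNCOND_NAIVE),
}

#: Table-style pairing of methods with 0.5-adding policies.
POINT_POLICY_TABLE: dict[str, tuple[ZeroPolicy, ...]] = {
    "DL": (ZeroPolicy.ONLY, ZeroPolicy.ALWAYS),
    "REML": (ZeroPolicy.ONLY, ZeroPolicy.ALWAYS),
    "MP": (ZeroPolicy.ONLY, ZeroPolicy.ALWAYS),
    "SSC": (ZeroPolicy.ONLY, ZeroPolicy.ALWAYS),
    "SMC": (ZeroPolicy.ONLY, ZeroPolicy.ALWAYS),
    "SSU model": (ZeroPolicy.ALWAYS,),
    "SSU naive": (ZeroPolicy.ALWAYS,),
    "SMU model": (ZeroPolicy.ALWAYS,),
    "SMU naive": (ZeroPolicy.ALWAYS,),
}
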