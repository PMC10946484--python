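"""Confidence intervals for the between-study variance tau2.

QP: Q-profile, inverting the chi-square(K-1) reference distribution of the
generalized Q with weights 1/(v^2 + tau2).  PL: profile likelihood, inverting
the chi-square(1) likelihood-ratio statistic of the normal random-effects
likelihood profiled over the overall effect.  FPC/FPU: Farebrother profile,
inverting the approximate CDF F(QF_obs | tau2) of the fixed-weights statistic
with conditional or unconditional second moments.  All intervals split the
miscoverage alpha equally between tails.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import chi2

from .data import StudySummary, VarianceVariant
from .qstats import pooled_ssw, q_f, second_moments
from .quadform import qf_spectrum, ruben_cdf

__all__ = [
    "IntervalStatus",
    "Tau2Interval",
    "ci_qprofile",
    "ci_pl",
    "ci_fpc",
    "ci_fpu",
    "INTERVAL_ESTIMATORS",
]

_UPPER_CAP = 1e4
_XTOL = 1e-10  # bisection width on tau2; endpoint residuals ~1e-7 or better


class IntervalStatus(str, enum.Enum):
    OK = "ok"
    DEGENERATE_ZERO = "degenerate_zero"
    UPPER_UNBOUNDED = "upper_unbounded"
    NO_CONVERGENCE = "no_convergence"


@dataclass(frozen=True)
class Tau2Interval:
    lower: float
    upper: float
    level: float
    method: str
    status: IntervalStatus = IntervalStatus.OK

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    def contains(self, tau2: float) -> bool:
        return self.lower <= tau2 <= self.upper


def _bisect(fn: Callable[[float], float], target: float, lo: float, hi: float) -> float:
    """Root of decreasing fn(x) = target on [lo, hi] with fn(lo) >= target >= fn(hi)."""
    while hi - lo > _XTOL:
        mid = 0.5 * (lo + hi)
        if fn(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _invert_decreasing(
    fn: Callable[[float], float],
    upper_target: float,
    lower_target: float,
    level: float,
    method: str,
) -> Tau2Interval:
    """CI {tau2 >= 0 : lower_target <= fn(tau2) <= upper_target} for decreasing fn."""
    f0 = fn(0.0)
    if f0 < lower_target:
        return Tau2Interval(0.0, 0.0, level, method, IntervalStatus.DEGENERATE_ZERO)
    lower = 0.0 if f0 <= upper_target else None
    hi = 5.0
    while fn(hi) > lower_target:
        hi *= 2.0
        if hi > _UPPER_CAP:
            lo_val = _bisect(fn, upper_target, 0.0, hi) if lower is None else lower
            return Tau2Interval(lo_val, _UPPER_CAP, level, method, IntervalStatus.UPPER_UNBOUNDED)
    if lower is None:
        lower = _bisect(fn, upper_target, 0.0, hi)
    upper = _bisect(fn, lower_target, lower, hi)
    return Tau2Interval(lower, upper, level, method, IntervalStatus.OK)


def ci_qprofile(summaries: Sequence[StudySummary], level: float = 0.95) -> Tau2Interval:
    """Q-profile interval: chi-square(K-1) quantile band for Q_gen(tau2)."""
    k = len(summaries)
    if k < 2:
        raise ValueError("need at least two studies")
    th = np.array([s.theta_hat for s in summaries])
    v2 = np.array([s.v2_cond for s in summaries])
    alpha = 1.0 - level

    def q_gen(tau2: float) -> float:
        w = 1.0 / (v2 + tau2)
        mu = np.sum(w * th) / w.sum()
        return float(np.sum(w * (th - mu) ** 2))

    lo_q, hi_q = chi2.ppf(alpha / 2, k - 1), chi2.ppf(1 - alpha / 2, k - 1)
    return _invert_decreasing(q_gen, hi_q, lo_q, level, "QP")


def _profile_loglik(tau2: float, th: np.ndarray, v2: np.ndarray) -> float:
    w = 1.0 / (v2 + tau2)
    mu = np.sum(w * th) / w.sum()
    return float(-0.5 * np.sum(np.log(v2 + tau2)) - 0.5 * np.sum(w * (th - mu) ** 2))


def ci_pl(summaries: Sequence[StudySummary], level: float = 0.95) -> Tau2Interval:
    """Profile-likelihood interval from the normal random-effects likelihood.

    {tau2 >= 0 : 2 [l_p(tau2_ML) - l_p(tau2)] <= chi2_{1, level}} with the
    overall effect profiled out at each tau2.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two studies")
    th = np.array([s.theta_hat for s in summaries])
    v2 = np.array([s.v2_cond for s in summaries])

    # ML point by golden-section-free grid + refinement: the profile
    # log-likelihood is smooth and typically unimodal in tau2.
    from scipy.optimize import minimize_scalar

    hi = 5.0
    while _profile_loglik(hi, th, v2) > _profile_loglik(0.0, th, v2) and hi < _UPPER_CAP:
        hi *= 2.0
    res = minimize_scalar(
        lambda t: -_profile_loglik(t, th, v2), bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2_ml = float(res.x) if res.fun < -_profile_loglik(0.0, th, v2) + 1e-12 else 0.0
    if -res.fun < _profile_loglik(0.0, th, v2):
        tau2_ml = 0.0
    l_max = _profile_loglik(tau2_ml, th, v2)
    crit = 0.5 * chi2.ppf(level, 1)

    def drop(t: float) -> float:
        return l_max - _profile_loglik(t, th, v2)

    # lower endpoint
    if drop(0.0) <= crit:
        lower = 0.0
    else:
        lower = _bisect(lambda t: drop(t), crit, 0.0, tau2_ml)  # drop decreasing to ML
    # upper endpoint: drop increases beyond the ML point
    hi = max(2.0 * tau2_ml, 5.0)
    while drop(hi) < crit:
        hi *= 2.0
        if hi > _UPPER_CAP:
            return Tau2Interval(lower, _UPPER_CAP, level, "PL", IntervalStatus.UPPER_UNBOUNDED)
    lo = tau2_ml
    while hi - lo > _XTOL:
        mid = 0.5 * (lo + hi)
        if drop(mid) < crit:
            lo = mid
        else:
            hi = mid
    return Tau2Interval(lower, 0.5 * (lo + hi), level, "PL", IntervalStatus.OK)


def _ci_farebrother(
    summaries: Sequence[StudySummary],
    variant: VarianceVariant,
    level: float,
    method: str,
) -> Tau2Interval:
    if len(summaries) < 2:
        raise ValueError("need at least two studies")
    qr = q_f(summaries)
    theta_pooled = pooled_ssw(summaries) if variant is VarianceVariant.UNCOND_MODEL else None
    alpha = 1.0 - level

    def cdf_at(tau2: float) -> float:
        m2 = second_moments(summaries, tau2, variant, theta_pooled)
        spec = qf_spectrum(qr.q_norm, qr.w_total, m2)
        return ruben_cdf(spec, qr.q)

    return _invert_decreasing(cdf_at, 1.0 - alpha / 2, alpha / 2, level, method)


def ci_fpc(summaries: Sequence[StudySummary], level: float = 0.95) -> Tau2Interval:
    """Farebrother-profile interval with conditional second moments."""
    return _ci_farebrother(summaries, VarianceVariant.CONDITIONAL, level, "FPC")


def ci_fpu(
    summaries: Sequence[StudySummary],
    variant: VarianceVariant = VarianceVariant.UNCOND_MODEL,
    level: float = 0.95,
) -> Tau2Interval:
    """Farebrother-profile interval with unconditional second moments."""
    if variant is VarianceVariant.CONDITIONAL:
        raise ValueError("FPU requires an unconditional variance variant")
    label = "FPU model" if variant is VarianceVariant.UNCOND_MODEL else "FPU naive"
    return _ci_farebrother(summaries, variant, level, label)


#: Method label -> interval callable (summaries, level) -> Tau2Interval.
INTERVAL_ESTIMATORS: dict[str, Callable[..., Tau2Interval]] = {
    "QP": ci_qprofile,
    "PL": ci_pl,
    "FPC": ci_fpc,
    "FPU model": lambda s, level=0.95: ci_fpu(s, VarianceVariant.UNCOND_MODEL, level),
    "FPU naive": lambda s, level=0.95: ci_fpu(s, VarianceVariant.UNCOND_NAIVE, level),
}
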