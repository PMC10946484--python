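"""Q statistics for heterogeneity: inverse-variance and fixed-weights flavours.

``Q = sum_i w_i (theta_i - theta_bar_w)^2`` measures dispersion of study
effects about their weighted mean.  With weights 1/v_i^2 (estimated inverse
variances) this is Cochran's QIV; with the fixed effective-sample-size
weights n_tilde_i = n_iC n_iT / n_i it is the generalized statistic QF whose
weights do not depend on any estimated variance.  Under the random-effects
model E QF = W * sum q_i (1 - q_i) M2_i, where q_i = w_i / W and M2_i is the
second moment of theta_hat_i - theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import StudySummary, VarianceVariant, uncond_terms

__all__ = [
    "QResult",
    "weighted_mean",
    "q_statistic",
    "q_iv",
    "q_f",
    "i_squared",
    "expected_qf",
    "pooled_ssw",
    "pooled_iv",
]


@dataclass(frozen=True)
class QResult:
    """A Q statistic together with its weights and weighted mean."""

    q: float
    weights: np.ndarray
    theta_bar: float
    flavor: str  # "IV" or "F"

    @property
    def w_total(self) -> float:
        return float(np.sum(self.weights))

    @property
    def q_norm(self) -> np.ndarray:
        """Normalized weights q_i = w_i / W (sum to 1)."""
        return self.weights / self.w_total


def weighted_mean(thetas: Sequence[float], weights: Sequence[float]) -> float:
    thetas = np.asarray(thetas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if thetas.size == 0 or thetas.shape != weights.shape:
        raise ValueError("thetas and weights must be equal-length and nonempty")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(weights * thetas) / np.sum(weights))


def q_statistic(
    thetas: Sequence[float], weights: Sequence[float], flavor: str = "generic"
) -> QResult:
    """Weighted sum of squared deviations from the weighted mean."""
    thetas = np.asarray(thetas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if thetas.size < 2:
        raise ValueError("Q requires at least two studies")
    tb = weighted_mean(thetas, weights)
    q = float(np.sum(weights * (thetas - tb) ** 2))
    return QResult(q=q, weights=weights, theta_bar=tb, flavor=flavor)


def _arrays(summaries: Sequence[StudySummary]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    th = np.array([s.theta_hat for s in summaries])
    v2 = np.array([s.v2_cond for s in summaries])
    nt = np.array([s.n_tilde for s in summaries])
    return th, v2, nt


def q_iv(summaries: Sequence[StudySummary]) -> QResult:
    """Cochran's Q with inverse estimated-variance weights."""
    th, v2, _ = _arrays(summaries)
    return q_statistic(th, 1.0 / v2, flavor="IV")


def q_f(summaries: Sequence[StudySummary]) -> QResult:
    """Generalized Q with fixed effective-sample-size weights n_tilde."""
    th, _, nt = _arrays(summaries)
    return q_statistic(th, nt, flavor="F")


def i_squared(q: float, k: int) -> float:
    """Higgins' I^2 (percent), max(0, (Q - (K-1))/Q) * 100."""
    if k < 2 or q < 0:
        raise ValueError("require k >= 2 and q >= 0")
    if q == 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q) * 100.0


def second_moments(
    summaries: Sequence[StudySummary],
    tau2: float,
    variant: VarianceVariant,
    theta_pooled: float | None = None,
) -> np.ndarray:
    """Per-study second moments M2_i of theta_hat_i - theta at a given tau2.

    Conditional: v_i^2 + tau2.  Unconditional: E v_i^2 + tau2 * C_i, with the
    naive or model-based treatment-arm probability.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    if variant is VarianceVariant.CONDITIONAL:
        _, v2, _ = _arrays(summaries)
        return v2 + tau2
    if variant is VarianceVariant.UNCOND_MODEL and theta_pooled is None:
        theta_pooled = pooled_ssw(summaries)
    ev, ci = uncond_terms(summaries, variant, theta_pooled)
    return ev + tau2 * ci


def expected_qf(
    summaries: Sequence[StudySummary],
    tau2: float,
    variant: VarianceVariant = VarianceVariant.CONDITIONAL,
    theta_pooled: float | None = None,
) -> float:
    """E QF = W * sum q_i (1 - q_i) M2_i under the random-effects model."""
    _, _, nt = _arrays(summaries)
    w_total = float(nt.sum())
    qn = nt / w_total
    m2 = second_moments(summaries, tau2, variant, theta_pooled)
    return float(w_total * np.sum(qn * (1 - qn) * m2))


def pooled_ssw(summaries: Sequence[StudySummary]) -> float:
    """Fixed-weights pooled LOR: effective-sample-size weighted mean."""
    th, _, nt = _arrays(summaries)
    return weighted_mean(th, nt)


def pooled_iv(summaries: Sequence[StudySummary], tau2: float = 0.0) -> tuple[float, float]:
    """Inverse-variance pooled LOR and its standard error.

    With tau2 = 0 this is the common-effect estimate; with tau2 > 0 the
    random-effects estimate using weights 1/(v_i^2 + tau2).
    """
    th, v2, _ = _arrays(summaries)
    w = 1.0 / (v2 + tau2)
    est = weighted_mean(th, w)
    return est, float(np.sqrt(1.0 / np.sum(w)))
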