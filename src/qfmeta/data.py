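"""Per-study 2x2 tables and study-level quantities for log-odds-ratio meta-analysis.

Each study contributes a 2x2 table of event counts: ``x_t`` events among
``n_t`` treatment subjects and ``x_c`` events among ``n_c`` control subjects,
modelled as independent binomials.  This module computes the study-level
log-odds-ratio (LOR), its conditional (delta-method) variance, its
unconditional variance under the fixed-intercept random-effects model, the
effective sample size used as a fixed weight, and the continuity-correction
("add 0.5") policies.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "ProportionRule",
    "ZeroPolicy",
    "VarianceVariant",
    "Study2x2",
    "StudySummary",
    "estimate_proportion",
    "resolve_rule",
    "log_odds_ratio",
    "conditional_variance",
    "inflation_factor",
    "unconditional_variance",
    "effective_sample_size",
    "filter_studies",
    "summarize_studies",
    "uncond_terms",
    "read_studies",
    "write_studies",
]


class ProportionRule(str, enum.Enum):
    """How to estimate an arm-level event probability from (x, n)."""

    MLE = "mle"  # p = x/n
    ADJUSTED = "adjusted"  # p = (x + 0.5)/(n + 1), Gart's bias-reducing estimate


class ZeroPolicy(str, enum.Enum):
    """When to use the adjusted (add 0.5) proportion rule.

    ``ONLY``: adjust a study iff one of its four cells (events or
    non-events, either arm) is zero.  ``ALWAYS``: adjust every study.
    """

    ONLY = "only"
    ALWAYS = "always"


class VarianceVariant(str, enum.Enum):
    """Which per-study second moment feeds the Q-statistic machinery.

    ``CONDITIONAL`` uses the delta-method variance given the study's own
    probabilities.  The unconditional variants additionally account for the
    random study effect; they differ in the treatment-arm probability used:
    ``UNCOND_MODEL`` predicts it from the control arm and a pooled effect
    (expit(logit(p_c) + theta_pooled)), ``UNCOND_NAIVE`` uses the study's own
    adjusted proportion.
    """

    CONDITIONAL = "conditional"
    UNCOND_MODEL = "uncond_model"
    UNCOND_NAIVE = "uncond_naive"


@dataclass(frozen=True)
class Study2x2:
    """One study's arm-level counts (treatment and control)."""

    x_t: int
    n_t: int
    x_c: int
    n_c: int
    id: str = ""

    def __post_init__(self) -> None:
        for name in ("x_t", "n_t", "x_c", "n_c"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise TypeError(f"{name} must be an integer, got {v!r}")
        if self.n_t < 1 or self.n_c < 1:
            raise ValueError(f"arm sizes must be >= 1 (study {self.id!r})")
        if not (0 <= self.x_t <= self.n_t) or not (0 <= self.x_c <= self.n_c):
            raise ValueError(f"event counts must satisfy 0 <= x <= n (study {self.id!r})")

    @property
    def n(self) -> int:
        """Total sample size of the study."""
        return self.n_t + self.n_c

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """The four cells (events/non-events by arm) of the 2x2 table."""
        return (self.x_t, self.n_t - self.x_t, self.x_c, self.n_c - self.x_c)

    @property
    def double_zero(self) -> bool:
        """True iff both arms have zero events."""
        return self.x_t == 0 and self.x_c == 0

    @property
    def double_n(self) -> bool:
        """True iff both arms have all events."""
        return self.x_t == self.n_t and self.x_c == self.n_c


def estimate_proportion(x: int, n: int, rule: ProportionRule) -> float:
    """Arm-level event probability estimate.

    ``MLE`` gives x/n; ``ADJUSTED`` gives (x + 0.5)/(n + 1), which removes the
    O(1/n) bias of the log-odds and is strictly inside (0, 1).
    """
    if n < 1 or not (0 <= x <= n):
        raise ValueError(f"invalid counts x={x}, n={n}")
    if rule is ProportionRule.MLE:
        return x / n
    return (x + 0.5) / (n + 1)


def resolve_rule(study: Study2x2, policy: ZeroPolicy) -> ProportionRule:
    """Proportion rule actually applied to a study under a 0.5-adding policy."""
    if policy is ZeroPolicy.ALWAYS:
        return ProportionRule.ADJUSTED
    return ProportionRule.ADJUSTED if min(study.cells) == 0 else ProportionRule.MLE


def _arm_estimates(study: Study2x2, rule: ProportionRule) -> tuple[float, float, int, int]:
    """(p_t, p_c, N_t, N_c): probabilities and the sample sizes entering variances.

    Under the adjusted rule n + 1 replaces n, matching the use of
    (x + 0.5)/(n + 1); the pair (p, N) then satisfies N*p = x + 0.5 and
    N*(1 - p) = n - x + 0.5.
    """
    p_t = estimate_proportion(study.x_t, study.n_t, rule)
    p_c = estimate_proportion(study.x_c, study.n_c, rule)
    if rule is ProportionRule.ADJUSTED:
        return p_t, p_c, study.n_t + 1, study.n_c + 1
    return p_t, p_c, study.n_t, study.n_c


def log_odds_ratio(study: Study2x2, rule: ProportionRule) -> float:
    """Study-level LOR log[p_t(1-p_c) / (p_c(1-p_t))] under the given rule."""
    if rule is ProportionRule.MLE and min(study.cells) == 0:
        raise ValueError(
            f"MLE log-odds-ratio undefined with a zero cell (study {study.id!r}); "
            "apply resolve_rule first"
        )
    p_t, p_c, _, _ = _arm_estimates(study, rule)
    return math.log(p_t / (1 - p_t)) - math.log(p_c / (1 - p_c))


def conditional_variance(study: Study2x2, rule: ProportionRule) -> float:
    """Delta-method variance of the LOR given the study's probabilities.

    1/(N_t p_t (1-p_t)) + 1/(N_c p_c (1-p_c)) with N = n (MLE) or n + 1
    (adjusted).  Equals the Woolf 1/a + 1/b + 1/c + 1/d form on the (possibly
    0.5-augmented) cells.
    """
    if rule is ProportionRule.MLE and min(study.cells) == 0:
        raise ValueError(
            f"MLE variance undefined with a zero cell (study {study.id!r})"
        )
    p_t, p_c, N_t, N_c = _arm_estimates(study, rule)
    return 1.0 / (N_t * p_t * (1 - p_t)) + 1.0 / (N_c * p_c * (1 - p_c))


def inflation_factor(study: Study2x2, p_t: float, rule: ProportionRule = ProportionRule.ADJUSTED) -> float:
    """Multiplier C_i of tau2 in the unconditional variance of the LOR.

    C_i = 1 + [ (p_t(1-p_t))^{-1} - 2 ] / (2 N_t), with N_t = n_t + 1 under
    the adjusted rule.  It arises from averaging the conditional variance over
    the random study effect: the second derivative of [N_t p(1-p)]^{-1} with
    respect to the effect (on the logit scale) is [(p(1-p))^{-1} - 2]/N_t, so
    a second-order expansion contributes tau2/2 times that amount.  Since
    p(1-p) <= 1/4, C_i >= 1 always, and C_i -> 1 as the arm grows.
    """
    if not (0.0 < p_t < 1.0):
        raise ValueError("p_t must lie strictly in (0, 1)")
    N_t = study.n_t + 1 if rule is ProportionRule.ADJUSTED else study.n_t
    return 1.0 + (1.0 / (p_t * (1 - p_t)) - 2.0) / (2.0 * N_t)


def _uncond_components(
    study: Study2x2, variant: VarianceVariant, theta_pooled: float | None = None
) -> tuple[float, float]:
    """(E v_i^2, C_i): the two terms of the unconditional variance E v^2 + tau2*C.

    Both use the adjusted proportions (n + 1 in denominators).  The
    treatment-arm probability is either the study's own adjusted estimate
    (naive) or expit(logit(p_c) + theta_pooled) (model-based).
    """
    if variant is VarianceVariant.CONDITIONAL:
        raise ValueError("use conditional_variance for the conditional variant")
    p_c = estimate_proportion(study.x_c, study.n_c, ProportionRule.ADJUSTED)
    if variant is VarianceVariant.UNCOND_MODEL:
        if theta_pooled is None:
            raise ValueError("model-based variant requires a pooled LOR estimate")
        p_t = float(expit(logit(p_c) + theta_pooled))
    else:
        p_t = estimate_proportion(study.x_t, study.n_t, ProportionRule.ADJUSTED)
    N_t, N_c = study.n_t + 1, study.n_c + 1
    ev = 1.0 / (N_t * p_t * (1 - p_t)) + 1.0 / (N_c * p_c * (1 - p_c))
    c_i = 1.0 + (1.0 / (p_t * (1 - p_t)) - 2.0) / (2.0 * N_t)
    return ev, c_i


def unconditional_variance(
    study: Study2x2,
    tau2: float,
    variant: VarianceVariant,
    theta_pooled: float | None = None,
) -> float:
    """Unconditional variance E v_i^2 + tau2 * C_i of the study LOR."""
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    ev, c_i = _uncond_components(study, variant, theta_pooled)
    return ev + tau2 * c_i


def effective_sample_size(study: Study2x2) -> float:
    """n_tilde = n_c * n_t / (n_c + n_t); the fixed weight of the study in QF."""
    return study.n_c * study.n_t / (study.n_c + study.n_t)


def filter_studies(
    studies: Iterable[Study2x2],
) -> tuple[list[Study2x2], list[Study2x2]]:
    """Drop double-zero and double-n studies; return (kept, dropped) in order."""
    kept: list[Study2x2] = []
    dropped: list[Study2x2] = []
    for s in studies:
        (dropped if (s.double_zero or s.double_n) else kept).append(s)
    return kept, dropped


@dataclass(frozen=True)
class StudySummary:
    """Derived per-study quantities feeding the Q statistics and estimators."""

    study: Study2x2
    theta_hat: float  # LOR estimate under the rule in force
    v2_cond: float  # conditional (delta-method) variance estimate
    n_tilde: float  # effective sample size, the fixed weight in QF
    rule_used: ProportionRule

    @property
    def v2_uncond(self) -> float:
        """Naive E v_i^2 (the tau2-free term of the unconditional variance)."""
        return _uncond_components(self.study, VarianceVariant.UNCOND_NAIVE)[0]

    @property
    def c_i(self) -> float:
        """Naive inflation factor C_i multiplying tau2."""
        return _uncond_components(self.study, VarianceVariant.UNCOND_NAIVE)[1]


def summarize_studies(
    studies: Sequence[Study2x2], policy: ZeroPolicy
) -> list[StudySummary]:
    """Compute per-study LOR, variance and weight under a 0.5-adding policy.

    Degenerate (double-zero / double-n) studies must have been filtered out;
    they trigger an error here under the MLE rule.
    """
    out = []
    for s in studies:
        rule = resolve_rule(s, policy)
        out.append(
            StudySummary(
                study=s,
                theta_hat=log_odds_ratio(s, rule),
                v2_cond=conditional_variance(s, rule),
                n_tilde=effective_sample_size(s),
                rule_used=rule,
            )
        )
    return out


def uncond_terms(
    summaries: Sequence[StudySummary],
    variant: VarianceVariant,
    theta_pooled: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (E v_i^2, C_i) for all studies under an unconditional variant."""
    ev, ci = zip(
        *(_uncond_components(s.study, variant, theta_pooled) for s in summaries)
    )
    return np.asarray(ev), np.asarray(ci)


# ---------------------------------------------------------------------------
# Delimited-text I/O

_COLUMNS = ["study", "x_t", "n_t", "x_c", "n_c"]


def read_studies(path) -> list[Study2x2]:
    """Read per-study 2x2 tables from delimited text.

    Expects a header row ``study,x_t,n_t,x_c,n_c`` (comma or tab, dialect
    auto-detected); blank lines are ignored and malformed rows are reported
    with their line number.
    """
    df = pd.read_csv(path, sep=None, engine="python", skip_blank_lines=True)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; "
                         f"expected header {','.join(_COLUMNS)}")
    studies = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            vals = {}
            for c in _COLUMNS[1:]:
                v = row[c]
                if pd.isna(v) or float(v) != int(float(v)):
                    raise ValueError(f"column {c} must be an integer, got {v!r}")
                vals[c] = int(float(v))
            studies.append(Study2x2(id=str(row["study"]), **vals))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return studies


def write_studies(studies: Sequence[Study2x2], path) -> None:
    """Write studies in the standard ``study,x_t,n_t,x_c,n_c`` CSV format."""
    df = pd.DataFrame(
        [(s.id, s.x_t, s.n_t, s.x_c, s.n_c) for s in studies], columns=_COLUMNS
    )
    df.to_csv(path, index=False)
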