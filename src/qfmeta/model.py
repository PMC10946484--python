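"""Model/results interface for random-effects meta-analysis of log-odds-ratio.

``MetaLogOddsRatio`` holds the per-study 2x2 tables (degenerate studies are
filtered on construction); ``fit`` runs the heterogeneity tests and the
requested tau2 point and interval estimators under a 0.5-adding policy and
returns a ``MetaLORResults`` with a ``summary()`` table and JSON-ready
serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import intervals as ci_mod
from .data import (
    Study2x2,
    VarianceVariant,
    ZeroPolicy,
    filter_studies,
    read_studies,
    summarize_studies,
)
from .intervals import INTERVAL_ESTIMATORS, Tau2Interval
from .point import POINT_ESTIMATORS, POINT_POLICY_TABLE, Tau2Estimate
from .qstats import i_squared, pooled_iv, pooled_ssw, q_f, q_iv
from .quadform import chisq_pvalue_qiv, qf_cdf

__all__ = ["MetaLogOddsRatio", "MetaLORResults", "analyze"]


class MetaLogOddsRatio:
    """Random-effects model for per-study 2x2 binary-outcome tables.

    Parameters
    ----------
    studies
        Per-study counts.  Double-zero and double-n studies are excluded from
        estimation (kept in ``dropped`` for reporting).
    """

    def __init__(self, studies: Sequence[Study2x2]):
        self.studies, self.dropped = filter_studies(studies)
        if len(self.studies) < 2:
            raise ValueError(
                f"need at least 2 usable studies, have {len(self.studies)} "
                f"after dropping {len(self.dropped)} degenerate"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MetaLogOddsRatio":
        """Build from a DataFrame with columns study, x_t, n_t, x_c, n_c."""
        studies = [
            Study2x2(id=str(r["study"]), x_t=int(r["x_t"]), n_t=int(r["n_t"]),
                     x_c=int(r["x_c"]), n_c=int(r["n_c"]))
            for _, r in df.iterrows()
        ]
        return cls(studies)

    @classmethod
    def from_csv(cls, path) -> "MetaLogOddsRatio":
        return cls(read_studies(path))

    @property
    def k(self) -> int:
        return len(self.studies)

    def fit(
        self,
        policy: ZeroPolicy | str = ZeroPolicy.ONLY,
        level: float = 0.95,
        methods: Sequence[str] | None = None,
        interval_methods: Sequence[str] | None = None,
    ) -> "MetaLORResults":
        """Estimate tau2 by every requested method and compute the Q tests.

        With ``methods=None`` the default battery follows the policy pairing:
        the unconditional estimators (SSU/SMU/FPU) are reported only under
        the "always" policy, matching their definition via the adjusted
        proportions.
        """
        policy = ZeroPolicy(policy)
        if methods is None:
            methods = [m for m, pols in POINT_POLICY_TABLE.items() if policy in pols]
        if interval_methods is None:
            interval_methods = ["QP", "PL", "FPC"]
            if policy is ZeroPolicy.ALWAYS:
                interval_methods += ["FPU model", "FPU naive"]
        summaries = summarize_studies(self.studies, policy)

        qiv = q_iv(summaries)
        qf = q_f(summaries)
        theta_ssw = pooled_ssw(summaries)
        theta_iv, se_iv = pooled_iv(summaries)

        tau2: dict[str, Tau2Estimate] = {}
        errors: dict[str, str] = {}
        for m in methods:
            try:
                tau2[m] = POINT_ESTIMATORS[m](summaries)
            except KeyError:
                raise KeyError(f"unknown point estimator {m!r}") from None
            except Exception as exc:  # per-method failure capture
                errors[m] = f"{type(exc).__name__}: {exc}"
        cis: dict[str, Tau2Interval] = {}
        for m in interval_methods:
            try:
                cis[m] = INTERVAL_ESTIMATORS[m](summaries, level=level)
            except KeyError:
                raise KeyError(f"unknown interval estimator {m!r}") from None
            except Exception as exc:
                errors[f"CI {m}"] = f"{type(exc).__name__}: {exc}"

        p_fssw = {
            "naive": 1.0 - qf_cdf(summaries, qf.q, 0.0, VarianceVariant.UNCOND_NAIVE),
            "model": 1.0 - qf_cdf(
                summaries, qf.q, 0.0, VarianceVariant.UNCOND_MODEL, theta_ssw
            ),
        }
        return MetaLORResults(
            model=self,
            policy=policy,
            level=level,
            q_iv=qiv.q,
            p_qiv=chisq_pvalue_qiv(qiv.q, self.k),
            i2=i_squared(qiv.q, self.k),
            q_f=qf.q,
            p_fssw_naive=p_fssw["naive"],
            p_fssw_model=p_fssw["model"],
            theta_iv=theta_iv,
            se_theta_iv=se_iv,
            theta_ssw=theta_ssw,
            tau2=tau2,
            intervals=cis,
            errors=errors,
        )


@dataclass
class MetaLORResults:
    """Fitted heterogeneity analysis: tests, pooled effects, tau2 estimates."""

    model: MetaLogOddsRatio
    policy: ZeroPolicy
    level: float
    q_iv: float
    p_qiv: float
    i2: float
    q_f: float
    p_fssw_naive: float
    p_fssw_model: float
    theta_iv: float
    se_theta_iv: float
    theta_ssw: float
    tau2: dict[str, Tau2Estimate] = field(default_factory=dict)
    intervals: dict[str, Tau2Interval] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.model.k

    def to_dict(self) -> dict:
        """JSON-serializable report (round-trips through json.dumps/loads)."""
        return {
            "k": self.k,
            "policy": self.policy.value,
            "level": self.level,
            "dropped": [s.id for s in self.model.dropped],
            "pooled": {
                "theta_iv": self.theta_iv,
                "se_theta_iv": self.se_theta_iv,
                "theta_ssw": self.theta_ssw,
            },
            "tests": {
                "q_iv": self.q_iv, "p_qiv": self.p_qiv, "i2": self.i2,
                "q_f": self.q_f, "p_fssw_naive": self.p_fssw_naive,
                "p_fssw_model": self.p_fssw_model,
            },
            "tau2": {
                m: {"value": e.value, "raw": e.raw, "converged": e.converged}
                for m, e in self.tau2.items()
            },
            "intervals": {
                m: {"lower": ci.lower, "upper": ci.upper, "status": ci.status.value}
                for m, ci in self.intervals.items()
            },
            "errors": self.errors,
        }

    def summary(self) -> str:
        """Plain-text report with 4-decimal values."""
        lines = [
            "Random-effects meta-analysis of log-odds-ratio",
            f"K = {self.k} studies"
            + (f" ({len(self.model.dropped)} degenerate dropped)" if self.model.dropped else ""),
            f"0.5-adding policy: {self.policy.value}",
            "",
            f"Pooled LOR (inverse-variance): {self.theta_iv:.4f} (SE {self.se_theta_iv:.4f})",
            f"Pooled LOR (fixed SSW weights): {self.theta_ssw:.4f}",
            "",
            f"Q_IV = {self.q_iv:.4f}  chi2({self.k - 1}) p = {self.p_qiv:.4f}  I2 = {self.i2:.2f}%",
            f"Q_F  = {self.q_f:.4f}  F-SSW p (naive) = {self.p_fssw_naive:.4f}"
            f"  (model) = {self.p_fssw_model:.4f}",
            "",
            "tau2 point estimates",
        ]
        for m, e in self.tau2.items():
            note = "" if e.converged else "  [not converged]"
            lines.append(f"  {m:<10s} {e.value:.4f}{note}")
        lines.append("")
        lines.append(f"tau2 {100 * self.level:.0f}% confidence intervals")
        for m, ci in self.intervals.items():
            note = "" if ci.status is ci_mod.IntervalStatus.OK else f"  [{ci.status.value}]"
            lines.append(f"  {m:<10s} [{ci.lower:.4f}, {ci.upper:.4f}]{note}")
        for m, msg in self.errors.items():
            lines.append(f"  {m}: FAILED ({msg})")
        return "\n".join(lines)


def analyze(
    studies: Sequence[Study2x2],
    policy: ZeroPolicy | str = ZeroPolicy.ONLY,
    methods: Sequence[str] | None = None,
    interval_methods: Sequence[str] | None = None,
    level: float = 0.95,
) -> MetaLORResults:
    """One-call analysis: filter studies, fit, and return the report object."""
    return MetaLogOddsRatio(studies).fit(
        policy=policy, level=level, methods=methods, interval_methods=interval_methods
    )
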