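"""Monte-Carlo study of the tau2 estimators under the binomial REM.

Data generation: study i has control probability pi_c (fixed), a true effect
theta_i ~ N(theta, tau2) on the log-odds scale, treatment probability
expit(logit(pi_c) + theta_i), and independent binomial counts in arms of
sizes n/2 each.  Double-zero and double-n studies are discarded, repetitions
with fewer than 3 surviving studies are dropped, and each requested
(estimator, policy) battery is evaluated on the rest.  Summaries are mean
bias, median bias P(tau2_hat >= tau2) - P(tau2_hat <= tau2), and for
intervals the coverage and the left/right miss rates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import Study2x2, ZeroPolicy, filter_studies, summarize_studies
from .intervals import INTERVAL_ESTIMATORS, Tau2Interval
from .point import POINT_ESTIMATORS

__all__ = [
    "Scenario",
    "ScenarioMetrics",
    "EQUAL_SIZES",
    "UNEQUAL_SIZES",
    "scenario_grid",
    "simulate_study",
    "simulate_meta",
    "run_scenario",
    "bias_metrics",
    "coverage_metrics",
]

THETA_GRID = (0.0, 0.1, 0.5, 1.0, 1.5, 2.0)
TAU2_GRID = tuple(round(0.1 * i, 1) for i in range(11))
K_GRID = (5, 10, 30)
PIC_GRID = (0.1, 0.2, 0.5)
EQUAL_SIZES = (20, 40, 100, 250)
#: Unequal five-study size sets keyed by their mean; skewness 1.464 pattern.
UNEQUAL_SIZES = {
    30: (12, 16, 18, 20, 84),
    60: (24, 32, 36, 40, 168),
    100: (64, 72, 76, 80, 208),
    160: (124, 132, 136, 140, 268),
}


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid."""

    theta: float
    tau2: float
    k: int
    sizes: tuple[int, ...]
    pi_c: float
    f: float = 0.5
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if len(self.sizes) != self.k:
            raise ValueError("sizes must have length k")
        if not (0 < self.pi_c < 1):
            raise ValueError("pi_c must be in (0, 1)")
        if self.reps < 1 or self.tau2 < 0:
            raise ValueError("invalid reps or tau2")

    @property
    def label(self) -> str:
        n = int(round(sum(self.sizes) / self.k))
        kind = "equal" if len(set(self.sizes)) == 1 else "unequal"
        return (f"theta={self.theta},tau2={self.tau2},K={self.k},n={n}({kind}),"
                f"piC={self.pi_c}")


def _sizes_for(k: int, base: Sequence[int] | int) -> tuple[int, ...]:
    if isinstance(base, int):
        return (base,) * k
    return tuple(base) * (k // len(base))


def scenario_grid(reps: int = 10_000, seed: int = 0) -> list[Scenario]:
    """The full factorial design: 6 theta x 11 tau2 x 3 K x 8 n x 3 piC = 4752."""
    size_specs: list[Sequence[int] | int] = list(EQUAL_SIZES) + list(UNEQUAL_SIZES.values())
    out = []
    for theta, tau2, k, spec, pi_c in itertools.product(
        THETA_GRID, TAU2_GRID, K_GRID, size_specs, PIC_GRID
    ):
        out.append(
            Scenario(theta=theta, tau2=tau2, k=k, sizes=_sizes_for(k, spec),
                     pi_c=pi_c, reps=reps, seed=seed)
        )
    return out


def simulate_study(
    n: int, f: float, pi_c: float, theta_i: float, rng: np.random.Generator, id: str = ""
) -> Study2x2:
    """Draw one study's 2x2 table: binomial counts in arms of sizes f*n and (1-f)*n."""
    n_c = int(round(f * n))
    n_t = n - n_c
    p_t = float(expit(logit(pi_c) + theta_i))
    x_c = int(rng.binomial(n_c, pi_c))
    x_t = int(rng.binomial(n_t, p_t))
    return Study2x2(x_t=x_t, n_t=n_t, x_c=x_c, n_c=n_c, id=id)


def _rep_rng(s: Scenario, rep_index: int) -> np.random.Generator:
    # one independent stream per (scenario seed, repetition): order-independent
    ss = np.random.SeedSequence(entropy=s.seed, spawn_key=(rep_index,))
    return np.random.default_rng(ss)


def simulate_meta(s: Scenario, rep_index: int) -> list[Study2x2]:
    """One repetition: draw theta_i ~ N(theta, tau2), simulate K studies, filter."""
    rng = _rep_rng(s, rep_index)
    thetas = s.theta + np.sqrt(s.tau2) * rng.standard_normal(s.k)
    studies = [
        simulate_study(n, s.f, s.pi_c, float(th), rng, id=str(i + 1))
        for i, (n, th) in enumerate(zip(s.sizes, thetas))
    ]
    kept, _ = filter_studies(studies)
    return kept


def bias_metrics(estimates: Sequence[float], tau2_true: float) -> tuple[float, float]:
    """(mean bias, median bias); ties at tau2_true count in both tails."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates")
    bias = float(est.mean() - tau2_true)
    med_bias = float(np.mean(est >= tau2_true) - np.mean(est <= tau2_true))
    return bias, med_bias


def coverage_metrics(
    intervals: Sequence[Tau2Interval], tau2_true: float
) -> tuple[float, float, float]:
    """(coverage, miss_left, miss_right): how often tau2_true falls in/below/above."""
    if len(intervals) == 0:
        raise ValueError("no intervals")
    left = np.mean([tau2_true < ci.lower for ci in intervals])
    right = np.mean([tau2_true > ci.upper for ci in intervals])
    return float(1.0 - left - right), float(left), float(right)


@dataclass
class ScenarioMetrics:
    """Aggregated per-scenario results for each requested estimator/interval."""

    scenario: Scenario
    reps_used: int
    reps_discarded: int
    point: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    interval: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    failures: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (estimator, policy) with its metrics."""
        rows = []
        base = {
            "theta": self.scenario.theta, "tau2": self.scenario.tau2,
            "K": self.scenario.k, "n_mean": sum(self.scenario.sizes) / self.scenario.k,
            "pi_c": self.scenario.pi_c, "reps_used": self.reps_used,
        }
        for (method, policy), stats in self.point.items():
            rows.append({**base, "kind": "point", "method": method, "policy": policy, **stats})
        for (method, policy), stats in self.interval.items():
            rows.append({**base, "kind": "interval", "method": method, "policy": policy, **stats})
        return pd.DataFrame(rows)


def run_scenario(
    s: Scenario,
    points: Iterable[tuple[str, str]] = (),
    intervals: Iterable[tuple[str, str]] = (),
    level: float = 0.95,
    progress: bool = False,
) -> ScenarioMetrics:
    """Run all repetitions of a scenario and aggregate the requested batteries.

    ``points`` and ``intervals`` are (method label, policy) pairs, e.g.
    ``[("SMC", "only"), ("DL", "always")]``.  A method that raises in one
    repetition is excluded from that repetition's aggregate (counted in
    ``failures``) without discarding the other methods.
    """
    points = [(m, ZeroPolicy(p)) for m, p in points]
    intervals = [(m, ZeroPolicy(p)) for m, p in intervals]
    for m, _ in points:
        if m not in POINT_ESTIMATORS:
            raise KeyError(f"unknown point estimator {m!r}")
    for m, _ in intervals:
        if m not in INTERVAL_ESTIMATORS:
            raise KeyError(f"unknown interval estimator {m!r}")
    policies = {p for _, p in points} | {p for _, p in intervals}

    est_values: dict[tuple[str, str], list[float]] = {
        (m, p.value): [] for m, p in points
    }
    ci_values: dict[tuple[str, str], list[Tau2Interval]] = {
        (m, p.value): [] for m, p in intervals
    }
    failures: dict[tuple[str, str], int] = {}
    used = discarded = 0
    iterator = range(s.reps)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm  # type: ignore

            iterator = tqdm(iterator, desc=s.label)
        except ImportError:
            pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for rep in iterator:
            studies = simulate_meta(s, rep)
            if len(studies) < 3:
                discarded += 1
                continue
            used += 1
            summaries = {p: summarize_studies(studies, p) for p in policies}
            for m, p in points:
                key = (m, p.value)
                try:
                    est_values[key].append(POINT_ESTIMATORS[m](summaries[p]).value)
                except Exception:
                    failures[key] = failures.get(key, 0) + 1
            for m, p in intervals:
                key = (m, p.value)
                try:
                    ci_values[key].append(INTERVAL_ESTIMATORS[m](summaries[p], level=level))
                except Exception:
                    failures[key] = failures.get(key, 0) + 1

    metrics = ScenarioMetrics(scenario=s, reps_used=used, reps_discarded=discarded,
                              failures=failures)
    for key, vals in est_values.items():
        if not vals:
            continue
        bias, med_bias = bias_metrics(vals, s.tau2)
        arr = np.asarray(vals)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        metrics.point[key] = {
            "bias": bias, "median_bias": med_bias, "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "q1": float(q1), "median": float(med), "q3": float(q3),
            "n_est": int(arr.size),
        }
    for key, cis in ci_values.items():
        if not cis:
            continue
        cov, left, right = coverage_metrics(cis, s.tau2)
        metrics.interval[key] = {
            "coverage": cov, "miss_left": left, "miss_right": right,
            "n_est": len(cis),
        }
    return metrics
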