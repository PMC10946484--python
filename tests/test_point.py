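import numpy as np
import pytest

from conftest import random_summaries
from qfmeta.data import StudySummary, VarianceVariant, ZeroPolicy, summarize_studies
from qfmeta.point import (
    POINT_ESTIMATORS,
    tau2_dl,
    tau2_mp,
    tau2_reml,
    tau2_smc,
    tau2_smu,
    tau2_ssc,
    tau2_ssu,
)
from qfmeta.qstats import expected_qf, q_f
from qfmeta.quadform import qf_cdf


def _override(summary, **kw):
    for k, v in kw.items():
        object.__setattr__(summary, k, v)
    return summary


def two_study_unit_variance():
    rng = np.random.default_rng(11)
    s = random_summaries(rng, k=2)
    _override(s[0], theta_hat=0.0, v2_cond=1.0)
    _override(s[1], theta_hat=2.0, v2_cond=1.0)
    return s


def equal_variance_summaries(k=8, v=0.5, seed=12):
    rng = np.random.default_rng(seed)
    s = random_summaries(rng, k=k)
    for x in s:
        _override(x, v2_cond=v, theta_hat=float(rng.normal(0.3, 0.8)))
    return s


def test_dl_hand_example():
    # Q=2, S1=2, S2=2 -> (2-1)/(2-1) = 1
    assert tau2_dl(two_study_unit_variance()).value == pytest.approx(1.0)


def test_dl_truncates_at_zero():
    rng = np.random.default_rng(13)
    s = random_summaries(rng, k=5)
    for x in s:
        _override(x, theta_hat=0.4)  # perfectly homogeneous
    est = tau2_dl(s)
    assert est.value == 0.0 and est.raw < 0


def test_reml_balanced_closed_form():
    """Equal within-study variances: REML = max(0, SS/(K-1) - v)."""
    s = equal_variance_summaries()
    th = np.array([x.theta_hat for x in s])
    closed = max(0.0, th.var(ddof=1) - 0.5)
    est = tau2_reml(s)
    assert est.converged
    assert est.value == pytest.approx(closed, abs=1e-7)


def test_mp_equals_reml_in_balanced_case():
    s = equal_variance_summaries(seed=14)
    th = np.array([x.theta_hat for x in s])
    closed = max(0.0, th.var(ddof=1) - 0.5)
    assert tau2_mp(s).value == pytest.approx(closed, abs=1e-6)


def test_mp_zero_when_q_below_df():
    rng = np.random.default_rng(15)
    s = random_summaries(rng, k=5)
    for x in s:
        _override(x, theta_hat=0.4)
    assert tau2_mp(s).value == 0.0


def test_ssc_inversion_identity(het_summaries):
    est = tau2_ssc(het_summaries)
    assert est.raw > 0
    assert expected_qf(het_summaries, est.raw) == pytest.approx(
        q_f(het_summaries).q, abs=1e-8
    )


def test_ssu_inversion_identity(het_summaries):
    for variant in (VarianceVariant.UNCOND_MODEL, VarianceVariant.UNCOND_NAIVE):
        est = tau2_ssu(het_summaries, variant)
        assert est.raw > 0
        assert expected_qf(het_summaries, est.raw, variant) == pytest.approx(
            q_f(het_summaries).q, abs=1e-8
        )


def test_ssu_close_to_ssc_for_large_studies(het_summaries):
    """The two moment estimators differ by O(1/n) terms only."""
    ssc = tau2_ssc(het_summaries).value
    ssu = tau2_ssu(het_summaries, VarianceVariant.UNCOND_NAIVE).value
    assert ssu == pytest.approx(ssc, abs=0.02)
    assert ssu != ssc


def test_smc_root_contract(het_summaries):
    est = tau2_smc(het_summaries)
    assert est.value > 0 and est.converged
    f = qf_cdf(het_summaries, q_f(het_summaries).q, est.value)
    assert abs(f - 0.5) <= 1e-6


def test_smc_truncates_when_median_below_observed():
    rng = np.random.default_rng(16)
    s = random_summaries(rng, k=6)
    for x in s:
        _override(x, theta_hat=0.4)  # QF = 0 < any median
    assert tau2_smc(s).value == 0.0


def test_smu_root_contract_and_degenerate_identity(het_summaries, monkeypatch):
    est = tau2_smu(het_summaries, VarianceVariant.UNCOND_MODEL)
    f = qf_cdf(
        het_summaries, q_f(het_summaries).q, est.value, VarianceVariant.UNCOND_MODEL
    )
    assert abs(f - 0.5) <= 1e-6
    # forcing Ev^2 = v^2 and C = 1 collapses SMU onto SMC
    import qfmeta.qstats as qstats

    def fake_uncond_terms(summaries, variant, theta_pooled=None):
        v2 = np.array([s.v2_cond for s in summaries])
        return v2, np.ones_like(v2)

    monkeypatch.setattr(qstats, "uncond_terms", fake_uncond_terms)
    smu = tau2_smu(het_summaries, VarianceVariant.UNCOND_NAIVE)
    smc = tau2_smc(het_summaries)
    assert smu.value == pytest.approx(smc.value, abs=1e-7)


def test_estimators_permutation_invariant(het_summaries):
    rng = np.random.default_rng(17)
    perm = list(rng.permutation(len(het_summaries)))
    shuffled = [het_summaries[i] for i in perm]
    for name, fn in POINT_ESTIMATORS.items():
        a, b = fn(het_summaries).value, fn(shuffled).value
        assert a == pytest.approx(b, abs=1e-9), name


def test_requires_two_studies(het_summaries):
    for fn in (tau2_dl, tau2_reml, tau2_mp, tau2_smc):
        with pytest.raises(ValueError):
            fn(het_summaries[:1])


@pytest.mark.parametrize("fixture_name", ["stead_like", "sparse"])
@pytest.mark.parametrize("policy", ["only", "always"])
def test_classical_estimators_match_metafor(
    metafor, fixture_name, policy, stead_like_studies, sparse_studies
):
    """DL/REML/MP and the fixed-weights moment estimator vs the R reference."""
    studies = {"stead_like": stead_like_studies, "sparse": sparse_studies}[fixture_name]
    ref = metafor[(fixture_name, policy)]
    s = summarize_studies(studies, ZeroPolicy(policy))
    assert tau2_dl(s).value == pytest.approx(ref["DL"], abs=1e-8)
    assert tau2_ssc(s).value == pytest.approx(ref["GENQ"], abs=1e-8)
    assert tau2_reml(s).value == pytest.approx(ref["REML"], abs=1e-6)
    assert tau2_mp(s).value == pytest.approx(ref["PM"], abs=1e-5)
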