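import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qfmeta.data import (
    ProportionRule,
    Study2x2,
    VarianceVariant,
    ZeroPolicy,
    conditional_variance,
    effective_sample_size,
    estimate_proportion,
    filter_studies,
    inflation_factor,
    log_odds_ratio,
    read_studies,
    resolve_rule,
    summarize_studies,
    unconditional_variance,
    write_studies,
)

MLE, ADJ = ProportionRule.MLE, ProportionRule.ADJUSTED


def study(x_t, n_t, x_c, n_c, id=""):
    return Study2x2(x_t=x_t, n_t=n_t, x_c=x_c, n_c=n_c, id=id)


# strategy: arbitrary legal 2x2 study, excluding degenerate double-zero/double-n
@st.composite
def studies_st(draw, max_n=60, degenerate_ok=False):
    n_t = draw(st.integers(1, max_n))
    n_c = draw(st.integers(1, max_n))
    x_t = draw(st.integers(0, n_t))
    x_c = draw(st.integers(0, n_c))
    s = study(x_t, n_t, x_c, n_c)
    if not degenerate_ok and (s.double_zero or s.double_n):
        x_t = max(1, min(x_t, n_t - 1))
        s = study(x_t, n_t, x_c, n_c)
    return s


@pytest.mark.parametrize(
    "x,n,rule,expected",
    [
        (5, 10, MLE, 0.5),
        (0, 10, ADJ, 0.5 / 11),
        (10, 10, ADJ, 10.5 / 11),
        (0, 10, MLE, 0.0),
    ],
)
def test_estimate_proportion(x, n, rule, expected):
    assert estimate_proportion(x, n, rule) == pytest.approx(expected, abs=1e-12)


def test_estimate_proportion_rejects_bad_counts():
    with pytest.raises(ValueError):
        estimate_proportion(11, 10, MLE)
    with pytest.raises(ValueError):
        estimate_proportion(0, 0, ADJ)


@pytest.mark.parametrize(
    "s,policy,expected",
    [
        (study(3, 10, 2, 10), ZeroPolicy.ONLY, MLE),
        (study(0, 10, 2, 10), ZeroPolicy.ONLY, ADJ),
        (study(3, 10, 10, 10), ZeroPolicy.ONLY, ADJ),  # zero non-events
        (study(3, 10, 2, 10), ZeroPolicy.ALWAYS, ADJ),
    ],
)
def test_resolve_rule(s, policy, expected):
    assert resolve_rule(s, policy) is expected


def test_log_odds_ratio_values():
    assert log_odds_ratio(study(5, 10, 5, 10), MLE) == 0.0
    assert log_odds_ratio(study(3, 10, 1, 10), MLE) == pytest.approx(
        math.log(27 / 7), rel=1e-12
    )


@given(studies_st())
@settings(max_examples=50, deadline=None)
def test_log_odds_ratio_antisymmetric_in_arms(s):
    swapped = study(s.x_c, s.n_c, s.x_t, s.n_t)
    assert log_odds_ratio(s, ADJ) == pytest.approx(-log_odds_ratio(swapped, ADJ))


def test_mle_with_zero_cell_raises():
    with pytest.raises(ValueError):
        log_odds_ratio(study(0, 10, 2, 10), MLE)
    with pytest.raises(ValueError):
        conditional_variance(study(3, 10, 10, 10), MLE)


def test_conditional_variance_values():
    # 1/(10*0.25) + 1/(10*0.25)
    assert conditional_variance(study(5, 10, 5, 10), MLE) == pytest.approx(0.8)
    v = conditional_variance(study(0, 10, 2, 10), ADJ)
    assert np.isfinite(v) and v > 0
    # Woolf form on 0.5-augmented cells
    assert v == pytest.approx(1 / 0.5 + 1 / 10.5 + 1 / 2.5 + 1 / 8.5, rel=1e-12)


def test_conditional_variance_halves_when_arms_double():
    v1 = conditional_variance(study(3, 10, 2, 10), MLE)
    v2 = conditional_variance(study(6, 20, 4, 20), MLE)
    assert v2 == pytest.approx(v1 / 2, rel=1e-12)


@given(studies_st())
@settings(max_examples=50, deadline=None)
def test_adjusted_variance_symmetric_in_events_nonevents(s):
    flipped = study(s.n_t - s.x_t, s.n_t, s.n_c - s.x_c, s.n_c)
    assert conditional_variance(s, ADJ) == pytest.approx(
        conditional_variance(flipped, ADJ), rel=1e-12
    )


@given(studies_st(degenerate_ok=True))
@settings(max_examples=100, deadline=None)
def test_estimates_finite_for_every_policy_and_study(s):
    for policy in ZeroPolicy:
        rule = resolve_rule(s, policy)
        assert np.isfinite(log_odds_ratio(s, rule))
        assert conditional_variance(s, rule) > 0


def test_inflation_factor_properties():
    s_small = study(5, 50, 5, 50)
    s_large = study(5, 10**9, 5, 10**9)
    assert inflation_factor(s_large, 0.3) == pytest.approx(1.0, abs=1e-7)
    ci_vals = [
        inflation_factor(study(5, n, 5, n), 0.2) for n in (20, 50, 200, 1000)
    ]
    assert all(c >= 1 for c in ci_vals)
    assert sorted(ci_vals, reverse=True) == ci_vals  # non-increasing in n_t
    # transcription cross-check: equivalent algebraic form (1 - 2pq)/(2 N pq)
    p, n = 0.5, 50
    expected = 1 + (1 - 2 * p * (1 - p)) / (2 * (n + 1) * p * (1 - p))
    assert inflation_factor(s_small, p) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        inflation_factor(s_small, 1.0)


def test_unconditional_naive_at_zero_tau2_is_adjusted_conditional():
    rng = np.random.default_rng(0)
    for _ in range(5):
        n_t, n_c = rng.integers(10, 200, size=2)
        s = study(int(rng.integers(0, n_t + 1)), int(n_t),
                  int(rng.integers(1, n_c)), int(n_c))
        assert unconditional_variance(s, 0.0, VarianceVariant.UNCOND_NAIVE) == (
            pytest.approx(conditional_variance(s, ADJ), rel=1e-12)
        )


def test_unconditional_variance_linear_in_tau2_with_slope_ci():
    s = study(8, 60, 5, 55)
    p_t = estimate_proportion(8, 60, ADJ)
    slope = inflation_factor(s, p_t)
    v0 = unconditional_variance(s, 0.0, VarianceVariant.UNCOND_NAIVE)
    for tau2 in (0.1, 0.5, 2.0):
        v = unconditional_variance(s, tau2, VarianceVariant.UNCOND_NAIVE)
        assert v == pytest.approx(v0 + tau2 * slope, rel=1e-12)


def test_model_variant_requires_pooled_effect():
    with pytest.raises(ValueError):
        unconditional_variance(study(3, 10, 2, 10), 0.1, VarianceVariant.UNCOND_MODEL)


def test_conditional_and_unconditional_converge_for_large_arms():
    gaps = []
    for scale in (1, 10, 100):
        s = study(30 * scale, 100 * scale, 20 * scale, 100 * scale)
        gap = abs(
            unconditional_variance(s, 0.0, VarianceVariant.UNCOND_NAIVE)
            - conditional_variance(s, MLE)
        )
        gaps.append(gap)
    assert gaps[0] > gaps[1] > gaps[2]


def test_effective_sample_size():
    assert effective_sample_size(study(1, 10, 1, 10)) == 5
    assert effective_sample_size(study(1, 84, 1, 84)) == 42
    s = study(1, 30, 1, 100)
    assert effective_sample_size(s) <= min(s.n_t, s.n_c)


def test_filter_studies():
    dz = study(0, 10, 0, 12)
    dn = study(10, 10, 12, 12)
    ok = study(3, 10, 1, 10)
    kept, dropped = filter_studies([dz, ok, dn])
    assert kept == [ok] and dropped == [dz, dn]
    kept2, dropped2 = filter_studies([ok])
    assert kept2 == [ok] and not dropped2


def test_summaries_respect_policy(sparse_studies):
    only = summarize_studies(sparse_studies, ZeroPolicy.ONLY)
    always = summarize_studies(sparse_studies, ZeroPolicy.ALWAYS)
    assert any(s.rule_used is MLE for s in only)
    assert all(s.rule_used is ADJ for s in always)
    # weights never depend on the policy
    assert [s.n_tilde for s in only] == [s.n_tilde for s in always]


def test_read_write_roundtrip(tmp_path, stead_like_studies):
    path = tmp_path / "studies.csv"
    write_studies(stead_like_studies, path)
    back = read_studies(path)
    assert back == stead_like_studies


def test_reader_tab_dialect_and_blank_lines(tmp_path):
    path = tmp_path / "studies.tsv"
    path.write_text("study\tx_t\tn_t\tx_c\tn_c\nA\t3\t10\t1\t12\n\nB\t0\t8\t2\t9\n")
    studies = read_studies(path)
    assert len(studies) == 2 and studies[0].n_c == 12


def test_reader_errors_name_the_problem(tmp_path):
    p1 = tmp_path / "missing.csv"
    p1.write_text("study,x_t,n_t,x_c\nA,1,2,3\n")
    with pytest.raises(ValueError, match="n_c"):
        read_studies(p1)
    p2 = tmp_path / "bad.csv"
    p2.write_text("study,x_t,n_t,x_c,n_c\nA,1,10,2,12\nB,1.5,10,2,12\n")
    with pytest.raises(ValueError, match="line 3"):
        read_studies(p2)
    p3 = tmp_path / "over.csv"
    p3.write_text("study,x_t,n_t,x_c,n_c\nA,11,10,2,12\n")
    with pytest.raises(ValueError, match="line 2"):
        read_studies(p3)
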