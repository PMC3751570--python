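"""Kaplan-Meier, log-rank and Cox: closed forms, hand tables, recovery."""

import numpy as np
import pandas as pd
import pytest

from bsitrack.cohort import round_half_up
from bsitrack.survival import (
    SurvivalError,
    cox_fit,
    kaplan_meier,
    log_rank,
    two_year_survival,
)


def test_km_three_deaths_no_censoring():
    km = kaplan_meier([1, 2, 3], [1, 1, 1])
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    assert list(km.at_risk) == [3, 2, 1]


def test_km_all_censored_stays_at_one():
    km = kaplan_meier([5, 8, 12], [0, 0, 0])
    assert km.event_times.size == 0
    assert km.at(100.0) == 1.0


def test_km_matches_hand_computed_product_limit_table():
    """8-record fixture worked through the product-limit formula by hand."""
    time = [1, 3, 3, 5, 8, 10, 12, 14]
    event = [1, 1, 0, 1, 1, 0, 1, 0]
    km = kaplan_meier(time, event)
    assert list(km.event_times) == [1, 3, 5, 8, 12]
    assert np.allclose(km.survival, [7 / 8,
                                     7 / 8 * 6 / 7,
                                     7 / 8 * 6 / 7 * 4 / 5,
                                     7 / 8 * 6 / 7 * 4 / 5 * 3 / 4,
                                     7 / 8 * 6 / 7 * 4 / 5 * 3 / 4 * 1 / 2])
    assert list(km.at_risk) == [8, 7, 5, 4, 2]


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(2)
    t = rng.exponential(10, size=40).round(1) + 0.1
    km = kaplan_meier(t, np.ones_like(t))
    for q in [1.0, 5.0, 12.0]:
        assert km.at(q) == pytest.approx((t > q).mean())


def test_logrank_identical_groups_is_null():
    t = [2, 4, 6, 8]
    e = [1, 1, 0, 1]
    stat, p = log_rank(t + t, e + e, [0] * 4 + [1] * 4)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_brute_force_tabulation():
    """Independent O-E tabulation over every event time, 10-record fixture."""
    time = np.array([1, 2, 3, 4, 5, 2, 4, 6, 8, 10], dtype=float)
    event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0], dtype=bool)
    group = np.array([0] * 5 + [1] * 5)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(time[event])):
        n = (time >= t).sum()
        n1 = ((time >= t) & (group == 1)).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    expected = o_minus_e ** 2 / var
    stat, p = log_rank(time, event, group)
    assert stat == pytest.approx(expected, abs=1e-12)
    assert 0 <= p <= 1


def test_logrank_agrees_with_lifelines():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(3)
    t = rng.exponential(12, 30).round(0) + 1
    e = rng.random(30) < 0.7
    g = rng.integers(0, 2, 30)
    stat, p = log_rank(t, e, g)
    ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
    assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
    assert p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_invariant_to_group_swap():
    t = [1, 2, 3, 4, 5, 6]
    e = [1, 0, 1, 1, 0, 1]
    g = [0, 1, 0, 1, 0, 1]
    s1, _ = log_rank(t, e, g)
    s2, _ = log_rank(t, e, [1 - x for x in g])
    assert s1 == pytest.approx(s2)
    assert s1 >= 0


def test_logrank_requires_two_groups():
    with pytest.raises(SurvivalError, match="2 groups"):
        log_rank([1, 2], [1, 1], [0, 0])


def test_cox_insufficient_events_rejected():
    df = pd.DataFrame({"time_months": [3.0, 8.0], "event": [1, 0], "x": [0.0, 1.0]})
    with pytest.raises(SurvivalError, match="events"):
        cox_fit(df, "x")


def test_cox_constant_covariate_rejected():
    df = pd.DataFrame({"time_months": [1, 2, 3, 4.0], "event": [1, 1, 1, 1],
                       "x": [2.0, 2.0, 2.0, 2.0]})
    with pytest.raises(SurvivalError, match="constant"):
        cox_fit(df, "x")


def test_cox_recovers_generating_coefficient():
    """Exponential hazards with log-HR 0.02 per covariate unit, n = 300."""
    rng = np.random.default_rng(5)
    x = rng.normal(0, 10, 300)
    t = rng.exponential(1.0 / (0.05 * np.exp(0.02 * x)))
    df = pd.DataFrame({"time_months": np.clip(t, 1e-3, None),
                       "event": np.ones(300, dtype=bool), "x": x})
    res = cox_fit(df, "x")
    assert abs(res.coefficient - 0.02) <= 3 * res.se
    assert res.ci_low < res.hazard_ratio < res.ci_high


def test_two_year_survival_reproduces_reported_proportions():
    """3/17 alive -> 18%; 8/14 alive -> 57% (no censoring before 24 months)."""
    rows = []
    for k in range(17):
        alive = k < 3
        rows.append({"time_months": 27.0 if alive else 2.0 + k, "event": not alive,
                     "grp": "increase"})
    for k in range(14):
        alive = k < 8
        rows.append({"time_months": 30.0 if alive else 3.0 + k, "event": not alive,
                     "grp": "decrease"})
    df = pd.DataFrame(rows)
    out = two_year_survival(df, "grp")
    assert round_half_up(out["increase"]) == 18
    assert round_half_up(out["decrease"]) == 57


def test_two_year_survival_all_alive_is_100():
    df = pd.DataFrame({"time_months": [30.0, 40.0], "event": [False, False],
                       "grp": ["a", "a"]})
    assert two_year_survival(df, "grp")["a"] == 100.0


def test_null_association_gives_uniform_logrank_p(atlas):
    """With a zero log-hazard coefficient the BSI-direction groups have
    indistinguishable survival: log-rank p is not enriched below 0.05."""
    from bsitrack import simulate_cohort

    pvals = []
    for rep in range(60):
        table, _, _ = simulate_cohort(50, 0.5, survival_model=(0.04, 0.0),
                                      seed=5000 + rep, atlas=atlas, imaging=False)
        grp = table["bsi_pct_change"] > 0
        if grp.nunique() < 2 or not table["event"].any():
            continue
        _, p = log_rank(table["time_months"], table["event"], grp)
        pvals.append(p)
    pvals = np.asarray(pvals)
    assert len(pvals) >= 50
    # ~5% expected below 0.05; allow generous binomial slack
    assert (pvals < 0.05).mean() <= 0.15
    assert pvals.mean() == pytest.approx(0.5, abs=0.2)
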