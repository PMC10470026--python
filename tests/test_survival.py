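"""Survival primitives against brute-force oracles and reference libraries."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from tmtme.survival import (
    NoEventsError,
    NonIdentifiableError,
    SurvivalData,
    ValidationError,
    fit_cox,
    km_estimate,
    logrank_test,
    td_roc,
    univariate_cox_screen,
)

from oracles import brute_cox_1d, km_by_hand, logrank_2group, pairwise_auc

# single-covariate datasets (time, event, x) with finite maximizers,
# with and without tied event times
COX_FIXTURES = [
    ([1, 2, 3, 4], [1, 1, 1, 1], [1, 0, 1, 0]),
    ([1, 1, 2, 3], [1, 1, 1, 0], [0, 1, 1, 0]),
    ([2, 2, 2, 1, 3], [1, 1, 0, 1, 1], [1, 0, 1, 0, 1]),
    ([1, 2, 2, 3, 4, 5], [1, 0, 1, 1, 0, 1], [2, 1, 0, 1, 2, 0]),
    ([1, 1, 1, 2], [1, 1, 1, 1], [1, 0, 1, 0]),
    ([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], [0, 1, 0, 1, 1, 0]),
]


def _sv(time, event):
    ids = np.array([f"s{i}" for i in range(len(time))], dtype=object)
    return SurvivalData(ids, time, event)


@pytest.mark.parametrize("time,event,x", COX_FIXTURES)
def test_cox_matches_brute_force_1d_maximizer(time, event, x):
    fit = fit_cox(np.asarray(x, float)[:, None], _sv(time, event))
    oracle = brute_cox_1d(x, time, event)
    assert abs(oracle) < 9, "fixture must have an interior maximizer"
    assert fit.converged
    assert fit.coefficients[0] == pytest.approx(oracle, abs=1e-4)


def test_cox_agrees_with_lifelines_on_censored_data():
    rng = np.random.default_rng(3)
    n = 150
    X = rng.normal(size=(n, 3))
    T = rng.exponential(1.0 / (0.05 * np.exp(X @ [0.6, -0.4, 0.0])))
    C = rng.exponential(30.0, n)
    t, e = np.minimum(T, C), (T <= C).astype(int)
    fit = fit_cox(pd.DataFrame(X, columns=list("abc")), _sv(t, e))
    df = pd.DataFrame(X, columns=list("abc")).assign(T=t, E=e)
    ref = CoxPHFitter().fit(df, "T", "E")
    np.testing.assert_allclose(fit.coefficients, ref.params_.values, atol=1e-4)
    np.testing.assert_allclose(fit.standard_errors, ref.standard_errors_.values,
                               atol=1e-4)


def test_cox_negating_covariate_negates_coefficient():
    time, event, x = COX_FIXTURES[3]
    x = np.asarray(x, float)[:, None]
    a = fit_cox(x, _sv(time, event))
    b = fit_cox(-x, _sv(time, event))
    assert a.coefficients[0] == pytest.approx(-b.coefficients[0], abs=1e-12)


def test_cox_degenerate_inputs():
    sv = _sv([1, 2, 3, 4], [1, 1, 0, 1])
    with pytest.raises(NonIdentifiableError, match="x0"):
        fit_cox(np.ones((4, 1)), sv)
    with pytest.raises(NoEventsError):
        fit_cox(np.arange(4.0)[:, None], _sv([1, 2, 3, 4], [0, 0, 0, 0]))


# ---------------------------------------------------------------------------


def test_km_hand_values(toy_survival):
    km = km_estimate(toy_survival)
    np.testing.assert_array_equal(km.event_times, [1.0, 3.0])
    np.testing.assert_allclose(km.survival, [0.75, 0.375], atol=1e-12)
    assert km.evaluate([2.5])[0] == pytest.approx(0.75)


def test_km_no_events_and_full_followup():
    km = km_estimate(_sv([1, 2, 3], [0, 0, 0]))
    assert km.event_times.size == 0
    assert km.evaluate([0.5, 2.5]).tolist() == [1.0, 1.0]
    km = km_estimate(_sv([1, 2, 3, 4], [1, 1, 1, 1]))
    np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0], atol=1e-12)


def test_km_matches_hand_loop_and_lifelines_on_random_data():
    rng = np.random.default_rng(11)
    t = rng.exponential(10, 80).round(1) + 0.1
    e = rng.integers(0, 2, 80)
    km = km_estimate(_sv(t, e))
    ot, os_ = km_by_hand(t, e)
    np.testing.assert_array_equal(km.event_times, ot)
    np.testing.assert_allclose(km.survival, os_, atol=1e-12)
    ref = KaplanMeierFitter().fit(t, e)
    np.testing.assert_allclose(km.evaluate(km.event_times),
                               ref.predict(km.event_times).to_numpy(), atol=1e-10)
    # reconstruction identity: S_k = prod (1 - d/n)
    np.testing.assert_allclose(
        km.survival, np.cumprod(1 - km.n_events_at / km.at_risk), atol=1e-12)
    assert (np.diff(km.survival) <= 1e-15).all()
    assert ((km.survival >= 0) & (km.survival <= 1)).all()


def test_km_empty_group_rejected(toy_survival):
    with pytest.raises(ValidationError):
        km_estimate(toy_survival, np.array(["g1", "g1", "g1"], dtype=object))


# ---------------------------------------------------------------------------


def test_logrank_mirrored_groups_is_zero():
    t = [1, 2, 3, 4, 1, 2, 3, 4]
    e = [1, 0, 1, 1, 1, 0, 1, 1]
    g = ["A"] * 4 + ["B"] * 4
    res = logrank_test(_sv(t, e), g)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def test_logrank_two_group_matches_hand_table():
    t = [1, 2, 3, 4]
    e = [1, 1, 1, 1]
    g = np.array(["A", "A", "B", "B"])
    res = logrank_test(_sv(t, e), g)
    assert res.statistic == pytest.approx(logrank_2group(t, e, g), abs=1e-12)


def test_logrank_matches_lifelines_three_groups():
    rng = np.random.default_rng(5)
    n = 120
    t = rng.exponential(10, n)
    e = rng.integers(0, 2, n)
    e[t.argmax()] = 1
    g = rng.integers(0, 3, n)
    res = logrank_test(_sv(t, e), g)
    ref = multivariate_logrank_test(t, g, e)
    assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
    assert res.p_value == pytest.approx(ref.p_value, abs=1e-9)
    assert res.df == 2


def test_logrank_single_group_rejected(toy_survival):
    with pytest.raises(ValidationError):
        logrank_test(toy_survival, np.array(["A"] * 4, dtype=object))


# ---------------------------------------------------------------------------


def test_td_roc_uninformative_and_reversed_scores():
    rng = np.random.default_rng(9)
    t = rng.exponential(10, 60)
    e = np.ones(60, int)
    sv = _sv(t, e)
    flat = td_roc(np.zeros(60), sv, np.median(t))
    assert flat.auc == pytest.approx(0.5, abs=1e-12)
    s = rng.normal(size=60)
    a = td_roc(s, sv, np.median(t)).auc
    b = td_roc(-s, sv, np.median(t)).auc
    assert a == pytest.approx(1 - b, abs=1e-12)


def test_td_roc_equals_pairwise_auc_without_censoring():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        t = rng.exponential(10, n).round(1) + 0.1
        s = rng.normal(size=n).round(1)  # ties likely
        sv = _sv(t, np.ones(n, int))
        hz = float(np.median(t))
        if (t <= hz).sum() == 0 or (t > hz).sum() == 0:
            continue
        r = td_roc(s, sv, hz)
        assert r.auc == pytest.approx(pairwise_auc(s[t <= hz], s[t > hz]), abs=1e-10)


def test_td_roc_matches_scikit_survival_under_censoring():
    from sksurv.metrics import cumulative_dynamic_auc

    rng = np.random.default_rng(17)
    n = 250
    T = rng.exponential(100, n)
    C = rng.exponential(150, n)
    t, e = np.minimum(T, C), (T <= C).astype(int)
    s = rng.normal(size=n) - 0.01 * t
    sv = _sv(t, e)
    y = sv.to_structured()
    for hz in (50.0, 120.0):
        mine = td_roc(s, sv, hz).auc
        ref, _ = cumulative_dynamic_auc(y, y, s, [hz])
        assert mine == pytest.approx(ref[0], abs=1e-10)


def test_td_roc_monotone_curve_and_errors():
    rng = np.random.default_rng(2)
    t = rng.exponential(10, 40)
    sv = _sv(t, np.ones(40, int))
    r = td_roc(rng.normal(size=40), sv, np.median(t))
    assert (np.diff(r.sensitivities) >= -1e-15).all()
    assert (np.diff(r.specificities) <= 1e-15).all()
    with pytest.raises(ValidationError):
        td_roc(np.zeros(4), _sv([5, 6, 7, 8], [1, 1, 1, 1]), 1.0)  # no cases
    with pytest.raises(ValidationError):
        td_roc(np.zeros(4), _sv([1, 2, 3, 4], [1, 1, 1, 1]), 4.0)  # horizon at max


# ---------------------------------------------------------------------------


def test_screen_skips_zero_variance_gene_with_warning(caplog):
    rng = np.random.default_rng(0)
    n = 100
    expr = pd.DataFrame({"flat": np.ones(n), "ok": rng.normal(size=n)})
    sv = _sv(rng.exponential(10, n), np.ones(n, int))
    with caplog.at_level("WARNING"):
        res = univariate_cox_screen(expr, sv, alpha=0.9)
    assert "flat" not in res["gene"].tolist()
    assert any("zero-variance" in r.message for r in caplog.records)


def test_screen_matches_per_gene_fit():
    rng = np.random.default_rng(1)
    n = 120
    expr = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"g{i}" for i in range(6)])
    T = rng.exponential(1.0 / (0.1 * np.exp(1.2 * expr["g0"])))
    sv = _sv(T, np.ones(n, int))
    res = univariate_cox_screen(expr, sv, alpha=0.999999).set_index("gene")
    for g in expr.columns:
        single = fit_cox(expr[[g]], sv)
        assert res.loc[g, "coefficient"] == pytest.approx(single.coefficients[0],
                                                          abs=1e-6)


def test_screen_detects_planted_gene():
    """Standardized log-hazard 1.0 at n=500 is found at alpha=0.05 (3 seeds)."""
    for seed in range(3):
        rng = np.random.default_rng(seed)
        n = 500
        expr = pd.DataFrame(rng.normal(size=(n, 20)),
                            columns=[f"g{i}" for i in range(20)])
        T = rng.exponential(1.0 / (0.05 * np.exp(1.0 * expr["g0"])))
        C = rng.exponential(1.0 / 0.02, n)
        sv = _sv(np.minimum(T, C), (T <= C).astype(int))
        res = univariate_cox_screen(expr, sv, alpha=0.05)
        assert "g0" in res["gene"].tolist()


def test_screen_empty_gene_set_rejected(toy_survival):
    with pytest.raises(ValueError):
        univariate_cox_screen(pd.DataFrame(index=range(4)), toy_survival)


def test_survival_data_validation():
    with pytest.raises(ValidationError):
        SurvivalData(np.array(["a", "a"], dtype=object), [1, 2], [1, 0])
    with pytest.raises(ValidationError):
        SurvivalData(np.array(["a", "b"], dtype=object), [1, -2], [1, 0])
    with pytest.raises(ValidationError):
        SurvivalData(np.array(["a", "b"], dtype=object), [1, 2], [1, 2])
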