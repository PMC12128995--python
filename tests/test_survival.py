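"""Survival frame rules, KM/concordance oracles, splines, Cox, forests."""

import numpy as np
import pandas as pd
import pytest
from sksurv.metrics import concordance_index_censored

import txinjury as tx
from txinjury.survival import (
    SurvivalFrame,
    build_survival_frame,
    c_statistic,
    correlate_with_covariate,
    cox_time_interaction,
    group_summaries,
    km_curve,
    rcs_fit,
    rsf_importance,
    survival_at,
)

from conftest import toy_meta


def _frame(time, event, **extra):
    n = len(time)
    df = pd.DataFrame(
        {
            "kidney_id": [f"K{i}" for i in range(n)],
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
            "txbx_days": extra.pop("txbx_days", np.full(n, 365.0)),
            **extra,
        },
        index=[f"B{i}" for i in range(n)],
    )
    return SurvivalFrame(df)


# ---------------------------------------------------------------------------
# Frame construction


def test_failure_inside_window_is_an_event():
    meta = toy_meta(followup_days=np.array([400.0]), graft_failed=np.array([1]))
    f = build_survival_frame(meta, seed=0)
    assert f.df.iloc[0]["event"] == 1 and f.df.iloc[0]["time"] == 400


def test_death_with_function_is_censoring():
    meta = toy_meta(
        followup_days=np.array([200.0]),
        graft_failed=np.array([0]),
        died_with_function=np.array([1]),
    )
    f = build_survival_frame(meta, seed=0)
    assert f.df.iloc[0]["event"] == 0 and f.df.iloc[0]["time"] == 200


def test_administrative_censoring_at_three_years():
    meta = toy_meta(followup_days=np.array([1200.0]), graft_failed=np.array([1]))
    f = build_survival_frame(meta, seed=0)
    assert f.df.iloc[0]["event"] == 0 and f.df.iloc[0]["time"] == 1095


def test_frame_conserves_kidneys(cohort):
    _, _, meta, _, _ = cohort
    f = build_survival_frame(meta, seed=3)
    fup = pd.to_numeric(meta.df["followup_days"], errors="coerce")
    eligible = meta.df.loc[fup.notna() & (fup > 0), "kidney_id"].nunique()
    assert len(f.df) == eligible
    assert f.df["kidney_id"].is_unique


def test_zero_followup_rows_excluded():
    meta = toy_meta(followup_days=np.array([0.0, 500.0]), kidney_id=["K1", "K2"])
    f = build_survival_frame(meta, seed=0)
    assert list(f.df["kidney_id"]) == ["K2"]


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_hand_product_limit():
    f = _frame([1, 2, 3], [1, 0, 1])
    curve = km_curve(f)["all"]
    assert survival_at(curve, 1) == pytest.approx(2 / 3)
    assert survival_at(curve, 2) == pytest.approx(2 / 3)
    assert survival_at(curve, 3) == pytest.approx(0.0)
    assert survival_at(curve, 0.5) == 1.0


def test_km_no_events_is_flat_one():
    with pytest.warns(UserWarning, match="no events"):
        curve = km_curve(_frame([5, 6, 7], [0, 0, 0]))["all"]
    assert (curve["survival"] == 1.0).all()


def test_km_all_events_matches_empirical_survival():
    f = _frame([1, 2, 3, 4], [1, 1, 1, 1])
    curve = km_curve(f)["all"]
    for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
        assert survival_at(curve, t) == pytest.approx(s)


def test_km_matches_bruteforce_product_limit_with_censoring():
    rng = np.random.default_rng(7)
    time = rng.integers(1, 15, 30)
    event = rng.integers(0, 2, 30)
    curve = km_curve(_frame(time, event))["all"]
    # brute-force product-limit estimator
    s = 1.0
    for t in sorted(set(time[event == 1])):
        at_risk = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / at_risk
        assert survival_at(curve, t) == pytest.approx(s)
    # monotone, starts at 1
    assert (np.diff(curve["survival"]) <= 1e-12).all()


def test_km_groups_and_empty_group_warning():
    f = _frame([1, 2, 3, 4], [1, 1, 0, 1])
    groups = pd.Series(["a", "a", "b", "b"], index=f.df.index)
    curves = km_curve(f, groups)
    assert set(curves) == {"a", "b"}


# ---------------------------------------------------------------------------
# Concordance


def test_c_statistic_perfect_and_constant():
    time = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    event = np.ones(5, dtype=int)
    assert c_statistic(-time, time, event) == 1.0  # risk reversed in time
    assert c_statistic(np.zeros(5), time, event) == 0.5


def test_c_statistic_matches_bruteforce_enumeration():
    risk = np.array([2.0, 1.0, 3.0, 2.0, 0.5])
    time = np.array([3.0, 6.0, 2.0, 4.0, 5.0])
    event = np.array([1, 0, 1, 1, 0])
    conc = ties = pairs = 0
    for i in range(5):
        for j in range(5):
            if i == j or event[i] != 1:
                continue
            if time[j] > time[i] or (time[j] == time[i] and event[j] == 0):
                pairs += 1
                conc += risk[i] > risk[j]
                ties += risk[i] == risk[j]
    assert c_statistic(risk, time, event) == pytest.approx((conc + 0.5 * ties) / pairs)


def test_c_statistic_matches_sksurv():
    rng = np.random.default_rng(8)
    risk = rng.standard_normal(60)
    time = rng.exponential(100, 60)
    event = rng.integers(0, 2, 60)
    expected = concordance_index_censored(event.astype(bool), time, risk)[0]
    assert c_statistic(risk, time, event) == pytest.approx(expected)


def test_c_statistic_no_comparable_pairs():
    with pytest.raises(ValueError, match="comparable"):
        c_statistic([1.0, 2.0], [5.0, 6.0], [0, 0])


# ---------------------------------------------------------------------------
# Restricted cubic splines


def test_rcs_reproduces_affine_functions_exactly():
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 10, 50)
    y = 3.0 - 2.0 * x
    fit = rcs_fit(y, x)
    assert np.allclose(fit.predict(x), y, atol=1e-8)
    assert len(fit.knots) == 3
    assert np.allclose(fit.knots, np.quantile(x, [0.1, 0.5, 0.9]))


def test_rcs_linear_beyond_boundary_knots():
    rng = np.random.default_rng(10)
    x = rng.uniform(0, 10, 200)
    y = np.sin(x / 3) + 0.1 * rng.standard_normal(200)
    fit = rcs_fit(y, x)
    # numerical second derivative outside the boundary knots is zero
    for x0 in (fit.knots[-1] + 2.0, fit.knots[0] - 2.0):
        h = 0.01
        d2 = fit.predict(x0 + h) - 2 * fit.predict(x0) + fit.predict(x0 - h)
        assert abs(d2) < 1e-8


def test_rcs_recovers_a_known_spline():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 10, 1000)
    truth = rcs_fit(np.zeros_like(x), x)  # borrow the basis/knots
    truth.coef = np.array([1.0, -0.5, 2.0])
    y = truth.predict(x) + 0.1 * rng.standard_normal(1000)
    fit = rcs_fit(y, x)
    grid = np.linspace(0.5, 9.5, 200)
    rmse = np.sqrt(np.mean((fit.predict(grid) - truth.predict(grid)) ** 2))
    assert rmse < 0.05


def test_rcs_insufficient_distinct_x():
    with pytest.raises(ValueError):
        rcs_fit(np.arange(12, dtype=float), np.ones(12))


# ---------------------------------------------------------------------------
# Cox with time interactions


def test_cox_recovers_constant_effect_with_null_interaction():
    rng = np.random.default_rng(12)
    n = 1500
    x3 = rng.standard_normal(n)
    txbx = np.exp(rng.uniform(np.log(3), np.log(5000), n))
    lam = 5e-4 * np.exp(0.5 * x3)
    t = rng.exponential(1 / lam)
    cens = rng.uniform(100, 2000, n)
    f = _frame(
        np.maximum(np.minimum(t, cens), 1.0),
        (t <= cens).astype(int),
        txbx_days=txbx,
        PC3=x3,
    )
    effects, cph = cox_time_interaction(f, ["PC3"])
    eff = effects["PC3"]
    se_main = np.sqrt(eff.cov[0, 0])
    se_int = np.sqrt(eff.cov[1, 1])
    # beta(t) at the geometric-mean time should be near 0.5 and the
    # interaction near 0
    assert abs(eff.beta(365.0) - 0.5) < 0.15
    assert abs(eff.interaction) < 3 * se_int
    lo, hi = eff.band(365.0)
    assert lo < 0.5 < hi


def test_cox_degenerate_predictor_is_error():
    f = _frame([1, 2, 3, 4], [1, 1, 0, 1], PC1=np.zeros(4))
    with pytest.raises(ValueError, match="degenerate"):
        cox_time_interaction(f, ["PC1"])


def test_cohort_hazard_couplings_recovered_by_cox():
    """Cox on a generated cohort recovers the configured hazard couplings:
    the acute axis effect grows with log TxBx at the configured slope and
    the remodeling axis effect is constant at its configured value."""
    from conftest import small_config

    cfg = small_config(n_biopsies=4000, seed=17)
    _, meta, _, truth = tx.generate_cohort(cfg)
    frame = build_survival_frame(meta, truth.df[["z1", "z3"]], seed=0)
    effects, _ = cox_time_interaction(frame, ["z1", "z3"])
    hp = cfg.hazard_params
    e1, e3 = effects["z1"], effects["z3"]
    ln365 = np.log(365.0)

    def se_at(eff, g):
        return np.sqrt(eff.cov[0, 0] + g**2 * eff.cov[1, 1] + 2 * g * eff.cov[0, 1])

    assert abs(e1.beta(365.0) - hp.acute_coef) <= 2.5 * se_at(e1, ln365)
    assert abs(e1.interaction - hp.acute_time_slope) <= 2.5 * np.sqrt(e1.cov[1, 1])
    assert abs(e3.beta(365.0) - hp.remodeling_coef) <= 2.5 * se_at(e3, ln365)
    assert abs(e3.interaction) <= 2.5 * np.sqrt(e3.cov[1, 1])


def test_time_varying_effect_curve_is_reproducible_from_coefficients():
    eff = tx.survival.TimeVaryingEffect(
        name="PC1", main=-1.0, interaction=0.3, cov=np.eye(2) * 0.01
    )
    t = np.array([10.0, 100.0, 1000.0])
    assert np.allclose(eff.beta(t), -1.0 + 0.3 * np.log(t))
    lo, hi = eff.band(t)
    assert np.all(lo < eff.beta(t)) and np.all(eff.beta(t) < hi)


# ---------------------------------------------------------------------------
# Random survival forest


@pytest.fixture(scope="module")
def planted_rsf():
    rng = np.random.default_rng(13)
    n = 400
    X = pd.DataFrame(
        rng.standard_normal((n, 4)), columns=["signal", "n1", "n2", "n3"]
    )
    lam = 1e-3 * np.exp(0.9 * X["signal"].to_numpy())
    t = rng.exponential(1 / lam)
    cens = rng.uniform(100, 2000, n)
    frame = _frame(
        np.maximum(np.minimum(t, cens), 1.0), (t <= cens).astype(int),
        txbx_days=rng.uniform(10, 3000, n),
        **{c: X[c].to_numpy() for c in X.columns},
    )
    return frame, list(X.columns)


def test_rsf_ranks_planted_signal_first(planted_rsf):
    frame, predictors = planted_rsf
    imp, oob, _ = rsf_importance(frame, predictors, ntree=150, seed=1, n_repeats=2)
    assert imp.index[0] == "signal"
    assert oob < 0.45  # informative model beats chance


def test_rsf_importance_invariant_to_column_order(planted_rsf):
    frame, predictors = planted_rsf
    a, oob_a, _ = rsf_importance(frame, predictors, ntree=80, seed=2, n_repeats=2)
    b, oob_b, _ = rsf_importance(frame, predictors[::-1], ntree=80, seed=2, n_repeats=2)
    pd.testing.assert_series_equal(a, b)
    assert oob_a == oob_b


def test_rsf_constant_predictor_warns_with_zero_importance(planted_rsf):
    frame, predictors = planted_rsf
    frame2 = SurvivalFrame(frame.df.assign(flat=1.0))
    with pytest.warns(UserWarning, match="constant"):
        imp, _, _ = rsf_importance(frame2, predictors + ["flat"], ntree=50, seed=3, n_repeats=1)
    assert imp["flat"] == 0.0


def test_rsf_median_imputes_missing_predictors(planted_rsf):
    frame, predictors = planted_rsf
    df = frame.df.copy()
    df.loc[df.index[:20], "n1"] = np.nan
    imp, _, _ = rsf_importance(SurvivalFrame(df), predictors, ntree=50, seed=4, n_repeats=1)
    assert imp.index[0] == "signal"


# ---------------------------------------------------------------------------
# Associations and group summaries


def test_correlation_with_monotone_transform_is_one():
    scores = pd.DataFrame({"s": np.arange(10.0)})
    cov = pd.Series(np.exp(np.arange(10.0)), index=scores.index)
    out = correlate_with_covariate(scores, cov)
    assert out.loc["s", "rho"] == pytest.approx(1.0)


def test_correlation_matches_bruteforce_ranks():
    from scipy.stats import rankdata

    scores = pd.DataFrame({"s": [3.0, 1.0, 4.0, 1.0, 5.0]})
    cov = pd.Series([2.0, 7.0, 1.0, 8.0, 2.0], index=scores.index)
    out = correlate_with_covariate(scores, cov)
    expected = np.corrcoef(rankdata(scores["s"]), rankdata(cov))[0, 1]
    assert out.loc["s", "rho"] == pytest.approx(expected)


def test_correlation_constant_covariate_is_error():
    scores = pd.DataFrame({"s": np.arange(5.0)})
    with pytest.raises(ValueError, match="constant"):
        correlate_with_covariate(scores, pd.Series(np.ones(5), index=scores.index))


def test_group_summaries_single_group_equals_cohort_stats():
    meta = toy_meta(
        donor_age=np.array([40.0, 60.0]), txbx_days=np.array([100.0, 300.0])
    )
    groups = pd.Series(["g"] * 2, index=meta.df.index)
    out = group_summaries(meta, groups)
    assert out.loc["g", "n"] == 2
    assert out.loc["g", "mean_donor_age"] == 50.0
    assert out.loc["g", "pct_donor_age_ge50"] == 50.0
    assert out.loc["g", "median_txbx_days"] == 200.0


def test_group_summaries_epochs_and_empty_groups():
    meta = toy_meta(txbx_days=np.array([10.0, 30.0, 500.0]))
    groups = pd.Series(["a", "a", "b"], index=meta.df.index)
    early = group_summaries(meta, groups, epoch="early")
    assert early.loc["a", "n"] == 2 and early.loc["b", "n"] == 0
    late = group_summaries(meta, groups, epoch="late")
    assert late.loc["b", "n"] == 1
    with pytest.raises(ValueError):
        group_summaries(meta, groups, epoch="nope")


def test_donor_age_higher_in_remodeling_groups(cohort, results):
    """The age-z3 coupling surfaces as older donors in the CKDAKI group than
    the normal group."""
    _, _, meta, _, _ = cohort
    out = group_summaries(meta, results.groups)
    assert out.loc["CKDAKI", "mean_donor_age"] > out.loc["normal", "mean_donor_age"]
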