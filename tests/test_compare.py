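"""Group comparison suite: descriptives, variance test, bootstrap R² difference,
interaction models, deciles, stratified prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adoptsim import compare
from adoptsim.errors import DataError, DegenerateFitError


def test_descriptives_identical_groups_all_null(rng):
    y = rng.standard_normal(500)
    age = rng.uniform(40, 70, 500)
    sex = rng.integers(0, 2, 500)
    out = compare.descriptive_compare(
        np.r_[y, y], np.r_[age, age], np.r_[sex, sex],
        np.r_[np.zeros(500), np.ones(500)],
    )
    assert (out["p"] > 0.99).all()


def test_descriptive_wald_z_closed_form(rng):
    a_ = rng.normal(0.0, 1, 1_000)
    b_ = rng.normal(0.5, 1, 1_000)
    out = compare.descriptive_compare(
        np.r_[a_, b_],
        rng.uniform(40, 70, 2_000),
        rng.integers(0, 2, 2_000),
        np.r_[np.zeros(1_000), np.ones(1_000)],
    )
    z = abs(out.loc[out["variable"] == "years_edu", "statistic"].iloc[0])
    assert abs(z - 0.5 / np.sqrt(2 / 1_000)) < 4


def test_descriptive_small_group_rejected(rng):
    with pytest.raises(DataError):
        compare.descriptive_compare(
            np.r_[1.0, 2.0, 3.0], np.r_[50, 50, 50], np.r_[0, 1, 0], np.r_[0, 0, 1]
        )


def test_brown_forsythe_detects_variance_ratio(rng):
    a_ = rng.normal(0, 1, 5_000)
    b_ = rng.normal(0, np.sqrt(2), 5_000)
    F, p = compare.brown_forsythe(np.r_[a_, b_], np.r_[np.zeros(5_000), np.ones(5_000)])
    assert p < 0.05


def test_brown_forsythe_null_calibrated():
    ps = []
    for seed in range(150):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(200)
        _, p = compare.brown_forsythe(y, np.r_[np.zeros(100), np.ones(100)])
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_brown_forsythe_single_member_group_rejected():
    with pytest.raises(DataError):
        compare.brown_forsythe(np.r_[1.0, 2.0, 3.0], np.r_[0, 0, 1])


def test_bootstrap_identical_groups_zero_difference(rng):
    y = rng.standard_normal(400)
    s = 0.4 * y + rng.standard_normal(400)
    res = compare.bootstrap_r2_diff(y, s, None, y, s, None, reps=150, seed=3)
    assert res.diff == 0.0
    assert res.p == pytest.approx(1.0)
    # reproducibility: identical seed + reps => identical SEs
    res2 = compare.bootstrap_r2_diff(y, s, None, y, s, None, reps=150, seed=3)
    assert (res.se_a, res.se_b) == (res2.se_a, res2.se_b)


def test_bootstrap_detects_known_r2_gap(rng):
    n = 2_000
    s = rng.standard_normal(2 * n)
    y = np.empty(2 * n)
    y[:n] = 0.6 * s[:n] + rng.standard_normal(n)  # strong group
    y[n:] = 0.2 * s[n:] + rng.standard_normal(n)  # weak group
    res = compare.bootstrap_r2_diff(
        y[:n], s[:n], None, y[n:], s[n:], None, reps=200, seed=1
    )
    assert res.r2_a > res.r2_b
    assert res.p < 0.01


def test_interaction_additive_null_and_recovery(rng):
    n = 3_000
    s = rng.standard_normal(n)
    adopted = rng.integers(0, 2, n).astype(float)
    covs = pd.DataFrame({"sex": rng.integers(0, 2, n), "age": rng.uniform(40, 70, n)})
    # equal slope in both groups -> interaction ~ 0
    y0 = 0.3 * s + 0.1 * adopted + rng.standard_normal(n)
    t0 = compare.interaction_additive(y0, s, adopted, covs)
    row0 = t0[t0["term"] == "score:adopted"].iloc[0]
    assert abs(row0["estimate"]) < 4 * row0["se"]
    # slope 0.30 vs 0.15 -> interaction -0.15 (on the y-SD scale)
    y1 = 0.30 * s - 0.15 * s * adopted + rng.standard_normal(n)
    t1 = compare.interaction_additive(y1, s, adopted, covs)
    row1 = t1[t1["term"] == "score:adopted"].iloc[0]
    assert abs(row1["estimate"] * y1.std() - (-0.15)) < 4 * row1["se"] * y1.std()


def test_keller_adjustment_changes_confounded_estimate(rng):
    """With a group-dependent covariate interaction, omitting the covariate
    interaction terms biases the focal score-by-adoption estimate."""
    n = 4_000
    s = rng.standard_normal(n)
    adopted = rng.integers(0, 2, n).astype(float)
    c = rng.standard_normal(n) + 0.8 * adopted  # covariate differs by group
    y = 0.3 * s + 0.4 * s * c + rng.standard_normal(n)
    full = compare.interaction_additive(y, s, adopted, pd.DataFrame({"c": c}))
    full_est = full[full["term"] == "score:adopted"]["estimate"].iloc[0]
    # naive model without covariate interactions
    import statsmodels.api as sm

    X = pd.DataFrame(
        {"const": 1.0, "score": (s - s.mean()) / s.std(), "adopted": adopted,
         "score:adopted": (s - s.mean()) / s.std() * adopted, "c": c}
    )
    naive = sm.OLS((y - y.mean()) / y.std(), X).fit()
    assert abs(naive.params["score:adopted"] - full_est) > 2 * full["se"].iloc[3]


def test_interaction_rank_deficiency_names_terms(rng):
    n = 200
    s = rng.standard_normal(n)
    adopted = rng.integers(0, 2, n).astype(float)
    with pytest.raises(DegenerateFitError, match="aliased"):
        compare.interaction_additive(
            rng.standard_normal(n), s, adopted, pd.DataFrame({"dup": adopted})
        )


def test_interaction_multiplicative_null_recovery_and_degenerate(rng):
    n = 6_000
    s = rng.standard_normal(n)
    adopted = rng.integers(0, 2, n).astype(float)
    logit = -0.5 + 0.5 * s - 0.2 * s * adopted
    yrs = np.where(rng.random(n) < 1 / (1 + np.exp(-logit)), 20, 10)
    t = compare.interaction_multiplicative(yrs, s, adopted, None)
    row = t[t["term"] == "score:adopted"].iloc[0]
    assert abs(row["estimate"] - (-0.2)) < 4 * row["se"]
    with pytest.raises(DataError, match="single outcome class"):
        compare.interaction_multiplicative(np.full(50, 20.0), s[:50], adopted[:50], None)


def test_decile_table_shape_and_null(rng):
    n = 4_000
    s = rng.standard_normal(n)
    y = rng.standard_normal(n)
    adopted = rng.integers(0, 2, n).astype(bool)
    out = compare.decile_analysis(s, y, adopted)
    assert len(out) == 10
    assert (out["n_adopted"] + out["n_nonadopted"]).sum() == n
    assert out["significant_bonferroni"].sum() <= 1  # null: nothing flagged (rarely 1)


def test_decile_empty_group_row_continues(rng):
    n = 1_000
    s = np.r_[rng.uniform(0, 1, 500), rng.uniform(2, 3, 500)]
    adopted = np.r_[np.ones(500, bool), np.zeros(500, bool)]  # adoptees only low
    out = compare.decile_analysis(s, rng.standard_normal(n), adopted)
    top = out.iloc[-1]
    assert top["n_adopted"] == 0
    assert np.isnan(top["p"])


def test_stratified_prediction_rows_and_exclusion(rng):
    n = 7 * 300
    strata = np.repeat(np.arange(7), 300)
    s = rng.standard_normal(n)
    slope = 0.1 + 0.1 * strata  # increasing signal across strata
    y = slope * s + rng.standard_normal(n)
    out = compare.stratified_prediction(y, s, None, strata, reps=100, seed=2)
    assert len(out) == 7
    assert not out["excluded"].any()
    r2 = out.sort_values("stratum")["incremental_r2"].to_numpy()
    assert r2[-1] > r2[0]  # trend recovered
    # a tiny stratum is excluded with a log row
    strata2 = strata.copy()
    strata2[:250] = -1
    strata2[:50] = 99
    out2 = compare.stratified_prediction(y, s, None, strata2, reps=100, seed=2)
    assert out2.loc[out2["stratum"] == 99, "excluded"].iloc[0]
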