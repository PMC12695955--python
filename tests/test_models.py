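"""Median quantile regression and the region-transition multinomial model."""

import numpy as np
import pandas as pd
import pytest

from _oracles import pinball_grid_oracle
from philopatry.models import (
    FitError,
    MultinomFit,
    check_loss,
    fit_median_regression,
    fit_multinomial,
    transition_table,
)


def test_exact_line_is_interpolated():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    fit = fit_median_regression(x, 2.0 * x, B=50, seed=0, min_level_count=1)
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(0.0)
    assert fit.check_loss == pytest.approx(0.0)


def test_fit_matches_grid_search_oracle():
    rng = np.random.default_rng(4)
    x = np.repeat(np.arange(1.0, 5.0), 3)
    y = 30.0 * x + rng.normal(0, 40.0, size=x.size)
    fit = fit_median_regression(x, y, B=50, seed=0, min_level_count=1)
    a, b, oracle_loss = pinball_grid_oracle(x, y)
    assert fit.check_loss <= oracle_loss + 1e-6
    assert fit.slope == pytest.approx(b, abs=2.0)


def test_pinball_loss_beats_least_squares_line():
    rng = np.random.default_rng(8)
    for _ in range(5):
        x = rng.integers(1, 7, size=30).astype(float)
        y = 20.0 * x + rng.exponential(80.0, size=30)
        fit = fit_median_regression(x, y, B=50, seed=0, min_level_count=1)
        slope_ols, icpt_ols = np.polyfit(x, y, 1)
        assert fit.check_loss <= check_loss(y - icpt_ols - slope_ols * x, 0.5) + 1e-9


def test_fit_not_worse_than_statsmodels_quantreg():
    """Independent cross-check: exact fit's loss <= iterative QuantReg's."""
    import statsmodels.api as sm

    rng = np.random.default_rng(12)
    x = np.repeat(np.arange(1.0, 6.0), 8)
    y = 45.0 * x + rng.normal(0, 120.0, size=x.size)
    fit = fit_median_regression(x, y, B=50, seed=0, min_level_count=1)
    sm_fit = sm.QuantReg(y, sm.add_constant(x)).fit(q=0.5)
    sm_loss = check_loss(y - sm_fit.params[0] - sm_fit.params[1] * x, 0.5)
    # the exact minimizer can never do worse; with tied predictor levels the
    # optimum may be non-unique, so only the loss is comparable
    assert fit.check_loss <= sm_loss + 1e-6


def test_sparse_levels_are_dropped():
    # one lag-6 observation is not representative of that lag
    x = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3, 6], dtype=float)
    y = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 999], dtype=float)
    fit = fit_median_regression(x, y, min_level_count=2, B=50, seed=0)
    assert fit.dropped_levels == [6.0]
    assert fit.n_used == 9


def test_degenerate_predictor_raises():
    with pytest.raises(FitError, match="constant"):
        fit_median_regression([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0],
                              B=10, seed=0, min_level_count=1)


def test_bootstrap_p_detects_positive_drift():
    rng = np.random.default_rng(3)
    x = np.repeat(np.arange(1.0, 6.0), 12)
    y = 50.0 * x + rng.normal(0, 30.0, size=x.size)
    fit = fit_median_regression(x, y, B=400, seed=1, min_level_count=1)
    assert fit.p_one_sided < 0.01
    lo, hi = fit.slope_ci()
    assert lo <= 50.0 <= hi

    flat = fit_median_regression(x, rng.normal(100.0, 30.0, size=x.size),
                                 B=400, seed=1, min_level_count=1)
    assert flat.p_one_sided > 0.05


def test_bootstrap_reproducible():
    rng = np.random.default_rng(6)
    x = np.repeat(np.arange(1.0, 5.0), 6)
    y = 10 * x + rng.normal(0, 20, size=x.size)
    f1 = fit_median_regression(x, y, B=200, seed=9, min_level_count=1)
    f2 = fit_median_regression(x, y, B=200, seed=9, min_level_count=1)
    assert np.array_equal(f1.bootstrap_slopes, f2.bootstrap_slopes)


# ---------------------------------------------------------------------------
# transition table and multinomial fit
# ---------------------------------------------------------------------------


def _counts(mat):
    regions = ["Northern", "Central", "Southern"]
    return pd.DataFrame(np.asarray(mat, dtype=int), index=regions, columns=regions)


def test_transition_table_counts_and_percentages(toy_colony):
    pairs = pd.DataFrame(
        {
            "natal_beach": ["D", "E", "D", "A", "C"],
            "pupping_beach": ["E", "D", "A", "A", "C"],
        }
    )
    table = transition_table(pairs, toy_colony)
    assert table.counts.loc["Southern", "Southern"] == 2
    assert table.counts.loc["Southern", "Northern"] == 1
    assert table.counts.loc["Northern", "Northern"] == 1
    assert table.counts.loc["Central", "Central"] == 1
    assert table.n_pairs == 5
    assert table.natal_percent["Southern"] == pytest.approx(60.0)
    edges = table.to_edge_list()
    assert edges["count"].sum() == 5

    identical = pd.DataFrame(
        {"natal_beach": ["D", "E", "D"], "pupping_beach": ["D", "E", "E"]}
    )
    t2 = transition_table(identical, toy_colony)
    assert t2.counts.loc["Southern", "Southern"] == 3
    assert t2.counts.to_numpy().sum() == 3


def test_multinomial_independence_gives_unit_rrr():
    # identical outcome distributions in every row: predictor carries nothing
    table = _counts([[10, 20, 30], [20, 40, 60], [5, 10, 15]])
    fit = fit_multinomial(table)
    for _, row in fit.coefficients.iterrows():
        if row["parameter"].startswith("mother["):
            assert row["coef"] == pytest.approx(0.0, abs=1e-6)
            assert row["rrr"] == pytest.approx(1.0, abs=1e-6)


def test_multinomial_saturated_fit_reproduces_empirical_proportions():
    table = _counts([[19, 5, 8], [9, 5, 3], [9, 5, 57]])
    fit = fit_multinomial(table)
    assert fit.converged and not fit.separation_detected
    empirical = table.to_numpy() / table.to_numpy().sum(axis=1, keepdims=True)
    fitted = fit.fitted_probs.to_numpy(dtype=float)
    assert np.allclose(fitted, empirical, atol=1e-6)
    # RRRs are the empirical odds ratios against the baseline cells
    n = table.to_numpy(dtype=float)
    for i, pred in enumerate(["Northern", "Central"]):
        for j, out in enumerate(["Northern", "Central"]):
            expected = (n[i, j] / n[i, 2]) / (n[2, j] / n[2, 2])
            assert fit.rrr(out, pred) == pytest.approx(expected, rel=1e-5)


def test_multinomial_reciprocal_rendering():
    table = _counts([[1, 1, 1], [1, 1, 1], [1, 5, 50]])
    fit = fit_multinomial(table)
    # Southern mothers: P(C)/P(S) = 5/50 = 0.1 is the intercept-level odds
    sel = fit.coefficients[(fit.coefficients["outcome"] == "Central")
                           & (fit.coefficients["parameter"] == "intercept")]
    rrr = float(np.exp(sel["coef"].iloc[0]))
    assert rrr == pytest.approx(0.1, rel=1e-4)
    assert MultinomFit.render_rrr(rrr) == "10.0 times less likely"
    assert MultinomFit.render_rrr(2.6) == "2.6 times more likely"


def test_multinomial_separation_triggers_ridge():
    table = _counts([[10, 0, 2], [3, 4, 5], [1, 2, 20]])
    fit = fit_multinomial(table)
    assert fit.separation_detected
    assert fit.ridge > 0.0
    assert np.isfinite(fit.coefficients["coef"]).all()


def test_multinomial_matches_statsmodels_mnlogit():
    """Independent cross-check on a well-conditioned table."""
    import statsmodels.api as sm

    table = _counts([[19, 5, 8], [9, 5, 3], [9, 5, 57]])
    fit = fit_multinomial(table)

    rows = []
    for i, pred in enumerate(table.index):
        for j, out in enumerate(table.columns):
            rows.extend([{"mother": pred, "pup_idx": j}] * int(table.iloc[i, j]))
    df = pd.DataFrame(rows)
    X = pd.get_dummies(df["mother"], dtype=float)[["Northern", "Central"]]
    X.insert(0, "const", 1.0)
    # statsmodels baselines on outcome 0: order outcomes so Southern is first
    y = df["pup_idx"].map({2: 0, 0: 1, 1: 2})
    sm_fit = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
    sm_params = np.asarray(sm_fit.params)  # (params, 2): cols = Northern, Central
    for j, out in enumerate(["Northern", "Central"]):
        for p_idx, pname in enumerate(["intercept", "mother[Northern]", "mother[Central]"]):
            mine = fit.coefficients[
                (fit.coefficients["outcome"] == out)
                & (fit.coefficients["parameter"] == pname)
            ]["coef"].iloc[0]
            assert mine == pytest.approx(sm_params[p_idx, j], abs=1e-4)


def test_multinomial_loglik_is_maximal_against_perturbations():
    table = _counts([[12, 3, 4], [2, 9, 1], [5, 6, 30]])
    fit = fit_multinomial(table)
    n = table.to_numpy(dtype=float)
    probs = fit.fitted_probs.to_numpy(dtype=float)
    ll_fit = np.sum(n * np.log(probs))
    assert fit.log_likelihood == pytest.approx(ll_fit, abs=1e-6)
    rng = np.random.default_rng(0)
    for _ in range(20):
        q = probs * np.exp(rng.normal(0, 0.05, size=probs.shape))
        q /= q.sum(axis=1, keepdims=True)
        assert np.sum(n * np.log(q)) <= ll_fit + 1e-9


def test_multinomial_input_validation():
    with pytest.raises(FitError, match="baseline"):
        fit_multinomial(_counts(np.eye(3) * 5), baseline_outcome="Atlantis")
    empty_row = _counts([[0, 0, 0], [1, 1, 1], [1, 1, 1]])
    with pytest.raises(FitError, match="predictor level"):
        fit_multinomial(empty_row)
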