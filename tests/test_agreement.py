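"""ICC, bias estimates and Bland–Altman against independent oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import actvalid as av
from actvalid.agreement import AgreementError


def brute_force_icc_a1(x):
    """Independent oracle: two-way ANOVA mean squares computed by explicit
    loops, then the single-measures absolute-agreement formula."""
    n, k = len(x), len(x[0])
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = sum((x[i][j] - row[i] - col[j] + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def test_icc_perfect_agreement():
    x = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
    r = av.icc_absolute_agreement(x)
    assert r.icc == pytest.approx(1.0)
    assert r.interpretation == "strong"
    assert r.ci_low <= r.icc <= r.ci_high


def test_icc_penalizes_constant_offset():
    """Absolute agreement: a large systematic offset drives the ICC toward 0
    even though the rank ordering is perfect."""
    a = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
    x = np.column_stack([a, a + 100.0])
    r = av.icc_absolute_agreement(x)
    assert r.icc < 0.05
    assert r.icc == pytest.approx(brute_force_icc_a1(x.tolist()), abs=1e-10)


def test_icc_matches_handworked_mean_squares():
    x = [[7.0, 9.0], [10.0, 13.0], [8.0, 8.0], [13.0, 16.0]]
    assert av.icc_absolute_agreement(np.array(x)).icc == pytest.approx(
        brute_force_icc_a1(x), abs=1e-10)


def test_icc_matches_pingouin_reference():
    """Cross-check value and CI against an established implementation."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(12)
    for _ in range(20):
        n, k = int(rng.integers(4, 12)), int(rng.integers(2, 4))
        x = rng.normal(0, 1, (n, 1)) * 3 + rng.normal(0, 1, (n, k))
        ours = av.icc_absolute_agreement(x)
        df = pd.DataFrame({"s": np.repeat(np.arange(n), k),
                           "r": np.tile(np.arange(k), n), "y": x.ravel()})
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        ref = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert ours.icc == pytest.approx(ref["ICC"], abs=1e-10)
        assert ours.ci_low == pytest.approx(ref["CI95"][0], abs=0.01)
        assert ours.ci_high == pytest.approx(ref["CI95"][1], abs=0.01)


def test_icc_errors():
    with pytest.raises(AgreementError, match="2 complete subjects"):
        av.icc_absolute_agreement(np.array([[1.0, 2.0]]))
    with pytest.raises(AgreementError, match="zero total variance"):
        av.icc_absolute_agreement(np.full((4, 2), 7.0))
    # rows with missing cells are dropped, not fatal
    x = np.array([[1.0, 1.1], [2.0, np.nan], [3.0, 3.2], [4.0, 3.9]])
    assert av.icc_absolute_agreement(x).n_subjects == 3


def test_icc_interpretation_bands():
    assert av.interpret_icc(0.39) == "poor"
    assert av.interpret_icc(0.40) == "moderate"
    assert av.interpret_icc(0.65) == "moderate"
    assert av.interpret_icc(0.80) == "moderate"
    assert av.interpret_icc(0.85) == "strong"


def test_mean_difference():
    r = av.mean_difference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.delta == 0.0
    b = np.array([100.0, 150.0, 200.0])
    r = av.mean_difference(b + np.array([-10.0, -20.0, -30.0]), b)
    assert r.delta == pytest.approx(-20.0)
    half = 4.302652729911275 * 10.0 / np.sqrt(3)  # t_{.975,2} * SD/sqrt(n)
    assert r.ci_low == pytest.approx(-20.0 - half)
    assert r.ci_high == pytest.approx(-20.0 + half)
    with pytest.raises(AgreementError):
        av.mean_difference([1.0], [2.0])  # CI undefined at n=1
    assert av.mean_difference([1.0], [2.0], ci=False).delta == -1.0
    with pytest.raises(AgreementError, match="mismatch"):
        av.mean_difference([1.0, 2.0], [1.0])


def test_rmse():
    assert av.rmse([5.0, 6.0], [5.0, 6.0]) == 0.0
    assert av.rmse([7.0], [4.0]) == 3.0
    assert av.rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))
    with pytest.raises(AgreementError):
        av.rmse([], [])


@given(st.lists(st.tuples(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4)),
                min_size=2, max_size=40))
def test_rmse_decomposition(pairs):
    """RMSE^2 = delta^2 + (n-1)/n Var(d): bias and scatter are orthogonal."""
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    d = a - b
    n = d.size
    lhs = av.rmse(a, b) ** 2
    rhs = d.mean() ** 2 + (n - 1) / n * d.var(ddof=1)
    assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


def test_heteroscedasticity_screen():
    b = np.linspace(100.0, 1000.0, 30)
    a = b + np.linspace(1.0, 30.0, 30) * np.resize([1.0, -1.0], 30)
    tau, flag = av.assess_heteroscedasticity(a, b)
    assert tau == pytest.approx(1.0) and flag
    with pytest.warns(UserWarning, match="Kendall tau undefined"):
        tau, flag = av.assess_heteroscedasticity(np.full(5, 3.0), np.full(5, 3.0))
    assert not flag
    with pytest.raises(AgreementError):
        av.assess_heteroscedasticity([1.0, 2.0], [1.0, 2.0])


def test_bland_altman_homoscedastic_hand_case():
    b = np.array([100.0, 200.0, 300.0, 400.0])
    a = b + np.array([-1.0, 1.0, -1.0, 1.0])
    res = av.bland_altman(a, b)
    assert res.bias == 0.0
    assert res.sd_diff == pytest.approx(np.sqrt(4.0 / 3.0))
    assert res.loa_high == pytest.approx(2.0 * np.sqrt(4.0 / 3.0))
    assert not res.log_transformed
    # two-point version of the spec'd hand case: sample SD of {-1,+1} = sqrt(2)
    assert np.std([-1.0, 1.0], ddof=1) == pytest.approx(np.sqrt(2.0))


def test_bland_altman_constant_ratio_collapses_on_log_scale():
    """b = c*a is perfectly multiplicative: flagged heteroscedastic, zero
    log-scale SD, zero back-transformed LoA width, bias = mean log ratio."""
    a = np.linspace(50.0, 500.0, 20)
    res = av.bland_altman(1.5 * a, a)
    assert res.heteroscedastic and res.log_transformed
    assert res.sd_log10 == pytest.approx(0.0, abs=1e-12)
    assert res.loa_halfwidth_per_mean == pytest.approx(0.0, abs=1e-12)
    assert res.bias_log10 == pytest.approx(np.log10(1.5))


def test_bland_altman_zero_handling():
    a = np.array([0.0, 10.0, 40.0, 90.0, 160.0, 250.0])
    b = np.array([5.0, 22.0, 60.0, 130.0, 230.0, 360.0])
    res = av.bland_altman(a, b)
    if res.log_transformed:
        assert res.n_zero_adjusted == 1
        assert np.isfinite(res.bias_log10)
    from actvalid.agreement import _adjust_zeros

    neg = a.copy()
    neg[0] = -1.0
    with pytest.raises(AgreementError, match="nonnegative"):
        _adjust_zeros(neg, "x")


def test_proportional_bias_slope_recovered():
    m = np.linspace(100.0, 900.0, 60)
    rng = np.random.default_rng(3)
    d = 0.5 * m - 250.0 + rng.normal(0, 5.0, 60)
    res = av.bland_altman(m + d / 2.0, m - d / 2.0)
    assert res.prop_bias_beta == pytest.approx(0.5, abs=0.02)
    assert res.prop_bias_p < 0.001


def test_stratified_icc_and_missing_strata():
    rows = []
    for i, (pid, noise) in enumerate([("A", 0.0), ("B", 0.0)]):
        for d in range(3):
            v = 100.0 * (d + 1) + 10 * i
            rows.append((pid, v, v))
    rows.append(("C", 5.0, 5.0))  # single pair: below minimum n
    df = pd.DataFrame(rows, columns=["participant_id", "app_minutes",
                                     "device_minutes"])
    results, skipped = av.stratified_icc(df, "participant_id")
    assert results["A"].icc == pytest.approx(1.0)
    assert results["B"].icc == pytest.approx(1.0)
    assert skipped == {"C": 1}


def test_per_participant_icc_decreases_with_noise():
    """Participants whose reporting noise grows with their index show
    monotonically decreasing per-participant ICCs."""
    rng = np.random.default_rng(77)
    rows = []
    for j, pid in enumerate(["P1", "P2", "P3", "P4"]):
        truth = rng.normal(600.0, 80.0, 200)
        noise = rng.normal(0.0, 10.0 + 60.0 * j, 200)
        for t, e in zip(truth, noise):
            rows.append((pid, t + e, t))
    df = pd.DataFrame(rows, columns=["participant_id", "app_minutes",
                                     "device_minutes"])
    results, _ = av.stratified_icc(df, "participant_id")
    iccs = [results[p].icc for p in ["P1", "P2", "P3", "P4"]]
    assert all(x > y for x, y in zip(iccs, iccs[1:]))


def test_test_retest_reliability_bands():
    rng = np.random.default_rng(5)
    truth = rng.normal(600.0, 100.0, 30)
    frames = []
    for period, noise in [("week2", 20.0), ("week3", 20.0)]:
        frames.append(pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(30)],
            "period": period, "behavior": "sedentary",
            "app_minutes": truth + rng.normal(0, noise, 30),
        }))
    weekly = pd.concat(frames)
    res = av.TestRetestModel(weekly, "week2", "week3").fit()
    r = res.iccs["sedentary"]
    assert r.interpretation == av.interpret_icc(r.icc)
    assert 0.8 < r.icc <= 1.0


def test_covariate_regression_hook_recovers_slope():
    rng = np.random.default_rng(8)
    bmi = rng.uniform(20, 45, 40)
    icc = 0.02 * bmi + 0.1 + rng.normal(0, 0.01, 40)
    fit = av.regress_on_covariates(
        pd.Series(icc, index=range(40)),
        pd.DataFrame({"bmi": bmi}, index=range(40)))
    assert fit.params["bmi"] == pytest.approx(0.02, abs=0.005)
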