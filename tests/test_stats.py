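"""Regression accuracy/precision, curvature exclusion, TOST, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fishbeam.datatypes import ValidationError
from fishbeam.stats import (apply_curvature_exclusion, fit_strain_regression,
                            regression_diagnostics, tost_equivalence,
                            RegressionResult)


def _table(pred, meas, strike="s1", series="dorsal", rank=1, comb=0.1):
    return pd.DataFrame({
        "strike_id": strike, "series": series, "rank": rank,
        "frame": np.arange(len(pred)),
        "strain_measured": meas, "strain_predicted": pred,
        "combined_max_curvature": comb})


def test_exact_line_recovers_reported_coefficients():
    # data constructed on measured = 1.15 * predicted + 0.01
    pred = np.linspace(-0.1, 0.1, 200)
    reg = fit_strain_regression(_table(pred, 1.15 * pred + 0.01), "pooled")
    assert reg.slope == pytest.approx(1.15, abs=1e-10)
    assert reg.intercept == pytest.approx(0.01, abs=1e-12)
    assert reg.r_squared == pytest.approx(1.0, abs=1e-12)
    assert reg.violations() == []


def test_identity_regression():
    pred = np.linspace(-0.05, 0.05, 50)
    reg = fit_strain_regression(_table(pred, pred), "pooled")
    assert (reg.slope, reg.intercept) == (pytest.approx(1.0),
                                          pytest.approx(0.0, abs=1e-15))
    assert reg.r_squared == pytest.approx(1.0)


def test_noisy_regression_matches_closed_form_r2():
    rng = np.random.default_rng(21)
    n, sigma = 10_000, 0.02
    x = rng.normal(0, 0.05, n)
    y = x + rng.normal(0, sigma, n)
    reg = fit_strain_regression(_table(x, y), "pooled")
    assert abs(reg.slope - 1.0) < 3 * reg.slope_se
    expected_r2 = x.var() / (x.var() + sigma ** 2)
    assert reg.r_squared == pytest.approx(expected_r2, abs=0.02)


def test_degenerate_regressor_handling():
    with pytest.raises(ValidationError, match="degenerate"):
        fit_strain_regression(_table(np.zeros(10), np.ones(10)), "pooled")
    table = pd.concat([
        _table(np.zeros(10), np.random.default_rng(0).normal(size=10),
               strike="s1"),
        _table(np.linspace(0, 1, 10), np.linspace(0, 1.1, 10), strike="s2")])
    acc = fit_strain_regression(table, "per_strike_subregion")
    assert acc.set_index("strike_id").loc["s1", "degenerate"]
    assert not acc.set_index("strike_id").loc["s2", "degenerate"]
    assert np.isnan(acc.set_index("strike_id").loc["s1", "slope"])


def test_curvature_exclusion_threshold_semantics():
    low = _table(np.linspace(0, 1, 5), np.linspace(0, 1, 5),
                 strike="low", comb=0.04)
    high = _table(np.linspace(0, 1, 5), np.linspace(0, 1, 5),
                  strike="high", comb=0.06)
    table = pd.concat([low, high], ignore_index=True)
    kept, report = apply_curvature_exclusion(table, 0.05)
    assert set(kept["strike_id"]) == {"high"}
    assert report["n_records_excluded"] == 1
    # a vanishing threshold excludes nothing
    kept_all, rep = apply_curvature_exclusion(table, 1e-12)
    assert len(kept_all) == len(table) and rep["n_records_excluded"] == 0
    with pytest.raises(ValidationError):
        apply_curvature_exclusion(table, 0.0)


def test_exclusion_count_matches_brute_force():
    rng = np.random.default_rng(22)
    frames = []
    combs = np.concatenate([rng.uniform(0.01, 0.04, 7),
                            rng.uniform(0.07, 0.2, 9)])
    for i, c in enumerate(combs):
        frames.append(_table(np.linspace(0, 1, 4), np.linspace(0, 1, 4),
                             strike=f"s{i}", comb=c))
    table = pd.concat(frames, ignore_index=True)
    _, report = apply_curvature_exclusion(table, 0.05)
    assert report["n_records_excluded"] == int((combs < 0.05).sum())


def _reg(slope, intercept, slope_se, intercept_se, df=1000):
    return RegressionResult(
        slope=slope, intercept=intercept, r_squared=0.9, p_value=0.0,
        n=df + 2, slope_se=slope_se, intercept_se=intercept_se,
        slope_ci=(slope - 2 * slope_se, slope + 2 * slope_se),
        intercept_ci=(intercept - 2 * intercept_se,
                      intercept + 2 * intercept_se),
        scope="pooled", df_resid=df)


def test_tost_pass_and_fail_by_interval_containment():
    ok = tost_equivalence(_reg(1.0, 0.0, 0.03, 0.006))
    assert ok.slope_pass and ok.intercept_pass and ok.overall_pass
    assert ok.slope_p < 0.05
    # slope 90% CI reaching past 1.2 must fail
    bad = tost_equivalence(_reg(1.15, 0.0, 0.06, 0.006))
    assert not bad.slope_pass and not bad.overall_pass
    assert bad.slope_p > 0.05


def test_tost_monotone_in_margins():
    reg = _reg(1.1, 0.02, 0.05, 0.01)
    tight = tost_equivalence(reg, slope_margin=0.2, intercept_margin=0.05)
    loose = tost_equivalence(reg, slope_margin=0.4, intercept_margin=0.1)
    if tight.overall_pass:
        assert loose.overall_pass
    assert loose.overall_pass  # wide margins comfortably contain the CI
    with pytest.raises(ValidationError):
        tost_equivalence(reg, slope_margin=0.0)


def test_tost_passes_for_true_slope_115_as_se_shrinks():
    # simulated regressions with true slope 1.15: equivalence to slope 1
    # within +/-0.2 is achieved once the standard error is small
    rng = np.random.default_rng(23)
    passes = 0
    for _ in range(20):
        x = rng.normal(0, 0.05, 4000)
        y = 1.15 * x + 0.01 + rng.normal(0, 0.01, x.size)
        reg = fit_strain_regression(_table(x, y), "pooled")
        passes += tost_equivalence(reg).overall_pass
    assert passes == 20


def test_diagnostics_gaussian_heteroscedastic_and_perfect():
    rng = np.random.default_rng(24)
    x = rng.normal(0, 0.05, 3000)
    y = x + rng.normal(0, 0.01, x.size)
    diag = regression_diagnostics(_table(x, y))
    qq = diag["qq"]
    # Gaussian residuals: standardized sample quantiles hug the y=x line
    core = qq[np.abs(qq.theoretical_quantile) < 2]
    assert np.abs(core.sample_quantile - core.theoretical_quantile).max() < 0.2

    y_het = x + rng.normal(0, 0.002, x.size) * (1 + 40 * np.abs(x))
    fr = regression_diagnostics(_table(x, y_het))["fitted_residuals"]
    rho = scipy.stats.spearmanr(np.abs(fr.fitted), np.abs(fr.residual))[0]
    assert rho > 0.2

    perfect = regression_diagnostics(_table(x, 2 * x))["fitted_residuals"]
    assert np.abs(perfect.residual).max() < 1e-12
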