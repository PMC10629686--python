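"""Accuracy, precision and equivalence of beam-theory strain predictions.

Accuracy is the slope of a model-1 (ordinary least squares) regression of
measured on predicted strain (perfect accuracy: slope 1); precision is its
R^2 (perfect precision: 1).  Regressions are fitted pooled over all frames,
strikes and subregions, and per (strike, subregion).  Records whose combined
maximum curvature — the sum of the per-strike maxima of |kappa_ml| and
|kappa_dv| at the subregion — falls below a threshold can be excluded, and a
two-one-sided-tests (TOST) procedure declares the regression equivalent to
an ideal (slope 1, intercept 0) within stated margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .datatypes import ValidationError

#: Columns of the tidy strain table every statistical routine consumes.
STRAIN_COLUMNS = ("strike_id", "series", "rank", "frame", "strain_measured",
                  "strain_predicted", "combined_max_curvature")


@dataclass
class RegressionResult:
    """OLS fit of measured on predicted strain."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_se: float
    intercept_se: float
    slope_ci: tuple[float, float]      # 95%
    intercept_ci: tuple[float, float]  # 95%
    scope: str                         # pooled | per_strike_subregion
    df_resid: int

    def violations(self) -> list[str]:
        out = []
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            out.append(f"r_squared {self.r_squared} outside [0, 1]")
        if self.n < 3:
            out.append(f"n={self.n} < 3")
        if not self.slope_ci[0] <= self.slope <= self.slope_ci[1]:
            out.append("slope CI does not contain the point estimate")
        if not self.intercept_ci[0] <= self.intercept <= self.intercept_ci[1]:
            out.append("intercept CI does not contain the point estimate")
        return out


@dataclass
class EquivalenceResult:
    """TOST equivalence of a regression against target coefficients."""

    slope_target: float
    intercept_target: float
    slope_margin: float
    intercept_margin: float
    alpha: float
    slope_ci90: tuple[float, float]
    intercept_ci90: tuple[float, float]
    slope_p: float
    intercept_p: float
    slope_pass: bool
    intercept_pass: bool
    overall_pass: bool = field(init=False)

    def __post_init__(self):
        self.overall_pass = self.slope_pass and self.intercept_pass


def _ols(predicted: np.ndarray, measured: np.ndarray,
         scope: str) -> RegressionResult:
    X = sm.add_constant(predicted)
    fit = sm.OLS(measured, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared), p_value=float(fit.f_pvalue),
        n=int(fit.nobs), slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        scope=scope, df_resid=int(fit.df_resid))


def fit_strain_regression(table: pd.DataFrame, scope: str = "pooled"):
    """Fit measured-vs-predicted strain regression(s).

    ``table`` is a tidy frame with at least ``strain_measured`` and
    ``strain_predicted`` columns (see :data:`STRAIN_COLUMNS`); predicted
    strain is the regressor.  ``scope="pooled"`` concatenates everything and
    returns a :class:`RegressionResult`; ``scope="per_strike_subregion"``
    fits one regression per (strike_id, series, rank) and returns a
    DataFrame of accuracy records with slope, R^2, n and — when present in
    the input — the record's combined maximum curvature and x_bar.
    Degenerate records (zero predictor variance) are flagged and carry NaN
    coefficients.
    """
    if scope == "pooled":
        clean = table.dropna(subset=["strain_measured", "strain_predicted"])
        pred = clean["strain_predicted"].to_numpy(float)
        if np.ptp(pred) == 0.0:
            raise ValidationError("degenerate pooled regressor (zero variance)")
        return _ols(pred, clean["strain_measured"].to_numpy(float), "pooled")
    if scope != "per_strike_subregion":
        raise ValidationError(f"unknown regression scope '{scope}'")

    rows = []
    for (strike, series, rank), grp in table.groupby(
            ["strike_id", "series", "rank"], sort=True):
        grp = grp.dropna(subset=["strain_measured", "strain_predicted"])
        pred = grp["strain_predicted"].to_numpy(float)
        row = {"strike_id": strike, "series": series, "rank": rank,
               "n": len(grp)}
        for extra in ("combined_max_curvature", "x_bar"):
            if extra in grp.columns:
                row[extra] = float(grp[extra].iloc[0])
        if len(grp) < 3 or np.ptp(pred) == 0.0:
            row.update(slope=np.nan, intercept=np.nan, r_squared=np.nan,
                       degenerate=True)
        else:
            res = _ols(pred, grp["strain_measured"].to_numpy(float),
                       "per_strike_subregion")
            row.update(slope=res.slope, intercept=res.intercept,
                       r_squared=res.r_squared, degenerate=False)
        rows.append(row)
    return pd.DataFrame(rows)


def apply_curvature_exclusion(table: pd.DataFrame, threshold: float,
                              ) -> tuple[pd.DataFrame, dict]:
    """Drop all frames of (strike, subregion) records below the combined
    maximum curvature threshold (cm^-1).

    Returns the filtered table and a report with record/frame counts.
    Low-curvature records carry little strain signal relative to the noise
    floor, so removing them improves precision without touching accuracy.
    """
    if threshold <= 0:
        raise ValidationError("curvature exclusion threshold must be > 0")
    if "combined_max_curvature" not in table.columns:
        raise ValidationError(
            "table lacks 'combined_max_curvature'; compute it per "
            "(strike, subregion) before exclusion")
    keys = ["strike_id", "series", "rank"]
    records = table[keys + ["combined_max_curvature"]].drop_duplicates(keys)
    excluded = records[records["combined_max_curvature"] < threshold]
    kept = table.merge(excluded[keys], on=keys, how="left", indicator=True)
    kept = kept[kept["_merge"] == "left_only"].drop(columns="_merge")
    report = {
        "threshold_cm1": threshold,
        "n_records": int(len(records)),
        "n_records_excluded": int(len(excluded)),
        "n_frames_before": int(len(table)),
        "n_frames_after": int(len(kept)),
    }
    return kept.reset_index(drop=True), report


def tost_equivalence(reg: RegressionResult, slope_target: float = 1.0,
                     intercept_target: float = 0.0,
                     slope_margin: float = 0.2,
                     intercept_margin: float = 0.05,
                     alpha: float = 0.05) -> EquivalenceResult:
    """Two one-sided tests of regression-coefficient equivalence.

    Each coefficient passes when both one-sided t tests reject at ``alpha``
    — equivalently, when its (1 - 2*alpha) confidence interval lies inside
    [target - margin, target + margin].  Overall equivalence requires both
    coefficients to pass.  Default targets are the beam-theory ideal
    (slope 1, intercept 0); prior-study coefficients can be supplied instead.
    """
    if slope_margin <= 0 or intercept_margin <= 0:
        raise ValidationError("equivalence margins must be > 0")
    tcrit = scipy.stats.t.ppf(1 - alpha, reg.df_resid)

    def one_coef(est, se, target, margin):
        ci = (est - tcrit * se, est + tcrit * se)
        t_lo = (est - (target - margin)) / se
        t_hi = (est - (target + margin)) / se
        p = max(scipy.stats.t.sf(t_lo, reg.df_resid),
                scipy.stats.t.cdf(t_hi, reg.df_resid))
        ok = (target - margin) <= ci[0] and ci[1] <= (target + margin)
        return ci, float(p), bool(ok)

    s_ci, s_p, s_ok = one_coef(reg.slope, reg.slope_se, slope_target,
                               slope_margin)
    i_ci, i_p, i_ok = one_coef(reg.intercept, reg.intercept_se,
                               intercept_target, intercept_margin)
    return EquivalenceResult(
        slope_target=slope_target, intercept_target=intercept_target,
        slope_margin=slope_margin, intercept_margin=intercept_margin,
        alpha=alpha, slope_ci90=s_ci, intercept_ci90=i_ci,
        slope_p=s_p, intercept_p=i_p, slope_pass=s_ok, intercept_pass=i_ok)


def regression_diagnostics(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Plot-ready residual diagnostics for the pooled regression.

    Returns ``qq`` (theoretical normal vs ordered standardized residual
    quantiles) and ``fitted_residuals`` tables.  Mirrors a visual check of
    the normality and homoscedasticity assumptions; no automated pass/fail.
    """
    clean = table.dropna(subset=["strain_measured", "strain_predicted"])
    pred = clean["strain_predicted"].to_numpy(float)
    meas = clean["strain_measured"].to_numpy(float)
    fit = sm.OLS(meas, sm.add_constant(pred)).fit()
    resid = fit.resid
    sd = resid.std(ddof=2)
    std_resid = resid / sd if sd > 0 else resid
    (theo, ordered), _ = scipy.stats.probplot(std_resid, dist="norm")
    return {
        "qq": pd.DataFrame({"theoretical_quantile": theo,
                            "sample_quantile": ordered}),
        "fitted_residuals": pd.DataFrame({"fitted": fit.fittedvalues,
                                          "residual": resid}),
    }
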