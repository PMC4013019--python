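"""Ecological (population-level) correlation and regression analysis.

Populations, not individuals, are the analysis units: annual coronary
event rates per 100,000 (by sex stratum) are correlated with population
mean genetic risk score, allele frequencies, geography and risk-factor
levels via Spearman rank correlation and univariate OLS; predictors that
are univariately significant enter a multivariate OLS model.  Outlying
populations are detected by the Bonferroni outlier test on externally
studentized residuals of the GRS univariate model and, under the
exclude-and-refit policy, removed before all analyses are rerun.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import (CollinearityError, InvalidArgumentError,
                        UndefinedResultError)


# ---------------------------------------------------------------------------
# Primitive tests
# ---------------------------------------------------------------------------

def spearman_test(x, y):
    """Spearman rank correlation with two-sided t-approximation p.

    Mid-ranks are used for ties.  Requires n >= 4 finite pairs; zero rank
    variance raises :class:`UndefinedResultError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be equal-length vectors")
    if x.size < 4:
        raise InvalidArgumentError("need n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("inputs must be finite")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedResultError("zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class OLSFit:
    """OLS results plus the statsmodels object for residual diagnostics."""

    params: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    f_pvalue: float
    n: int
    k: int                       # predictors (excluding intercept)
    resid: np.ndarray
    sm_results: object = field(repr=False, default=None)


def ols_fit(y, X: pd.DataFrame) -> OLSFit:
    """Least squares with intercept; adjusted R² and overall F test.

    ``X`` holds predictors only (the intercept is added here).  Rank
    deficiency raises :class:`CollinearityError` naming the columns.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    n, k = X.shape
    if n <= k + 1:
        raise InvalidArgumentError(f"need n > k+1 (n={n}, k={k})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise CollinearityError(
            f"rank-deficient design; columns: {list(X.columns)}")
    res = sm.OLS(y, design).fit()
    return OLSFit(params=res.params, pvalues=res.pvalues,
                  r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
                  f_pvalue=float(res.f_pvalue), n=n, k=k,
                  resid=np.asarray(res.resid), sm_results=res)


def bonferroni_outliers(fit: OLSFit, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni outlier test on externally studentized residuals.

    Per observation: t_i with n-k-2 degrees of freedom, two-sided p, and
    the Bonferroni-adjusted p = min(1, n*p).  Flags observations with
    adjusted p below ``alpha``.
    """
    df = fit.n - fit.k - 2
    if df < 1:
        raise InvalidArgumentError(
            f"insufficient residual degrees of freedom (n-k-2 = {df})")
    out = fit.sm_results.outlier_test(method="bonferroni")
    out.columns = ["student_resid", "p_unadj", "p_bonf"]
    out["p_bonf"] = np.minimum(1.0, out["p_bonf"])
    out["flagged"] = out["p_bonf"] < alpha
    return out


# ---------------------------------------------------------------------------
# The full ecological report
# ---------------------------------------------------------------------------

@dataclass
class StratumResult:
    stratum: str
    univariate: pd.DataFrame          # predictor, rho, rho_p, adj_r2, slope_p
    excluded: list                    # populations removed as outliers
    outlier_test: Optional[pd.DataFrame]
    multivariate: Optional[OLSFit]
    multivariate_predictors: list


@dataclass
class EcoRegressionResult:
    response: str
    predictors: list
    strata: dict                      # stratum name -> StratumResult

    def table(self) -> pd.DataFrame:
        """Flat summary table: one row per predictor x stratum."""
        rows = []
        for name, s in self.strata.items():
            multi = s.multivariate
            for _, r in s.univariate.iterrows():
                in_multi = r.predictor in s.multivariate_predictors
                rows.append({
                    "stratum": name, "predictor": r.predictor,
                    "rho": r.rho, "rho_p": r.rho_p,
                    "adj_r2_uni": r.adj_r2, "uni_p": r.slope_p,
                    "in_multivariate": in_multi,
                    "coef": multi.params.get(r.predictor, np.nan) if (multi and in_multi) else np.nan,
                    "coef_p": multi.pvalues.get(r.predictor, np.nan) if (multi and in_multi) else np.nan,
                    "model_adj_r2": multi.adj_r2 if multi else np.nan,
                    "model_p": multi.f_pvalue if multi else np.nan,
                })
        return pd.DataFrame(rows)


def _stratum_analysis(df: pd.DataFrame, predictors, response,
                      outlier_policy, alpha_enter, outlier_alpha,
                      outlier_predictor) -> StratumResult:
    excluded: list = []
    outlier_table = None
    if outlier_policy == "exclude-and-refit":
        fit = ols_fit(df[response], df[[outlier_predictor]])
        outlier_table = bonferroni_outliers(fit, alpha=outlier_alpha)
        bad = outlier_table.index[outlier_table.flagged]
        excluded = df.loc[bad, "population"].tolist()
        df = df.drop(index=bad)
        if len(df) < 5:
            raise InvalidArgumentError(
                "fewer than 5 populations remain after outlier exclusion")

    uni_rows = []
    significant = []
    for pred in predictors:
        rho, rho_p = spearman_test(df[pred], df[response])
        fit = ols_fit(df[response], df[[pred]])
        slope_p = float(fit.pvalues[pred])
        uni_rows.append({"predictor": pred, "rho": rho, "rho_p": rho_p,
                         "adj_r2": fit.adj_r2, "slope_p": slope_p})
        if slope_p < alpha_enter:
            significant.append(pred)

    multi = None
    if significant:
        try:
            multi = ols_fit(df[response], df[significant])
        except (CollinearityError, InvalidArgumentError) as exc:
            warnings.warn(f"multivariate model not fitted: {exc}", stacklevel=2)
    return StratumResult(stratum=str(df["sex_stratum"].iloc[0]),
                         univariate=pd.DataFrame(uni_rows),
                         excluded=excluded, outlier_test=outlier_table,
                         multivariate=multi,
                         multivariate_predictors=significant)


def eco_report(eco: pd.DataFrame, predictors: Sequence[str],
               response: str = "event_rate",
               outlier_policy: str = "report",
               alpha_enter: float = 0.05,
               outlier_alpha: float = 0.01,
               outlier_predictor: Optional[str] = None) -> EcoRegressionResult:
    """Spearman + univariate OLS per predictor, outlier handling, and a
    multivariate model of the univariately significant predictors.

    ``eco`` must have one row per population x sex stratum with columns
    ``population``, ``sex_stratum``, the response and every predictor.
    Each sex stratum is analysed independently.  Under
    ``outlier_policy='exclude-and-refit'`` populations flagged by the
    Bonferroni test (adjusted p < ``outlier_alpha``) in the univariate
    model of ``outlier_predictor`` (default: the first predictor) are
    removed and the whole stratum analysis is rerun on the remainder;
    under ``'report'`` the data are left untouched.
    """
    if outlier_policy not in ("report", "exclude-and-refit"):
        raise InvalidArgumentError(f"unknown outlier policy {outlier_policy!r}")
    predictors = list(predictors)
    if not predictors:
        raise InvalidArgumentError("need at least one predictor")
    needed = {"population", "sex_stratum", response, *predictors}
    missing = needed - set(eco.columns)
    if missing:
        raise InvalidArgumentError(f"eco table missing columns: {sorted(missing)}")
    outlier_predictor = outlier_predictor or predictors[0]

    strata = {}
    for name, grp in eco.groupby("sex_stratum", sort=False):
        grp = grp.reset_index(drop=True)
        if len(grp) < 5:
            raise InvalidArgumentError(
                f"stratum {name!r} has fewer than 5 populations")
        strata[name] = _stratum_analysis(
            grp, predictors, response, outlier_policy,
            alpha_enter, outlier_alpha, outlier_predictor)
    return EcoRegressionResult(response=response, predictors=predictors,
                               strata=strata)
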