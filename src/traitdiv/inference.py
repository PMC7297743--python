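"""Regression layer: z-scores, OLS, backward elimination, variance shares.

The central model regresses population-level trait variation (iFD_CV) on
within-habitat heterogeneity (HD) and genetic diversity indices, with all
predictors z-transformed so their coefficients are comparable. Backward
elimination repeatedly drops the least significant predictor (p > alpha_stay,
default .1) and logs the AIC and a nested-model F test at every step. The
relative importance of the surviving predictors is reported as shares of
absolute standardized coefficients.

Natural logs are used for all log transforms; R-squared values are
base-invariant, coefficients are on the natural-log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def ztransform(values) -> np.ndarray:
    """Standardize to zero mean and unit sample SD (n-1 denominator)."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("z-transform needs at least 2 values")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("z-transform undefined for a constant vector")
    return (vals - vals.mean()) / sd


@dataclass
class RegressionResult:
    """OLS fit summary for one model (always with intercept)."""

    response: str
    predictors: list[str]
    params: pd.Series           # includes the intercept ("const")
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    r2_adj: float
    fvalue: float
    df1: int
    df2: int
    f_pvalue: float
    aic: float
    residuals: pd.Series        # keyed by the input index (population ids)
    nobs: int
    rss: float
    standardized: bool = False
    extras: dict = field(default_factory=dict)


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    # k predictors; parameter count k + 2 (intercept and error variance)
    return n * math.log(2 * math.pi * rss / n) + n + 2 * (k + 2)


def ols(y: pd.Series, X: pd.DataFrame, standardized: bool = False) -> RegressionResult:
    """Least-squares fit of ``y`` on the columns of ``X`` plus an intercept."""
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    if y.isna().any() or X.isna().any().any():
        raise ValueError("ols requires complete cases; drop or impute missing cells first")
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"n={len(y)} too small for {X.shape[1]} predictors")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        a, b = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        raise ValueError(
            f"rank-deficient design; most collinear columns: {corr.index[a]}, {corr.columns[b]}")
    fit = sm.OLS(y, design).fit()
    k = X.shape[1]
    rss = float(fit.ssr)
    return RegressionResult(
        response=y.name or "y",
        predictors=list(X.columns),
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        fvalue=float(fit.fvalue) if k else float("nan"),
        df1=k,
        df2=int(fit.df_resid),
        f_pvalue=float(fit.f_pvalue) if k else float("nan"),
        aic=_gaussian_aic(rss, len(y), k),
        residuals=pd.Series(fit.resid, index=y.index),
        nobs=len(y),
        rss=rss,
        standardized=standardized,
    )


def _nested_f(full: RegressionResult, reduced: RegressionResult) -> tuple[float, float]:
    """ANOVA F test of a reduced model nested in a full model."""
    df_num = full.df1 - reduced.df1
    f = ((reduced.rss - full.rss) / df_num) / (full.rss / full.df2)
    p = stats.f.sf(f, df_num, full.df2)
    return float(f), float(p)


def backward_select(y: pd.Series, X: pd.DataFrame, alpha_stay: float = 0.1,
                    standardized: bool = False,
                    ) -> tuple[RegressionResult, pd.DataFrame]:
    """Backward elimination: drop the least significant predictor until all stay.

    At each step the predictor with the largest p-value above ``alpha_stay`` is
    removed (ties broken by the smaller absolute t, then lexicographic name
    order) and the step is logged with the AIC before/after and the nested-F
    comparison of the two models. If everything is eliminated, the
    intercept-only model is returned with ``extras['intercept_only']`` set.
    """
    cols = list(X.columns)
    steps = []
    current = ols(y, X[cols], standardized=standardized)
    while cols:
        pv = current.pvalues.drop("const")
        worst_p = pv.max()
        if worst_p <= alpha_stay:
            break
        candidates = sorted(pv.index[pv == worst_p],
                            key=lambda c: (abs(current.tvalues[c]), c))
        drop = candidates[0]
        cols = [c for c in cols if c != drop]
        if cols:
            reduced = ols(y, X[cols], standardized=standardized)
            f, p = _nested_f(current, reduced)
        else:
            # intercept-only: residuals are deviations from the mean
            resid = y - y.mean()
            rss = float((resid ** 2).sum())
            reduced = RegressionResult(
                response=current.response, predictors=[],
                params=pd.Series({"const": y.mean()}),
                bse=pd.Series(dtype=float), tvalues=pd.Series(dtype=float),
                pvalues=pd.Series(dtype=float), r2=0.0, r2_adj=0.0,
                fvalue=float("nan"), df1=0, df2=len(y) - 1, f_pvalue=float("nan"),
                aic=_gaussian_aic(rss, len(y), 0),
                residuals=resid, nobs=len(y), rss=rss,
                standardized=standardized, extras={"intercept_only": True},
            )
            f, p = _nested_f(current, reduced)
        steps.append({"dropped": drop, "p_dropped": worst_p,
                      "aic_before": current.aic, "aic_after": reduced.aic,
                      "nested_F": f, "nested_F_p": p})
        current = reduced
    return current, pd.DataFrame(
        steps, columns=["dropped", "p_dropped", "aic_before", "aic_after",
                        "nested_F", "nested_F_p"])


def variance_partition(fit: RegressionResult) -> pd.Series:
    """Percent shares of explained variation from absolute standardized coefficients.

    share_i = |beta_i| / sum_j |beta_j| * 100, over the fitted predictors.
    Requires a fit on z-scored predictors (``standardized=True``) so the
    coefficient magnitudes are comparable.
    """
    if not fit.standardized:
        raise ValueError("variance_partition requires a fit on z-scored predictors")
    if not fit.predictors:
        raise ValueError("variance_partition needs at least one predictor")
    beta = fit.params.drop("const").abs()
    total = beta.sum()
    if total == 0:
        raise ValueError("all coefficients are zero; shares undefined")
    return 100.0 * beta / total


def trait_regressions(cv_table: pd.DataFrame, predictor: pd.Series,
                      traits: list[str] | None = None) -> pd.DataFrame:
    """Per-trait simple regressions ln(CV_trait) ~ predictor.

    ``cv_table`` is population-indexed with ``CV_<trait>`` columns; the
    predictor series (HD or GD) must share that index. A Shapiro-Wilk normality
    p-value of the log-transformed response is reported alongside (never used
    to switch transforms automatically).
    """
    tab = cv_table.set_index("population_id") if "population_id" in cv_table.columns else cv_table
    if traits is None:
        traits = [c[3:] for c in tab.columns if c.startswith("CV_")]
    predictor = predictor.loc[tab.index]
    rows = []
    for t in traits:
        vals = tab[f"CV_{t}"]
        if (vals <= 0).any():
            raise ValueError(f"trait {t}: non-positive CV, log undefined")
        logcv = np.log(vals.astype(float))
        fit = ols(logcv.rename(f"ln_CV_{t}"), predictor.to_frame())
        rows.append({
            "trait": t,
            "slope": fit.params.iloc[1],
            "r2": fit.r2,
            "F": fit.fvalue,
            "p": fit.f_pvalue,
            "shapiro_p": float(stats.shapiro(logcv).pvalue),
        })
    return pd.DataFrame(rows)


def cv_correlation_matrix(trait_cvs: pd.DataFrame, factor_cvs: pd.DataFrame,
                          alpha_mask: float = 0.1) -> dict:
    """Pearson correlations of ln(1 + CV_trait) against ln(1 + CV_factor).

    Both tables are population/location keyed frames of CV columns. Adding 1
    before the log keeps near-zero CVs finite and preserves ordering. Returns
    a dict with ``r`` and ``p`` grids, a boolean ``mask`` of entries with
    p < ``alpha_mask``, and ``positive_share``, the fraction of positive
    coefficients. Zero-variance columns yield NaN entries (flagged).
    """
    t = trait_cvs.set_index("population_id") if "population_id" in trait_cvs.columns else trait_cvs
    f = factor_cvs.set_index("location_id") if "location_id" in factor_cvs.columns else factor_cvs
    t = t[[c for c in t.columns if c.startswith("CV_")]]
    f = f[[c for c in f.columns if c.startswith("CV_")]]
    f = f.loc[t.index]
    lt, lf = np.log1p(t.astype(float)), np.log1p(f.astype(float))
    r = pd.DataFrame(index=lt.columns, columns=lf.columns, dtype=float)
    p = r.copy()
    for a in lt.columns:
        for b in lf.columns:
            if lt[a].std(ddof=1) == 0 or lf[b].std(ddof=1) == 0:
                continue
            rr, pp = stats.pearsonr(lt[a], lf[b])
            r.loc[a, b], p.loc[a, b] = rr, pp
    return {
        "r": r,
        "p": p,
        "mask": p < alpha_mask,
        "positive_share": float((r.to_numpy() > 0).sum() / np.isfinite(r.to_numpy()).sum()),
    }
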