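"""Severity-on-dimension regression profiles, screener classification and
demographic sensitivity correlations.

Standardized coefficients come from z-scaling all continuous variables on
the analysis sample before an ordinary least-squares fit (binary sex enters
unstandardized); confidence intervals are t-based.  Screener classification
applies each scale's published cut-point as ``score >= cut``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr, spearmanr

# Published screener cut-points: insomnia (ISI), the five RMT20 subscales,
# and the 6-item adult ADHD self-report scale.
DEFAULT_CUT_POINTS = {
    "ID": 10,
    "MDD": 13,
    "GAD": 11,
    "SAD": 12,
    "PD": 9,
    "PTSD": 8,
    "ADHD": 4,
}


@dataclass
class DisorderClassification:
    positive: pd.DataFrame       # persons x scales booleans
    counts: dict                 # none / one / multiple


def classify_probable_disorders(
    severity: pd.DataFrame, cut_points: dict | None = None
) -> DisorderClassification:
    """Threshold severity scores at each scale's cut-point (``>= cut``)."""
    cuts = dict(DEFAULT_CUT_POINTS)
    if cut_points:
        cuts.update(cut_points)
    unknown = [c for c in severity.columns if c not in cuts]
    if unknown:
        raise ValueError(f"unknown scale labels: {unknown}")
    pos = pd.DataFrame(
        {c: severity[c] >= cuts[c] for c in severity.columns},
        index=severity.index,
    )
    n_pos = pos.sum(axis=1)
    counts = {
        "none": int((n_pos == 0).sum()),
        "one": int((n_pos == 1).sum()),
        "multiple": int((n_pos >= 2).sum()),
    }
    return DisorderClassification(pos, counts)


@dataclass
class RegressionProfile:
    outcome: str
    table: pd.DataFrame          # rows: predictors; beta, se, t, p, ci_low, ci_high
    n_used: int
    r_squared: float
    covariate_set: str


def fit_profile(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    extended_covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    outcome_name: str | None = None,
) -> RegressionProfile:
    """OLS profile of one severity outcome on the dimension scores.

    Continuous variables (outcome, dimension scores, age and any extended
    continuous covariates) are standardized to unit sample SD on the
    listwise-complete analysis sample; binary columns (at most two distinct
    values) are left as is.  CI = beta +/- t_{1-alpha/2, df} * SE.
    """
    parts = [predictors]
    labels = list(predictors.columns)
    if covariates is not None:
        parts.append(covariates)
        labels += list(covariates.columns)
    if extended_covariates is not None:
        parts.append(extended_covariates)
        labels += list(extended_covariates.columns)
    X = pd.concat(parts, axis=1)
    y = pd.Series(outcome).astype(float)
    frame = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    n = len(frame)
    if n < X.shape[1] + 10:
        raise ValueError(
            f"only {n} complete cases for {X.shape[1]} parameters"
        )
    z = frame.copy()
    for col in z.columns:
        vals = z[col]
        if col != "__y__" and vals.nunique() <= 2:
            continue  # binary covariates (sex) stay on their own scale
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero-variance column {col!r}")
        z[col] = (vals - vals.mean()) / sd
    design = sm.add_constant(z[labels])
    model = sm.OLS(z["__y__"], design).fit()
    ci = model.conf_int(alpha=alpha)
    table = pd.DataFrame(
        {
            "beta": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    ).drop(index="const")
    covset = "age+sex" if covariates is not None else "none"
    if extended_covariates is not None:
        covset += "+extended"
    return RegressionProfile(
        outcome=outcome_name or getattr(outcome, "name", "outcome"),
        table=table,
        n_used=n,
        r_squared=float(model.rsquared),
        covariate_set=covset,
    )


def profile_all_outcomes(
    severities: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    extended_covariates: pd.DataFrame | None = None,
    single_dimension: bool = False,
) -> pd.DataFrame:
    """Long-format regression table over every outcome (and optionally every
    single-dimension model)."""
    rows = []
    for out in severities.columns:
        if single_dimension:
            for dim in scores.columns:
                prof = fit_profile(
                    severities[out], scores[[dim]], covariates,
                    extended_covariates, outcome_name=out,
                )
                t = prof.table.loc[[dim]].reset_index(names="predictor")
                t.insert(0, "outcome", out)
                t["n"] = prof.n_used
                rows.append(t)
        else:
            prof = fit_profile(
                severities[out], scores, covariates, extended_covariates,
                outcome_name=out,
            )
            t = prof.table.reset_index(names="predictor")
            t.insert(0, "outcome", out)
            t["n"] = prof.n_used
            rows.append(t)
    return pd.concat(rows, ignore_index=True)


def demographic_sensitivity(
    scores: pd.DataFrame, demographics: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r for age / years of education, Spearman rho for income
    (the socioeconomic-status proxy), per dimension, pairwise complete."""
    methods = {
        "age": "pearson",
        "education_years": "pearson",
        "income": "spearman",
    }
    rows = []
    for var, method in methods.items():
        if var not in demographics.columns:
            continue
        for dim in scores.columns:
            a, b = scores[dim], demographics[var].astype(float)
            ok = a.notna() & b.notna()
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for {dim!r} vs {var!r}"
                )
            if method == "pearson":
                r = pearsonr(a[ok], b[ok]).statistic
            else:
                r = spearmanr(a[ok], b[ok]).statistic
            rows.append(
                dict(dimension=dim, variable=var, method=method,
                     correlation=float(r), n=int(ok.sum()))
            )
    return pd.DataFrame(rows)
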