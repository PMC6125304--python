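"""Group comparison and regression statistics for network metrics.

One-way ANOVA (from raw scores or from published summary statistics),
covariate-adjusted group comparison (ANCOVA with age and sex), ordinary
least squares of a metric on age, and the Nyholt effective-number-of-tests
correction for families of correlated metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class GroupStatsResult:
    F: float
    df: tuple[int, int]
    p: float
    eta2: float


@dataclass
class RegressionResult:
    R: float       # |r|, the paper's convention: sign carried by beta / t
    R2: float
    beta: float    # slope per unit predictor
    t: float
    p: float
    n: int


def _as_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    samples = [values[groups == g] for g in levels]
    return levels, samples


def anova_oneway(values, groups) -> GroupStatsResult:
    """Classical one-way ANOVA with eta-squared effect size."""
    _, samples = _as_groups(values, groups)
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    grand = np.concatenate(samples).mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df1 = len(samples) - 1
    df2 = sum(len(s) for s in samples) - len(samples)
    if ssw == 0 and ssb == 0:
        return GroupStatsResult(F=0.0, df=(df1, df2), p=1.0, eta2=0.0)
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta2 = ssb / (ssb + ssw)
    return GroupStatsResult(F=float(f), df=(df1, df2), p=p, eta2=float(eta2))


def anova_from_summary(means, sds, ns) -> GroupStatsResult:
    """One-way ANOVA reconstructed from per-group means, SDs and sizes.

    SS_between uses the group means about the size-weighted grand mean;
    SS_within = sum (n_i - 1) sd_i^2. Exactly reproduces anova_oneway when
    the summaries come from the raw data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    grand = (ns * means).sum() / ns.sum()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    df1 = len(means) - 1
    df2 = int(ns.sum() - len(means))
    if ssb == 0:
        return GroupStatsResult(F=0.0, df=(df1, df2), p=1.0, eta2=0.0)
    f = (ssb / df1) / (ssw / df2)
    return GroupStatsResult(F=f, df=(df1, df2), p=float(sps.f.sf(f, df1, df2)),
                            eta2=ssb / (ssb + ssw))


def ancova_group(values, groups, age, sex) -> GroupStatsResult:
    """Group effect adjusted for age and sex (general linear model).

    Sex enters as a binary indicator; the group term is tested as the
    partial (type-III style) F for the single group factor given the
    covariates. Effect size is partial eta-squared.
    """
    values = np.asarray(values, dtype=float)
    g = pd.Categorical(groups)
    age = np.asarray(age, dtype=float)
    sex_codes = pd.Categorical(sex).codes.astype(float)
    for name, cov in (("age", age), ("sex", sex_codes)):
        if np.ptp(cov) == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
    covs = np.column_stack([age, sex_codes])
    if np.linalg.matrix_rank(np.column_stack(
            [np.ones(len(age)), covs])) < covs.shape[1] + 1:
        raise ValueError("collinear covariates")

    dummies = pd.get_dummies(g, drop_first=True).to_numpy(dtype=float)
    x_full = sm.add_constant(np.column_stack([dummies, covs]))
    x_red = sm.add_constant(covs)
    full = sm.OLS(values, x_full).fit()
    red = sm.OLS(values, x_red).fit()
    df1 = dummies.shape[1]
    df2 = int(full.df_resid)
    num = (red.ssr - full.ssr) / df1
    den = full.ssr / df2
    f = num / den if den > 0 else 0.0
    p = float(sps.f.sf(f, df1, df2)) if den > 0 else 1.0
    eta2 = ((red.ssr - full.ssr) / red.ssr) if red.ssr > 0 else 0.0
    return GroupStatsResult(F=float(f), df=(df1, df2), p=p,
                            eta2=float(eta2))


def regress_age(metric, age) -> RegressionResult:
    """OLS of a metric on age with a two-sided slope t test."""
    metric = np.asarray(metric, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(metric) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(age) == 0:
        raise ValueError("zero variance in the predictor")
    res = sps.linregress(age, metric)
    n = len(metric)
    t = res.slope / res.stderr if res.stderr > 0 else 0.0
    return RegressionResult(R=abs(res.rvalue), R2=res.rvalue ** 2,
                            beta=float(res.slope), t=float(t),
                            p=float(res.pvalue), n=n)


def nyholt_meff(corr) -> float:
    """Nyholt's effective number of independent tests.

    M_eff = 1 + (M - 1) (1 - Var(lambda) / M) with lambda the eigenvalues
    of the metric correlation matrix and the variance taken with the
    sample (M - 1) denominator, so perfectly correlated metrics give
    exactly 1 and uncorrelated metrics give M.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
        raise ValueError("not a correlation matrix (symmetric, unit diagonal)")
    lam = np.linalg.eigvalsh(c)
    if lam.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    m = c.shape[0]
    return float(1 + (m - 1) * (1 - np.var(lam, ddof=1) / m))


def corrected_alpha(alpha: float, m_eff: float) -> float:
    """Significance threshold corrected by the effective test count."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    return alpha / m_eff


def group_compare_table(metric_table: pd.DataFrame, metrics: list[str],
                        group_col: str = "group", covariates: bool = True,
                        log_transform: bool = False,
                        alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA/ANCOVA of every metric column, with the Nyholt-corrected flag.

    One row per metric: F, df, p, eta2, and whether p clears the
    alpha / M_eff threshold computed from the metrics' own correlation
    matrix. ``log_transform`` applies the natural-log control analysis
    (requires positive values).
    """
    vals = metric_table[metrics].astype(float)
    if log_transform:
        if (vals <= 0).any().any():
            raise ValueError("log transform requires positive metric values")
        vals = np.log(vals)
    usable = [m for m in metrics if vals[m].std() > 0]
    m_eff = nyholt_meff(vals[usable].corr().to_numpy()) if len(usable) > 1 \
        else float(len(usable))
    thresh = corrected_alpha(alpha, m_eff)
    rows = []
    for metric in metrics:
        if covariates:
            res = ancova_group(vals[metric], metric_table[group_col],
                               metric_table["age"], metric_table["sex"])
        else:
            res = anova_oneway(vals[metric], metric_table[group_col])
        rows.append({"metric": metric, "F": res.F, "df1": res.df[0],
                     "df2": res.df[1], "p": res.p, "eta2": res.eta2,
                     "significant_corrected": res.p < thresh})
    out = pd.DataFrame(rows)
    out.attrs["m_eff"] = m_eff
    out.attrs["corrected_alpha"] = thresh
    return out
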