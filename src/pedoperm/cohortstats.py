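"""Scalar group statistics: Welch t, Cohen's d, mean CIs, covariate models.

The two-group comparisons use the Welch (unequal variances) t statistic —
the convention consistent with the unbalanced group sizes this package is
built around — while Cohen's d uses the pooled standard deviation, the
usual effect-size convention.  Both are available from raw samples or from
printed summary statistics (n, mean, SD), and the two paths agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "SummaryStats",
    "EffectResult",
    "RegressionResult",
    "welch_t_from_summary",
    "pooled_cohens_d_from_summary",
    "mean_ci",
    "summarize",
    "compare_groups",
    "adjusted_sex_effect",
    "group_table",
]

#: Predictors of the covariate-adjusted models, in fitting order.
ADJUSTMENT_PREDICTORS = ("sex", "age", "bmi", "cadence", "foot_angle", "speed")


@dataclass(frozen=True)
class SummaryStats:
    """Group summary: sample size, mean, standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class EffectResult:
    t: float
    df: float
    p: float
    d: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


def summarize(x: Sequence[float]) -> SummaryStats:
    arr = np.asarray(x, dtype=float)
    return SummaryStats(n=arr.size, mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def welch_t_from_summary(a: SummaryStats, b: SummaryStats) -> tuple[float, float, float]:
    """Welch two-sample t, Welch–Satterthwaite df and two-sided p.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b).  Two groups with zero SD
    and equal means give t = 0, p = 1.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
    )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df), float(p)


def pooled_cohens_d_from_summary(a: SummaryStats, b: SummaryStats) -> float:
    """Cohen's d with the pooled standard deviation.

    s_pooled^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2).
    """
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance: Cohen's d undefined")
    return float((a.mean - b.mean) / np.sqrt(sp2))


def mean_ci(s: SummaryStats, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for the group mean."""
    half = stats.t.ppf((1 + level) / 2, s.n - 1) * s.sd / np.sqrt(s.n)
    return (s.mean - half, s.mean + half)


def compare_groups(
    a: Sequence[float] | SummaryStats, b: Sequence[float] | SummaryStats
) -> EffectResult:
    """Welch t, pooled-SD Cohen's d and 95% mean CIs for two groups.

    Accepts raw samples or :class:`SummaryStats`; raw samples are reduced to
    their summaries first, so the two input paths agree exactly.
    """
    sa = a if isinstance(a, SummaryStats) else summarize(a)
    sb = b if isinstance(b, SummaryStats) else summarize(b)
    t, df, p = welch_t_from_summary(sa, sb)
    d = pooled_cohens_d_from_summary(sa, sb)
    return EffectResult(t=t, df=df, p=p, d=d, ci_a=mean_ci(sa), ci_b=mean_ci(sb))


@dataclass
class RegressionResult:
    """OLS fit of a parameter on sex plus covariates, with VIF diagnostics."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    vif: pd.Series
    r_squared: float
    model: object = None


def adjusted_sex_effect(
    table: pd.DataFrame, parameter: str, predictors: Sequence[str] = ADJUSTMENT_PREDICTORS
) -> RegressionResult:
    """Sex effect on a parameter adjusted for covariates by OLS.

    ``table`` holds one row per participant with the parameter and the
    predictor columns; ``sex`` may be the strings female/male (coded
    male = 0, female = 1) or already numeric.  Variance inflation factors
    come from the auxiliary regressions of each predictor on the others
    (VIF = 1/(1 - R_j^2)).  Missing values and rank-deficient designs raise.
    """
    cols = [parameter, *predictors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    df = table[cols].copy()
    if df.isna().any().any():
        raise ValueError("missing values in regression table")
    if df["sex"].dtype == object:
        df["sex"] = df["sex"].map({"male": 0, "female": 1})
        if df["sex"].isna().any():
            raise ValueError("sex must be 'female'/'male' or numeric")
    X = sm.add_constant(df[list(predictors)].astype(float))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = df[list(predictors)].astype(float).corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"design matrix rank deficient (check columns {worst})")
    fit = sm.OLS(df[parameter].astype(float), X).fit()
    Xp = X.drop(columns="const").to_numpy()
    Xp_c = sm.add_constant(Xp)
    vif = pd.Series(
        [variance_inflation_factor(Xp_c, j + 1) for j in range(Xp.shape[1])],
        index=list(predictors),
    )
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        vif=vif,
        r_squared=float(fit.rsquared),
        model=fit,
    )


def group_table(
    data: pd.DataFrame,
    parameters: Sequence[str],
    group_col: str = "sex",
    groups: tuple[str, str] = ("female", "male"),
) -> pd.DataFrame:
    """Two-group comparison table: means, SDs, 95% CIs, Welch t, p, d.

    One row per parameter, mirroring the usual layout of cohort description
    tables.  Significance flags at .05 (*) and .01 (**), uncorrected for
    multiple comparisons.
    """
    rows = []
    ga = data[data[group_col] == groups[0]]
    gb = data[data[group_col] == groups[1]]
    for param in parameters:
        res = compare_groups(ga[param].to_numpy(), gb[param].to_numpy())
        sa, sb = summarize(ga[param]), summarize(gb[param])
        flag = "**" if res.p < 0.01 else "*" if res.p < 0.05 else ""
        rows.append(
            {
                "parameter": param,
                f"{groups[0]}_mean": sa.mean,
                f"{groups[0]}_sd": sa.sd,
                f"{groups[0]}_ci_lower": res.ci_a[0],
                f"{groups[0]}_ci_upper": res.ci_a[1],
                f"{groups[1]}_mean": sb.mean,
                f"{groups[1]}_sd": sb.sd,
                f"{groups[1]}_ci_lower": res.ci_b[0],
                f"{groups[1]}_ci_upper": res.ci_b[1],
                "t": res.t,
                "p": res.p,
                "cohens_d": res.d,
                "sig": flag,
            }
        )
    return pd.DataFrame(rows)
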