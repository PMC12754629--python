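"""Treatment-level statistics for biodiversity effects along the salinity gradient.

Given the partition table (one NBE/SE/CE triple per mixture x salinity), this
module reproduces the standard analysis surface: linear regression of each
effect against salinity restricted to the 0-15% range (the hypersaline 20%
level, where the system collapses, is excluded from trend fits but kept in
the treatment comparisons), classical one-way ANOVA across salinity
treatments, and Tukey HSD pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "EffectTrend",
    "AnovaResult",
    "effect_series",
    "effect_salinity_trend",
    "anova_oneway",
    "tukey_hsd",
    "selection_share",
    "run_effect_stats",
]

EFFECT_COLUMNS = {"NBE": "NBE", "SE": "SE", "CE": "CE"}


@dataclass
class EffectTrend:
    """OLS trend of one biodiversity effect against salinity."""

    effect: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    salinity_range: tuple

    def confidence_band(self, salinities, alpha: float = 0.05):
        """(lower, upper) of the mean-response band at the given salinities."""
        x = sm.add_constant(np.asarray(salinities, dtype=float))
        pred = self._fit.get_prediction(x).conf_int(alpha=alpha)
        return pred[:, 0], pred[:, 1]


@dataclass
class AnovaResult:
    """Classical one-way fixed-effects ANOVA across salinity treatments."""

    effect: str
    f: float
    p_value: float
    df_between: int
    df_within: int
    zero_within_variance: bool = False


def effect_series(partition_df: pd.DataFrame, effect: str, groups=None) -> pd.DataFrame:
    """Long series (salinity_pct, community_id, value) for one effect.

    ``groups`` restricts to communities whose id starts with one of the given
    group letters (the replicate unit for treatment comparisons is, by
    default downstream, the highest-diversity group). Rows with NaN effects
    (collapsed mixtures) are dropped.
    """
    if effect not in EFFECT_COLUMNS:
        raise ValueError(f"effect must be one of {sorted(EFFECT_COLUMNS)} (got {effect!r})")
    df = partition_df
    if groups is not None and "community_id" in df.columns:
        prefixes = tuple(groups)
        df = df[df["community_id"].astype(str).str.startswith(prefixes)]
    out = df[["salinity_pct", "community_id", EFFECT_COLUMNS[effect]]].rename(
        columns={EFFECT_COLUMNS[effect]: "value"}
    )
    return out.dropna(subset=["value"]).reset_index(drop=True)


def effect_salinity_trend(
    series: pd.DataFrame,
    effect: str = "effect",
    salinity_range: tuple = (0.0, 15.0),
) -> EffectTrend:
    """OLS of effect value on salinity within an inclusive salinity window.

    Salinities outside ``salinity_range`` are excluded before fitting, so by
    default the 20% treatment never enters the regression. Requires >= 3
    distinct salinities inside the window.
    """
    lo, hi = salinity_range
    sub = series[(series["salinity_pct"] >= lo) & (series["salinity_pct"] <= hi)]
    n_levels = sub["salinity_pct"].nunique()
    if n_levels < 3:
        raise ValueError(
            f"trend needs >= 3 distinct salinities in [{lo}, {hi}] (found {n_levels})"
        )
    x = sm.add_constant(sub["salinity_pct"].to_numpy(dtype=float))
    fit = sm.OLS(sub["value"].to_numpy(dtype=float), x).fit()
    trend = EffectTrend(
        effect=effect,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=len(sub),
        salinity_range=(lo, hi),
    )
    trend._fit = fit
    return trend


def _grouped_values(series: pd.DataFrame):
    levels = sorted(series["salinity_pct"].unique())
    groups = [series.loc[series["salinity_pct"] == s, "value"].to_numpy(dtype=float)
              for s in levels]
    if len(levels) < 2:
        raise ValueError("need >= 2 salinity levels")
    for s, g in zip(levels, groups):
        if len(g) < 2:
            raise ValueError(f"salinity level {s} has a single replicate; need >= 2")
    return levels, groups


def anova_oneway(series: pd.DataFrame, effect: str = "effect") -> AnovaResult:
    """One-way fixed-effects ANOVA of effect values across salinity treatments.

    F = MS_between / MS_within with (k-1, n-k) degrees of freedom. A dataset
    with zero within-group variance is flagged: F = 0 (p = 1) when the group
    means are also identical, +inf (p = 0) otherwise.
    """
    levels, groups = _grouped_values(series)
    k = len(groups)
    n = sum(len(g) for g in groups)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within == 0.0:
        means = np.array([g.mean() for g in groups])
        degenerate = float(np.ptp(means)) == 0.0
        return AnovaResult(
            effect=effect,
            f=0.0 if degenerate else float("inf"),
            p_value=1.0 if degenerate else 0.0,
            df_between=k - 1,
            df_within=n - k,
            zero_within_variance=True,
        )
    f, p = scipy.stats.f_oneway(*groups)
    return AnovaResult(
        effect=effect,
        f=float(f),
        p_value=float(p),
        df_between=k - 1,
        df_within=n - k,
    )


def tukey_hsd(series: pd.DataFrame, effect: str = "effect", alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons between all salinity levels.

    Studentized-range adjusted p-values for every pair (k levels -> k(k-1)/2
    rows); ``diff`` is mean(level_b) - mean(level_a). With two groups the
    adjusted p equals the pooled two-sample t-test p.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    levels, groups = _grouped_values(series)
    res = scipy.stats.tukey_hsd(*groups)
    means = [g.mean() for g in groups]
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            p_adj = float(min(max(res.pvalue[i, j], np.finfo(float).tiny), 1.0))
            rows.append(
                {
                    "effect": effect,
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "diff": float(means[j] - means[i]),
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


def selection_share(partition_df: pd.DataFrame, groups=None) -> pd.Series:
    """Selection effect's share of the net biodiversity effect per salinity.

    Aggregated as sum(SE)/sum(NBE) over the (optionally group-restricted)
    replicates at each salinity; returned as a fraction indexed by salinity.
    """
    df = partition_df.dropna(subset=["SE", "NBE"])
    if groups is not None:
        prefixes = tuple(groups)
        df = df[df["community_id"].astype(str).str.startswith(prefixes)]
    sums = df.groupby("salinity_pct")[["SE", "NBE"]].sum()
    return sums["SE"] / sums["NBE"]


def run_effect_stats(
    partition_df: pd.DataFrame,
    effects=("NBE", "SE", "CE"),
    groups=("D",),
    salinity_range: tuple = (0.0, 15.0),
    alpha: float = 0.05,
) -> dict:
    """Full treatment-level analysis for each effect.

    Returns ``{"trends": ..., "anova": ..., "tukey": ...}`` DataFrames
    matching the trends_effects.csv / anova.csv / tukey.csv schemas. Trends
    are range-restricted; ANOVA and Tukey use all salinity levels.
    """
    trend_rows, anova_rows, tukey_tables = [], [], []
    for effect in effects:
        series = effect_series(partition_df, effect, groups=groups)
        trend = effect_salinity_trend(series, effect=effect, salinity_range=salinity_range)
        trend_rows.append(
            {
                "effect": effect,
                "slope": trend.slope,
                "intercept": trend.intercept,
                "R2": trend.r2,
                "p_value": trend.p_value,
                "n": trend.n,
            }
        )
        an = anova_oneway(series, effect=effect)
        anova_rows.append(
            {
                "effect": effect,
                "F": an.f,
                "df1": an.df_between,
                "df2": an.df_within,
                "p_value": an.p_value,
                "zero_within_variance": an.zero_within_variance,
            }
        )
        tukey_tables.append(tukey_hsd(series, effect=effect, alpha=alpha))
    return {
        "trends": pd.DataFrame(trend_rows),
        "anova": pd.DataFrame(anova_rows),
        "tukey": pd.concat(tukey_tables, ignore_index=True),
    }
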