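"""Group-comparison statistics and dual z-score heatmap normalization.

Every comparison is routed through a normality check (Shapiro-Wilk at alpha = 0.05):
if all groups pass, the t family is used (independent or paired) and summaries are
mean +/- SEM; otherwise the nonparametric family (Mann-Whitney U between groups,
Wilcoxon signed-rank within subjects) with median +/- IQR summaries. Two-factor
designs use a two-way ANOVA with Tukey HSD post hoc tests.

Heatmaps use z = (x - mu) / sigma with sample SD (n - 1), under two complementary
normalization populations: across mice within one region (compare animals) or across
regions within one mouse (compare regions). Statistical outliers (Tukey 1.5 x IQR
fences) are excluded from mu and sigma and rendered as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SHAPIRO_ALPHA = 0.05

TEST_INDEPENDENT_T = "independent-t"
TEST_PAIRED_T = "paired-t"
TEST_MANN_WHITNEY = "Mann-Whitney U"
TEST_WILCOXON = "Wilcoxon signed-rank"

MODE_ACROSS_MOUSE = "across_mouse_within_region"
MODE_WITHIN_MOUSE = "within_mouse_across_regions"


@dataclass(frozen=True)
class GroupComparison:
    region: str
    channel: str
    test_name: str
    statistic: float
    p_value: float
    effect_direction: int  # sign of (group1 location - group2 location)
    group1_summary: str
    group2_summary: str
    n1: int
    n2: int


def route_test(samples_by_group: list[np.ndarray], paired: bool = False) -> str:
    """Choose the test family from per-group Shapiro-Wilk normality at alpha = 0.05.

    All groups normal -> t family (paired or independent); any group non-normal ->
    nonparametric (Wilcoxon signed-rank if paired, Mann-Whitney U otherwise). For a
    paired design the normality check is applied to the paired differences.
    """
    groups = [np.asarray(g, dtype=float) for g in samples_by_group]
    if any(len(g) < 3 for g in groups):
        raise ValueError("need at least 3 values per group for normality routing")
    if paired:
        if len(groups) != 2 or len(groups[0]) != len(groups[1]):
            raise ValueError("paired routing needs two equal-length groups")
        diffs = groups[0] - groups[1]
        normal = _shapiro_normal(diffs)
        return TEST_PAIRED_T if normal else TEST_WILCOXON
    normal = all(_shapiro_normal(g) for g in groups)
    if normal:
        return TEST_INDEPENDENT_T
    return TEST_MANN_WHITNEY


def _shapiro_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:  # constant sample: Shapiro-Wilk undefined; treat as normal
        return True
    return sps.shapiro(x).pvalue >= SHAPIRO_ALPHA


def _mean_sem(x: np.ndarray) -> str:
    sem = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    return f"{x.mean():.3f} ± {sem:.3f} (mean ± SEM)"


def _median_iqr(x: np.ndarray) -> str:
    q1, q3 = np.percentile(x, [25, 75])
    return f"{np.median(x):.3f} ± {q3 - q1:.3f} (median ± IQR)"


def compare_groups(
    group1: np.ndarray,
    group2: np.ndarray,
    paired: bool = False,
    region: str = "",
    channel: str = "",
) -> GroupComparison:
    """Two-tailed comparison of two samples with normality routing.

    Degenerate input (zero variance in both groups with equal means) returns p = 1 by
    convention. Mann-Whitney uses exact enumeration for n <= 8 per group and the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    test = route_test([x, y], paired=paired)
    degenerate = np.ptp(x) == 0 and np.ptp(y) == 0 and x.mean() == y.mean()
    if degenerate:
        stat, p = 0.0, 1.0
    elif test == TEST_INDEPENDENT_T:
        stat, p = sps.ttest_ind(x, y)
    elif test == TEST_PAIRED_T:
        stat, p = sps.ttest_rel(x, y)
    elif test == TEST_MANN_WHITNEY:
        method = "exact" if max(len(x), len(y)) <= 8 and np.unique(np.r_[x, y]).size == len(x) + len(y) else "asymptotic"
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    else:
        d = x - y
        if np.all(d == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(x, y)
    parametric = test in (TEST_INDEPENDENT_T, TEST_PAIRED_T)
    loc1 = x.mean() if parametric else np.median(x)
    loc2 = y.mean() if parametric else np.median(y)
    summ = _mean_sem if parametric else _median_iqr
    return GroupComparison(
        region=region,
        channel=channel,
        test_name=test,
        statistic=float(stat),
        p_value=float(p),
        effect_direction=int(np.sign(loc1 - loc2)),
        group1_summary=summ(x),
        group2_summary=summ(y),
        n1=len(x),
        n2=len(y),
    )


def two_way_anova_tukey(
    table: pd.DataFrame, value: str, factor_a: str, factor_b: str
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Two-way ANOVA (main effects + interaction) with Tukey HSD post hoc tests.

    Returns the ANOVA table (F and p for both main effects and the interaction) and
    Tukey results per factor (pairwise level comparisons via the studentized range).
    An empty design cell raises with the cell named. All-equal observations return
    F = 0, p = 1 by convention.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table[[value, factor_a, factor_b]].dropna().copy()
    levels_a = df[factor_a].unique()
    levels_b = df[factor_b].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("need at least 2 levels per factor")
    counts = df.groupby([factor_a, factor_b], sort=False).size()
    for a in levels_a:
        for b in levels_b:
            n = counts.get((a, b), 0)
            if n < 2:
                raise ValueError(f"design cell ({a}, {b}) has {n} replicates; need >= 2")
    if np.ptp(df[value].to_numpy(float)) == 0:
        idx = [f"C({factor_a})", f"C({factor_b})", f"C({factor_a}):C({factor_b})", "Residual"]
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": [0.0, 0.0, 0.0, np.nan],
             "PR(>F)": [1.0, 1.0, 1.0, np.nan]},
            index=idx,
        )
        tukey = {}
        return anova, tukey
    df = df.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(_fa)": f"C({factor_a})",
            "C(_fb)": f"C({factor_b})",
            "C(_fa):C(_fb)": f"C({factor_a}):C({factor_b})",
        }
    )
    tukey = {}
    for name, col in ((factor_a, "_fa"), (factor_b, "_fb")):
        res = pairwise_tukeyhsd(df["_y"], df[col])
        tukey[name] = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return anova, tukey


def flag_outliers(values: np.ndarray) -> np.ndarray:
    """Tukey-fence outlier mask: True where a value lies outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR]. NaNs are never flagged (they are already missing)."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise ValueError("need at least 4 values to flag outliers")
    q1, q3 = np.percentile(x[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = np.zeros_like(x, dtype=bool)
    mask[finite] = (x[finite] < lo) | (x[finite] > hi)
    return mask


@dataclass(frozen=True)
class ZScoreMatrix:
    """Mice x regions z-scores with normalization mode and outlier mask.

    ``values`` keeps the mice-as-rows orientation in both modes; ``outlier_mask`` is
    True where an entry was excluded before mu/sigma computation (rendered missing).
    ``degenerate_mask`` marks populations with sigma = 0 where z = 0 was assigned by
    convention.
    """

    values: pd.DataFrame
    normalization_mode: str
    outlier_mask: pd.DataFrame
    degenerate_mask: pd.DataFrame


def zscore(
    matrix: pd.DataFrame, mode: str, exclude_outliers: bool = True
) -> ZScoreMatrix:
    """Dual-mode z-score normalization of a mice x regions density matrix.

    mode ``across_mouse_within_region``: mu and sigma are computed over all mice
    (both groups) within one region (column populations). mode
    ``within_mouse_across_regions``: over all regions within one mouse (row
    populations). Sample SD (n - 1). Statistical outliers (1.5 x IQR fences) are
    excluded before conversion when ``exclude_outliers``; sigma = 0 populations get
    z = 0 and a degenerate flag. Populations of fewer than 2 retained values raise.
    """
    if mode not in (MODE_ACROSS_MOUSE, MODE_WITHIN_MOUSE):
        raise ValueError(f"unknown normalization mode {mode!r}")
    axis_populations = matrix.columns if mode == MODE_ACROSS_MOUSE else matrix.index
    z = pd.DataFrame(np.nan, index=matrix.index, columns=matrix.columns)
    out_mask = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    degen = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    for key in axis_populations:
        vec = matrix[key] if mode == MODE_ACROSS_MOUSE else matrix.loc[key]
        x = vec.to_numpy(dtype=float)
        if exclude_outliers and np.isfinite(x).sum() >= 4:
            flagged = flag_outliers(x)
        else:
            flagged = np.zeros(len(x), dtype=bool)
        retained = np.isfinite(x) & ~flagged
        if retained.sum() < 2:
            raise ValueError(f"normalization population {key!r} has fewer than 2 retained values")
        mu = x[retained].mean()
        sigma = x[retained].std(ddof=1)
        if sigma == 0:
            zvec = np.where(retained, 0.0, np.nan)
            is_degen = True
        else:
            zvec = np.where(retained, (x - mu) / sigma, np.nan)
            is_degen = False
        if mode == MODE_ACROSS_MOUSE:
            z[key] = zvec
            out_mask[key] = flagged
            degen[key] = is_degen
        else:
            z.loc[key] = zvec
            out_mask.loc[key] = flagged
            degen.loc[key] = is_degen
    return ZScoreMatrix(z, mode, out_mask, degen)


def order_by_usv(
    zmatrix: ZScoreMatrix, usv_counts: pd.Series, groups: pd.Series,
    exposed_label: str = "female-exposure",
) -> ZScoreMatrix:
    """Reorder mice: exposed sorted descending by USV count, controls kept in input
    order in their own block after the exposed block. Stable sort, so equal counts
    preserve input order. Raises on a missing count for an exposed mouse."""
    mice = zmatrix.values.index
    exposed = [m for m in mice if groups.get(m) == exposed_label]
    controls = [m for m in mice if groups.get(m) != exposed_label]
    for m in exposed:
        if m not in usv_counts.index or not np.isfinite(usv_counts[m]):
            raise ValueError(f"missing USV count for exposed mouse {m!r}")
    exposed_sorted = sorted(exposed, key=lambda m: -usv_counts[m])  # stable
    new_order = exposed_sorted + controls
    return ZScoreMatrix(
        zmatrix.values.loc[new_order],
        zmatrix.normalization_mode,
        zmatrix.outlier_mask.loc[new_order],
        zmatrix.degenerate_mask.loc[new_order],
    )
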