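"""Correlation of regional activation with USV output and functional classification.

Each region's per-mouse density (exposed mice only: controls emit no USVs and would
manufacture correlation) is tested against per-mouse USV counts with Pearson's r;
p is two-tailed from the t transform t = r sqrt(n-2) / sqrt(1-r^2) with df = n - 2,
and a 95% CI on r comes from the Fisher z transform. Regions are then classified:

* usv-positive / usv-negative  — significant correlation (sign of r),
* social-interaction-related   — no correlation but a significant group effect,
* unrelated                    — neither.

A correlation counts as *strong* when |r| > 0.7 and R^2 > 0.5. Anteroposterior
profiles repeat the correlation per bregma bin to localize the coupled extent of a
region along the rostrocaudal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GroupComparison

ALPHA_DEFAULT = 0.05
STRONG_R = 0.7
STRONG_R2 = 0.5

CATEGORY_UNRELATED = "unrelated"
CATEGORY_SOCIAL = "social-interaction-related"
CATEGORY_USV_POSITIVE = "usv-positive"
CATEGORY_USV_NEGATIVE = "usv-negative"


@dataclass(frozen=True)
class CorrelationResult:
    region: str
    channel: str
    n: int
    r: float
    R2: float
    p: float
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    undefined: bool = False  # zero variance in either variable


@dataclass(frozen=True)
class RegionClassification:
    region: str
    category: str
    strong: bool
    correlation: CorrelationResult | None
    group_comparison: GroupComparison | None
    note: str = ""


def r_to_R2(r: float) -> float:
    """Coefficient of determination of a simple linear fit: R^2 = r^2."""
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    return float(r) ** 2


def correlate_region(
    densities: pd.Series | np.ndarray,
    usv_counts: pd.Series | np.ndarray,
    region: str = "",
    channel: str = "",
) -> CorrelationResult:
    """Pearson correlation of per-mouse densities with USV counts.

    Needs n >= 3 paired values. Zero variance in either variable flags the result
    undefined (r, p = NaN) rather than raising.
    """
    x = np.asarray(usv_counts, dtype=float)
    y = np.asarray(densities, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 mice with both density and USV count")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(region, channel, n, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, np.nan, np.nan, undefined=True)
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    if n > 3 and abs(r) < 1:
        zr = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = sps.norm.ppf(0.975)
        ci_low, ci_high = np.tanh(zr - zc * se), np.tanh(zr + zc * se)
    else:
        ci_low = ci_high = np.nan
    return CorrelationResult(
        region=region, channel=channel, n=n,
        r=float(r), R2=r_to_R2(r), p=float(p),
        slope=float(slope), intercept=float(intercept),
        ci_low=float(ci_low), ci_high=float(ci_high),
    )


def classify_region(
    group_cmp: GroupComparison | None,
    corr: CorrelationResult,
    alpha: float = ALPHA_DEFAULT,
) -> RegionClassification:
    """Three-way functional classification of one region.

    Decision table: a significant correlation (corr.p < alpha) makes the region
    usv-positive or usv-negative by the sign of r; otherwise a significant group
    effect (group_cmp.p < alpha) makes it social-interaction-related; otherwise
    unrelated. The strong flag is set iff |r| > 0.7 and R^2 > 0.5, independent of
    the category. An undefined correlation restricts the choice to the social /
    unrelated branch with a note.
    """
    note = ""
    if corr.undefined or not np.isfinite(corr.p):
        note = "correlation undefined (zero variance); social/unrelated branch only"
        category = None
    elif corr.p < alpha:
        category = CATEGORY_USV_POSITIVE if corr.r > 0 else CATEGORY_USV_NEGATIVE
    else:
        category = None
    if category is None:
        if group_cmp is not None and group_cmp.p_value < alpha:
            category = CATEGORY_SOCIAL
        else:
            category = CATEGORY_UNRELATED
    strong = (
        not corr.undefined
        and np.isfinite(corr.r)
        and abs(corr.r) > STRONG_R
        and corr.R2 > STRONG_R2
    )
    return RegionClassification(
        region=corr.region, category=category, strong=strong,
        correlation=corr, group_comparison=group_cmp, note=note,
    )


@dataclass(frozen=True)
class ApProfile:
    """Bregma-binned correlation profile of one region."""

    region: str
    bin_edges_mm: np.ndarray  # descending rostral -> caudal? stored ascending
    table: pd.DataFrame  # bin_center_mm, n, r, R2, p, insufficient
    peak_bin_mm: float | None  # centre of the max-R^2 bin among significant bins


def ap_profile(
    section_records: pd.DataFrame,
    usv_counts: pd.Series,
    bin_width_mm: float = 0.2,
    region: str = "",
    density_col: str = "density_td",
    alpha: float = ALPHA_DEFAULT,
    min_mice: int = 3,
) -> ApProfile:
    """Anteroposterior correlation profile of a region.

    ``section_records`` needs ``mouse_id``, ``bregma_mm`` and the density column.
    Bins of ``bin_width_mm`` are anchored at atlas-round coordinates (integer
    multiples of the bin width). Per bin, each mouse's densities are averaged, then
    correlated against USV counts; bins reaching fewer than ``min_mice`` mice are
    flagged insufficient. The peak is the max-R^2 bin among bins with p < alpha
    (None when no bin is significant).
    """
    df = section_records
    if len(df) == 0:
        raise ValueError("empty region: no section records")
    b = df["bregma_mm"].to_numpy(float)
    lo = np.floor(b.min() / bin_width_mm) * bin_width_mm
    hi = np.ceil(b.max() / bin_width_mm) * bin_width_mm
    if hi <= lo:
        hi = lo + bin_width_mm
    edges = np.arange(lo, hi + bin_width_mm / 2, bin_width_mm)
    rows = []
    for k in range(len(edges) - 1):
        e0, e1 = edges[k], edges[k + 1]
        # half-open [e0, e1); top edge closed on the last (most anterior) bin
        sel = (b >= e0) & ((b < e1) | (k == len(edges) - 2) & (b == e1))
        chunk = df.loc[sel]
        center = (e0 + e1) / 2
        per_mouse = chunk.groupby("mouse_id")[density_col].mean()
        per_mouse = per_mouse[per_mouse.index.isin(usv_counts.index)]
        if len(per_mouse) < min_mice:
            rows.append({"bin_center_mm": center, "n": len(per_mouse),
                         "r": np.nan, "R2": np.nan, "p": np.nan, "insufficient": True})
            continue
        res = correlate_region(per_mouse, usv_counts.loc[per_mouse.index], region=region)
        rows.append({"bin_center_mm": center, "n": res.n, "r": res.r,
                     "R2": res.R2, "p": res.p, "insufficient": False})
    table = pd.DataFrame(rows)
    sig = table[(~table["insufficient"]) & (table["p"] < alpha)]
    peak = float(sig.loc[sig["R2"].idxmax(), "bin_center_mm"]) if len(sig) else None
    return ApProfile(region=region, bin_edges_mm=edges, table=table, peak_bin_mm=peak)
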