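"""End-to-end analysis pipeline over a cohort of sections.

Composes the quantification, statistics and classification stages:
section cell tables + ROI polygons -> per-section density records -> bregma
subregion labels -> per-mouse averages -> group comparisons, z-score heatmaps and
USV-correlation classification; and the striatal compartment branch -> per-quadrant
compartment densities -> control-normalized folds -> two-way ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import correlation as corrmod
from . import roi as roimod
from . import stats as statsmod
from . import striatum as strimod
from .synthetic import GROUP_CONTROL, GROUP_EXPOSED, SyntheticExperiment


def quantify_sections(
    sections,
    tol_um: float = roimod.DEFAULT_COLOC_TOL_UM,
    region_rules: dict | None = None,
) -> pd.DataFrame:
    """Per-section quantification of an iterable of SectionRecord-like objects,
    with bregma subregion labels applied."""
    rows = []
    for sec in sections:
        rec = roimod.quantify_section(sec.cells, list(sec.rois), tol_um=tol_um)
        rec["mouse_id"] = sec.mouse_id
        rec["section_id"] = sec.section_id
        rows.append(rec)
    table = pd.DataFrame(rows)
    return roimod.split_by_bregma(table, region_rules)


def per_mouse_table(section_table: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse per-subregion aggregation of the section table."""
    return roimod.aggregate_mouse(section_table)


def density_matrix(per_mouse: pd.DataFrame, value: str = "density_td") -> pd.DataFrame:
    """Mice x regions matrix of one density column."""
    return per_mouse.pivot(index="mouse_id", columns="region", values=value)


def group_comparisons(
    per_mouse: pd.DataFrame,
    mice: pd.DataFrame,
    value: str = "density_td",
    channel: str = "tdTomato",
) -> dict[str, statsmod.GroupComparison]:
    """Exposed-vs-control comparison per region with normality routing."""
    merged = per_mouse.merge(mice[["mouse_id", "group"]], on="mouse_id")
    out = {}
    for region, chunk in merged.groupby("region", sort=True):
        exposed = chunk.loc[chunk["group"] == GROUP_EXPOSED, value].to_numpy(float)
        control = chunk.loc[chunk["group"] == GROUP_CONTROL, value].to_numpy(float)
        out[region] = statsmod.compare_groups(
            exposed, control, paired=False, region=region, channel=channel
        )
    return out


def region_correlations(
    per_mouse: pd.DataFrame,
    mice: pd.DataFrame,
    value: str = "density_td",
    channel: str = "tdTomato",
) -> dict[str, corrmod.CorrelationResult]:
    """Per-region Pearson correlation with USV counts over exposed mice only."""
    exposed = mice[mice["group"] == GROUP_EXPOSED].set_index("mouse_id")["usv_count"]
    out = {}
    for region, chunk in per_mouse.groupby("region", sort=True):
        d = chunk.set_index("mouse_id")[value]
        d = d[d.index.isin(exposed.index)]
        out[region] = corrmod.correlate_region(
            d, exposed.loc[d.index], region=region, channel=channel
        )
    return out


def classify_regions(
    per_mouse: pd.DataFrame,
    mice: pd.DataFrame,
    value: str = "density_td",
    alpha: float = corrmod.ALPHA_DEFAULT,
) -> dict[str, corrmod.RegionClassification]:
    """Full functional classification: group comparison + correlation per region."""
    cmps = group_comparisons(per_mouse, mice, value=value)
    corrs = region_correlations(per_mouse, mice, value=value)
    return {
        region: corrmod.classify_region(cmps.get(region), corrs[region], alpha=alpha)
        for region in corrs
    }


def zscore_heatmaps(
    per_mouse: pd.DataFrame,
    mice: pd.DataFrame,
    value: str = "density_td",
) -> dict[str, statsmod.ZScoreMatrix]:
    """Both normalization modes, rows ordered by USV count within the exposed block."""
    matrix = density_matrix(per_mouse, value=value)
    usv = mice.set_index("mouse_id")["usv_count"]
    groups = mice.set_index("mouse_id")["group"]
    out = {}
    for mode in (statsmod.MODE_ACROSS_MOUSE, statsmod.MODE_WITHIN_MOUSE):
        z = statsmod.zscore(matrix, mode)
        out[mode] = statsmod.order_by_usv(z, usv, groups, exposed_label=GROUP_EXPOSED)
    return out


def analyze_experiment(exp: SyntheticExperiment, value: str = "density_td") -> dict:
    """Quantify + compare + correlate + classify a synthetic experiment."""
    section_table = quantify_sections(exp.sections)
    per_mouse = per_mouse_table(section_table)
    return {
        "section_table": section_table,
        "per_mouse": per_mouse,
        "comparisons": group_comparisons(per_mouse, exp.mice, value=value),
        "correlations": region_correlations(per_mouse, exp.mice, value=value),
        "classifications": classify_regions(per_mouse, exp.mice, value=value),
    }


# ---------------------------------------------------------------------------
# striatal compartment branch
# ---------------------------------------------------------------------------

def striatal_mouse_densities(
    section_results: list[tuple[pd.DataFrame, strimod.CompartmentMask, strimod.QuadrantPartition]],
) -> pd.DataFrame:
    """Average per-quadrant per-compartment densities over one mouse's sections.

    Each element is (cells, mask, partition); cells are labeled and binned per
    section, then densities are averaged unweighted across sections.
    """
    per_section = []
    for cells, mask, partition in section_results:
        labeled = strimod.assign_compartment(cells, mask)
        per_section.append(strimod.compartment_density(labeled, mask, partition))
    allsec = pd.concat(per_section, ignore_index=True)
    return (
        allsec.groupby(["quadrant", "compartment"], sort=True)["density"]
        .mean()
        .reset_index()
    )


def striatal_fold_table(
    mouse_densities: dict[str, pd.DataFrame], groups: dict[str, str]
) -> pd.DataFrame:
    """Exposed-mouse densities normalized to the control mean of the same
    compartment within the same quadrant (long table for the two-way ANOVA)."""
    rows = []
    for mouse, dens in mouse_densities.items():
        d = dens.copy()
        d["mouse_id"] = mouse
        d["group"] = groups[mouse]
        rows.append(d)
    long = pd.concat(rows, ignore_index=True)
    ctrl = (
        long[long["group"] == GROUP_CONTROL]
        .groupby(["quadrant", "compartment"])["density"]
        .mean()
        .rename("control_mean")
        .reset_index()
    )
    exposed = long[long["group"] == GROUP_EXPOSED].merge(ctrl, on=["quadrant", "compartment"])
    exposed["fold_vs_control"] = [
        strimod.normalize_to_control(d, c) if c > 0 else np.nan
        for d, c in zip(exposed["density"], exposed["control_mean"])
    ]
    return exposed
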