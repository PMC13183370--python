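"""ROI-based cell quantification.

Turns per-section cell-detection tables (QuPath-style exports) and region-of-interest
polygons into per-mouse, per-region densities, double-label (reactivation) counts and
bregma-resolved subregion tables.

Conventions
-----------
* Image coordinates are in micrometres, origin at the top-left corner, y increasing
  ventrally. Bregma coordinates are in millimetres, positive anterior.
* A cell whose centroid lies exactly on an ROI boundary counts as inside.
* Left and right hemispheres are pooled within a section before densities are computed.
* Densities are cells per square millimetre; per-mouse values are unweighted means of
  per-section densities ("averaged across all sections within each region of interest").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

CHANNEL_TDTOMATO = "tdTomato"
CHANNEL_CFOS = "cFos"

#: Default mutual-nearest-neighbour tolerance for calling a tdTomato/c-Fos pair
#: double-labeled, in micrometres (about one nuclear radius at the 10 um detection scale).
DEFAULT_COLOC_TOL_UM = 8.0

CELL_COLUMNS = ["x_um", "y_um", "channel", "intensity", "area_um2"]


def empty_cell_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "channel": pd.Series(dtype=object),
            "intensity": pd.Series(dtype=float),
            "area_um2": pd.Series(dtype=float),
        }
    )


@dataclass(frozen=True)
class RoiAnnotation:
    """A named brain-region polygon on one coronal section.

    Parameters
    ----------
    region : str
        Region label (e.g. ``"PrL"``, ``"cPAG"``).
    hemisphere : str
        ``"left"`` or ``"right"``.
    bregma_mm : float
        Anteroposterior coordinate of the section, millimetres, positive anterior.
    polygon : shapely.geometry.Polygon
        Simple closed polygon in micrometre image coordinates.
    """

    region: str
    hemisphere: str
    bregma_mm: float
    polygon: Polygon = field(compare=False)

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(
                f"ROI polygon for {self.region} ({self.hemisphere}) is degenerate "
                "(invalid or zero area)"
            )
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")

    @property
    def area_mm2(self) -> float:
        """Polygon area converted from um^2 to mm^2."""
        return self.polygon.area / 1e6


def assign_cells(cells: pd.DataFrame, roi: RoiAnnotation) -> pd.DataFrame:
    """Keep the cells whose centroid is inside or on the boundary of ``roi``."""
    if len(cells) == 0:
        return cells.copy()
    pts = shapely.points(cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float))
    inside = shapely.covers(roi.polygon, pts)  # covers: boundary counts as inside
    return cells.loc[inside].copy()


def density(cells: pd.DataFrame, roi: RoiAnnotation) -> dict:
    """Cell count and density (cells/mm^2) of ``cells`` within one ROI."""
    area = roi.area_mm2
    if area <= 0:
        raise ValueError("ROI area must be positive")
    inside = assign_cells(cells, roi)
    n = int(len(inside))
    return {
        "region": roi.region,
        "hemisphere": roi.hemisphere,
        "bregma_mm": roi.bregma_mm,
        "n_cells": n,
        "area_mm2": area,
        "density": n / area,
    }


def match_double_labeled(
    td: pd.DataFrame, fos: pd.DataFrame, tol_um: float = DEFAULT_COLOC_TOL_UM
) -> list[tuple[int, int, float]]:
    """One-to-one matching of two channels within a distance tolerance.

    A pair is valid iff the centroid distance is <= ``tol_um``. The matching is the
    one-to-one assignment that maximises the number of valid pairs and, among those,
    minimises the total matched distance (Hungarian assignment on the distance
    matrix with out-of-tolerance pairs priced prohibitively). Each cell enters at
    most one pair; the result is deterministic, and symmetric in the two tables for
    continuous coordinates (exact distance ties have measure zero).

    Returns
    -------
    list of (i, j, distance_um)
        Positional row indices into ``td`` and ``fos``, sorted by ``i``.
    """
    if len(td) == 0 or len(fos) == 0:
        return []
    from scipy.optimize import linear_sum_assignment

    a = td[["x_um", "y_um"]].to_numpy(float)
    b = fos[["x_um", "y_um"]].to_numpy(float)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    if not (d <= tol_um).any():
        return []
    big = tol_um * (d.size + 1) + d[d <= tol_um].sum() + 1.0
    cost = np.where(d <= tol_um, d, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j), float(d[i, j]))
        for i, j in zip(rows, cols)
        if d[i, j] <= tol_um
    ]
    return sorted(pairs)


def double_label_percentages(n_double: int, n_cfos: int, n_tdtomato: int) -> dict:
    """Double-label percentages relative to each channel's total.

    ``pct_double_of_cfos = 100 * n_double / n_cfos`` and analogously for tdTomato.
    A zero denominator makes the corresponding percentage undefined (NaN) and flags
    the record so it can be excluded from group statistics.
    """
    if n_double > min(n_cfos, n_tdtomato):
        raise ValueError("n_double cannot exceed either channel count")
    flagged = n_cfos == 0 or n_tdtomato == 0
    return {
        "pct_double_of_cfos": 100.0 * n_double / n_cfos if n_cfos > 0 else np.nan,
        "pct_double_of_tdtomato": 100.0 * n_double / n_tdtomato if n_tdtomato > 0 else np.nan,
        "undefined_percentage": flagged,
    }


# Bregma subdivision rules used in the analysis: the caudoputamen is split at +0.62 and
# -1.02 mm, the periaqueductal gray at -4.2 mm. Intervals are half-open with the
# boundary belonging to the more rostral subregion.
DEFAULT_REGION_RULES: dict[str, list[tuple[str, float, float]]] = {
    "CPu": [
        ("rCPu", 0.62, float("inf")),
        ("cCPu", -1.02, 0.62),
        ("tCPu", float("-inf"), -1.02),
    ],
    "PAG": [
        ("rPAG", -4.2, float("inf")),
        ("cPAG", float("-inf"), -4.2),
    ],
}


def split_by_bregma(
    records: pd.DataFrame,
    region_rules: dict[str, list[tuple[str, float, float]]] | None = None,
) -> pd.DataFrame:
    """Assign subregion labels to per-section records from bregma intervals.

    ``region_rules`` maps a region name to ``[(subregion, low_mm, high_mm), ...]``
    half-open intervals ``[low, high)`` read against the section's ``bregma_mm``:
    a boundary value belongs to the more rostral (higher-bregma) subregion because
    each interval includes its own lower edge. Sections of a ruled region that fall
    outside every interval are flagged ``excluded``. Regions without a rule keep
    their own name as subregion.
    """
    if region_rules is None:
        region_rules = DEFAULT_REGION_RULES
    out = records.reset_index(drop=True)
    sub = out["region"].to_numpy(object).copy()
    drop = np.zeros(len(out), dtype=bool)
    bregma = out["bregma_mm"].to_numpy(float)
    region_col = out["region"].to_numpy(object)
    for region, rules in region_rules.items():
        mask = region_col == region
        if not mask.any():
            continue
        assigned = np.full(len(out), None, dtype=object)
        for name, low, high in rules:
            hit = mask & (assigned == None) & (bregma >= low) & (bregma < high)  # noqa: E711
            assigned[hit] = name
        sub[mask] = assigned[mask]
        drop[mask] = assigned[mask] == None  # noqa: E711
    out = out.copy()
    out["subregion"] = sub
    return out.loc[~drop].reset_index(drop=True)


def quantify_section(
    cells: pd.DataFrame,
    rois: list[RoiAnnotation],
    tol_um: float = DEFAULT_COLOC_TOL_UM,
) -> dict:
    """Quantify one region on one section, pooling hemispheres.

    All ``rois`` must belong to the same region and section (same bregma). Cells of
    each channel are assigned to the pooled ROI polygons; double-labeled pairs are
    matched across the pooled cells.
    """
    regions = {r.region for r in rois}
    if len(regions) != 1:
        raise ValueError(f"quantify_section expects one region, got {sorted(regions)}")
    region = rois[0].region
    bregma = rois[0].bregma_mm
    area = sum(r.area_mm2 for r in rois)
    kept = [assign_cells(cells, r) for r in rois]
    pooled = pd.concat(kept, ignore_index=True) if kept else empty_cell_table()
    td = pooled[pooled["channel"] == CHANNEL_TDTOMATO]
    fos = pooled[pooled["channel"] == CHANNEL_CFOS]
    pairs = match_double_labeled(td, fos, tol_um=tol_um)
    n_td, n_fos, n_double = len(td), len(fos), len(pairs)
    pct = double_label_percentages(n_double, n_fos, n_td)
    return {
        "region": region,
        "bregma_mm": bregma,
        "area_mm2": area,
        "n_td": n_td,
        "n_fos": n_fos,
        "n_double": n_double,
        "density_td": n_td / area,
        "density_fos": n_fos / area,
        "density_double": n_double / area,
        **pct,
    }


def aggregate_mouse(section_records: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse per-(sub)region averages of per-section quantities.

    Densities and percentages are unweighted means over sections; counts and areas
    are summed so that totals remain auditable. NaN percentages (zero-denominator
    sections) are ignored in the averages.
    """
    key = ["mouse_id", "subregion"] if "subregion" in section_records else ["mouse_id", "region"]
    grouped = section_records.groupby(key, sort=True)
    out = grouped.agg(
        n_sections=("area_mm2", "size"),
        n_td=("n_td", "sum"),
        n_fos=("n_fos", "sum"),
        n_double=("n_double", "sum"),
        area_mm2=("area_mm2", "sum"),
        density_td=("density_td", "mean"),
        density_fos=("density_fos", "mean"),
        density_double=("density_double", "mean"),
        pct_double_of_cfos=("pct_double_of_cfos", "mean"),
        pct_double_of_tdtomato=("pct_double_of_tdtomato", "mean"),
    ).reset_index()
    if "subregion" in out.columns:
        out = out.rename(columns={"subregion": "region"})
    return out


#: Default detection parameters per channel: (background radius um, median radius um,
#: intensity threshold). Values follow common QuPath-style settings for these stains.
DEFAULT_DETECTION_PARAMS = {
    CHANNEL_TDTOMATO: {"background_radius_um": 10.0, "median_radius_um": 10.0, "threshold": 20.0},
    CHANNEL_CFOS: {"background_radius_um": 10.0, "median_radius_um": 8.0, "threshold": 10.0},
}


def detect_cells_simple(
    image: np.ndarray,
    um_per_px: float,
    background_radius_um: float = 10.0,
    median_radius_um: float = 10.0,
    threshold: float = 20.0,
) -> pd.DataFrame:
    """Simple blob detection on a single-channel image (synthetic images only).

    Pipeline: rolling-ball background subtraction -> median filter -> global intensity
    threshold -> connected components -> centroid and area per component. Deterministic.
    Coordinates are returned in micrometres (x = column * scale, y = row * scale).
    """
    if um_per_px is None or um_per_px <= 0:
        raise ValueError("um_per_px pixel scale is required and must be positive")
    from skimage import measure, morphology, restoration
    from skimage.filters import median as median_filter

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    bg = restoration.rolling_ball(img, radius=max(1, round(background_radius_um / um_per_px)))
    img = img - bg
    footprint = morphology.disk(max(1, round(median_radius_um / um_per_px / 2)))
    img = median_filter(img, footprint=footprint)
    labels = measure.label(img > threshold)
    rows = []
    for prop in measure.regionprops(labels, intensity_image=img):
        cy, cx = prop.centroid
        rows.append(
            {
                "x_um": cx * um_per_px,
                "y_um": cy * um_per_px,
                "channel": "",
                "intensity": float(prop.intensity_mean),
                "area_um2": float(prop.area) * um_per_px**2,
            }
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS) if rows else empty_cell_table()


def density_long(per_mouse: pd.DataFrame, mice: pd.DataFrame) -> pd.DataFrame:
    """Reshape the per-mouse wide table to the long export format.

    One row per (mouse, region, channel) where channel is tdTomato, cFos or double.
    ``mice`` must carry ``mouse_id``, ``group`` and ``usv_count``.
    """
    rows = []
    merged = per_mouse.merge(mice[["mouse_id", "group", "usv_count"]], on="mouse_id")
    for channel, ncol, dcol in (
        (CHANNEL_TDTOMATO, "n_td", "density_td"),
        (CHANNEL_CFOS, "n_fos", "density_fos"),
        ("double", "n_double", "density_double"),
    ):
        part = merged[["mouse_id", "group", "usv_count", "region", "area_mm2"]].copy()
        part["channel"] = channel
        part["n_cells"] = merged[ncol]
        part["density"] = merged[dcol]
        part["n_double"] = merged["n_double"]
        part["pct_double_of_cfos"] = merged["pct_double_of_cfos"]
        part["pct_double_of_tdtomato"] = merged["pct_double_of_tdtomato"]
        rows.append(part)
    return pd.concat(rows, ignore_index=True)
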