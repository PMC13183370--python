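"""Caudoputamen quadrant segmentation and striosome/matrix compartment analysis.

The dorsal striatum (caudoputamen, CP) is divided into four quadrants — dorsomedial
(DM), dorsolateral (DL), ventromedial (VM), ventrolateral (VL) — by two internal
divider lines constructed from anatomical landmark lines on a coronal section:

* Line 1: tangent through the dorsal edges of the bilateral CP.
* Line 2: through the anterior-commissure point, parallel to Line 1.
* Line 3: segment from the lateral CP boundary to the dorsal tip of the nucleus
  accumbens shell (NAcs).
* Line 4: through the NAcs tip, perpendicular to Line 1.
* Line 5 (divider): through the midpoints of the Line-1 and Line-2 chords clipped to
  the CP extent — separates medial from lateral.
* Line 6 (divider): through the midpoints of the clipped Line-3 and Line-4 chords —
  separates dorsal from ventral.

Points exactly on a divider go to the medial (Line 5) / dorsal (Line 6) side.
Striosomes are consumed as MOR1+ polygons; the matrix is the CP minus striosomes.
All coordinates are micrometres, y increasing ventrally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.ops import split as shapely_split
from shapely.ops import unary_union

QUADRANTS = ("DM", "DL", "VM", "VL")
COMPARTMENT_STRIOSOME = "striosome"
COMPARTMENT_MATRIX = "matrix"
COMPARTMENT_OUTSIDE = "outside"


@dataclass(frozen=True)
class StriatalLandmarks:
    """Named landmark points (micrometres) for the quadrant construction."""

    dorsal_edge_left: tuple[float, float]
    dorsal_edge_right: tuple[float, float]
    ac_point: tuple[float, float]
    nacs_tip: tuple[float, float]
    lateral_boundary: tuple[float, float]

    def __post_init__(self) -> None:
        pts = [self.dorsal_edge_left, self.dorsal_edge_right, self.ac_point,
               self.nacs_tip, self.lateral_boundary]
        if not all(np.isfinite(p).all() for p in map(np.asarray, pts)):
            raise ValueError("all landmark points must be finite")
        if np.allclose(self.dorsal_edge_left, self.dorsal_edge_right):
            raise ValueError("dorsal edge points must be distinct")

    def transformed(self, fn) -> "StriatalLandmarks":
        """Apply a coordinate transform ``fn((x, y)) -> (x, y)`` to every landmark."""
        return StriatalLandmarks(*(tuple(fn(p)) for p in (
            self.dorsal_edge_left, self.dorsal_edge_right, self.ac_point,
            self.nacs_tip, self.lateral_boundary)))


@dataclass(frozen=True)
class _Divider:
    """Infinite line (point + unit direction) with the sign of its preferred side."""

    point: np.ndarray
    direction: np.ndarray
    keep_sign: float  # sign of the cross product on the medial/dorsal side

    def signed(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx, dy = self.direction
        return dx * (np.asarray(y) - self.point[1]) - dy * (np.asarray(x) - self.point[0])

    def on_keep_side(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        s = self.signed(x, y)
        return np.where(s == 0, True, np.sign(s) == self.keep_sign)


@dataclass(frozen=True)
class QuadrantPartition:
    """DM/DL/VM/VL polygons plus the construction lines retained for audit."""

    polygons: dict[str, Polygon | MultiPolygon]
    lines: dict[str, LineString] = field(compare=False)
    medial_divider: _Divider = field(compare=False)
    dorsal_divider: _Divider = field(compare=False)
    cp_polygon: Polygon = field(compare=False)

    def assign(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Quadrant label per point; ties on a divider go medial / dorsal."""
        medial = self.medial_divider.on_keep_side(x, y)
        dorsal = self.dorsal_divider.on_keep_side(x, y)
        out = np.where(dorsal, np.where(medial, "DM", "DL"), np.where(medial, "VM", "VL"))
        return out


def _chord(line_point: np.ndarray, direction: np.ndarray, cp: Polygon) -> tuple[LineString, np.ndarray]:
    """Clip the infinite line to the CP extent; return the chord and its midpoint."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    p = np.asarray(line_point, float)
    minx, miny, maxx, maxy = cp.bounds
    span = 4 * max(maxx - minx, maxy - miny) + 1.0
    long_line = LineString([tuple(p - span * d), tuple(p + span * d)])
    inter = long_line.intersection(cp)
    if inter.is_empty:
        # tangent lines (e.g. the dorsal tangent along a flat CP edge) can miss the
        # polygon by floating-point error; retry against a hair-buffered polygon
        inter = long_line.intersection(cp.buffer(max(1e-9, 1e-7 * span)))
    if inter.is_empty:
        raise ValueError("landmark line does not intersect the CP polygon")
    coords = np.asarray(shapely.get_coordinates(inter), float)
    ts = (coords - p) @ d
    mid = p + d * (ts.min() + ts.max()) / 2.0
    chord = LineString([tuple(p + ts.min() * d), tuple(p + ts.max() * d)])
    return chord, mid


def construct_quadrants(cp_polygon: Polygon, landmarks: StriatalLandmarks) -> QuadrantPartition:
    """Build the DM/DL/VM/VL partition of the CP from the landmark lines.

    Raises when Lines 5 and 6 come out parallel (degenerate landmark configuration),
    with the offending geometry in the message. Quadrant areas sum to the CP area by
    construction (two straight cuts).
    """
    if not cp_polygon.is_valid or cp_polygon.area <= 0:
        raise ValueError("CP polygon is degenerate")
    lm = landmarks
    p_l = np.asarray(lm.dorsal_edge_left, float)
    p_r = np.asarray(lm.dorsal_edge_right, float)
    d1 = (p_r - p_l) / np.linalg.norm(p_r - p_l)
    n1 = np.array([-d1[1], d1[0]])  # perpendicular to Line 1

    line1, m1 = _chord(p_l, d1, cp_polygon)
    line2, m2 = _chord(np.asarray(lm.ac_point, float), d1, cp_polygon)
    seg3 = LineString([lm.lateral_boundary, lm.nacs_tip]).intersection(cp_polygon)
    if seg3.is_empty:
        raise ValueError("Line 3 (lateral boundary to NAcs tip) misses the CP polygon")
    c3 = np.asarray(shapely.get_coordinates(seg3), float)
    d3 = np.asarray(lm.nacs_tip, float) - np.asarray(lm.lateral_boundary, float)
    d3 = d3 / np.linalg.norm(d3)
    t3 = (c3 - np.asarray(lm.lateral_boundary, float)) @ d3
    m3 = np.asarray(lm.lateral_boundary, float) + d3 * (t3.min() + t3.max()) / 2.0
    line3 = LineString([tuple(np.asarray(lm.lateral_boundary, float) + t3.min() * d3),
                        tuple(np.asarray(lm.lateral_boundary, float) + t3.max() * d3)])
    line4, m4 = _chord(np.asarray(lm.nacs_tip, float), n1, cp_polygon)

    d5 = m2 - m1
    d6 = m4 - m3
    if np.linalg.norm(d5) == 0 or np.linalg.norm(d6) == 0:
        raise ValueError(f"divider endpoints coincide: m1={m1}, m2={m2}, m3={m3}, m4={m4}")
    d5 = d5 / np.linalg.norm(d5)
    d6 = d6 / np.linalg.norm(d6)
    if abs(d5[0] * d6[1] - d5[1] * d6[0]) < 1e-9:
        raise ValueError(
            "degenerate landmark configuration: Lines 5 and 6 are parallel "
            f"(m1={m1}, m2={m2}, m3={m3}, m4={m4})"
        )

    # preferred sides: medial = side of Line 5 holding the anterior commissure
    # (midline); dorsal = side of Line 6 holding the Line-1 chord midpoint.
    div5 = _Divider(m1, d5, 0.0)
    s_ac = div5.signed(lm.ac_point[0], lm.ac_point[1])
    if s_ac == 0:
        s_ac = div5.signed(lm.nacs_tip[0], lm.nacs_tip[1])
    if s_ac == 0:
        raise ValueError("cannot orient the medial side of Line 5 from the landmarks")
    div5 = _Divider(m1, d5, float(np.sign(s_ac)))
    div6 = _Divider(m3, d6, 0.0)
    s_d = div6.signed(m1[0], m1[1])
    if s_d == 0:
        raise ValueError("cannot orient the dorsal side of Line 6 from the landmarks")
    div6 = _Divider(m3, d6, float(np.sign(s_d)))

    # split the CP by the two dividers and label the pieces by their interior point
    minx, miny, maxx, maxy = cp_polygon.bounds
    span = 4 * max(maxx - minx, maxy - miny) + 1.0
    l5 = LineString([tuple(m1 - span * d5), tuple(m1 + span * d5)])
    l6 = LineString([tuple(m3 - span * d6), tuple(m3 + span * d6)])
    pieces = []
    for part in shapely.get_parts(shapely_split(cp_polygon, l5)):
        pieces.extend(shapely.get_parts(shapely_split(part, l6)))
    buckets: dict[str, list] = {q: [] for q in QUADRANTS}
    for piece in pieces:
        rp = piece.representative_point()
        medial = bool(div5.on_keep_side(rp.x, rp.y))
        dorsal = bool(div6.on_keep_side(rp.x, rp.y))
        q = ("DM" if medial else "DL") if dorsal else ("VM" if medial else "VL")
        buckets[q].append(piece)
    polygons = {q: unary_union(parts) if parts else Polygon() for q, parts in buckets.items()}
    lines = {"line1": line1, "line2": line2, "line3": line3, "line4": line4,
             "line5": l5.intersection(cp_polygon.buffer(span / 8)),
             "line6": l6.intersection(cp_polygon.buffer(span / 8))}
    return QuadrantPartition(polygons, lines, div5, div6, cp_polygon)


@dataclass(frozen=True)
class CompartmentMask:
    """Striosome polygons (MOR1+) within a CP polygon; matrix is the remainder."""

    cp_polygon: Polygon
    striosomes: list[Polygon]

    @property
    def striosome_union(self):
        return unary_union(self.striosomes) if self.striosomes else Polygon()

    @property
    def matrix(self):
        return self.cp_polygon.difference(self.striosome_union)

    @property
    def striosome_fraction(self) -> float:
        return self.striosome_union.area / self.cp_polygon.area


def assign_compartment(cells: pd.DataFrame, mask: CompartmentMask) -> pd.DataFrame:
    """Label each cell striosome / matrix / outside (boundary counts as striosome,
    CP boundary as inside)."""
    out = cells.copy()
    if len(out) == 0:
        out["compartment"] = pd.Series(dtype=object)
        return out
    pts = shapely.points(out["x_um"].to_numpy(float), out["y_um"].to_numpy(float))
    in_cp = shapely.covers(mask.cp_polygon, pts)
    strio_union = mask.striosome_union
    in_strio = shapely.covers(strio_union, pts) if not strio_union.is_empty else np.zeros(len(out), bool)
    label = np.where(~in_cp, COMPARTMENT_OUTSIDE,
                     np.where(in_strio, COMPARTMENT_STRIOSOME, COMPARTMENT_MATRIX))
    out["compartment"] = label
    return out


def compartment_density(
    labeled_cells: pd.DataFrame,
    mask: CompartmentMask,
    partition: QuadrantPartition,
) -> pd.DataFrame:
    """Per-quadrant, per-compartment densities (cells/mm^2).

    Areas are polygon intersections of the compartment geometry with each quadrant;
    counts come from the divider-side point assignment, so striosome + matrix counts
    per quadrant conserve the in-CP total. A zero intersection area carrying a
    nonzero count raises (geometry inconsistency).
    """
    cells = labeled_cells[labeled_cells["compartment"] != COMPARTMENT_OUTSIDE]
    quad_of = partition.assign(cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float)) \
        if len(cells) else np.array([], dtype=object)
    strio_union = mask.striosome_union
    rows = []
    for q in QUADRANTS:
        qpoly = partition.polygons[q]
        strio_area = strio_union.intersection(qpoly).area / 1e6 if not strio_union.is_empty else 0.0
        matrix_area = qpoly.area / 1e6 - strio_area
        for comp, area in ((COMPARTMENT_STRIOSOME, strio_area), (COMPARTMENT_MATRIX, matrix_area)):
            n = int(((quad_of == q) & (cells["compartment"] == comp).to_numpy()).sum()) if len(cells) else 0
            if area <= 0:
                if n > 0:
                    raise ValueError(
                        f"{comp} within {q} has zero area but {n} cells: geometry inconsistency"
                    )
                dens = np.nan
            else:
                dens = n / area
            rows.append({"quadrant": q, "compartment": comp, "n_cells": n,
                         "area_mm2": area, "density": dens})
    return pd.DataFrame(rows)


def normalize_to_control(density: float, control_mean: float) -> float:
    """Fold-change of a density over the matching control-group mean
    (same compartment, same quadrant)."""
    if not control_mean > 0:
        raise ValueError("control mean must be positive")
    return density / control_mean
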