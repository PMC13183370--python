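"""ROI quantification: point-in-polygon, density, matching, bregma splitting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon, box

from vocalmap import roi as roimod
from vocalmap.roi import (
    CHANNEL_CFOS,
    CHANNEL_TDTOMATO,
    RoiAnnotation,
    aggregate_mouse,
    assign_cells,
    density,
    detect_cells_simple,
    double_label_percentages,
    match_double_labeled,
    split_by_bregma,
)


def _cells(xy, channel=CHANNEL_TDTOMATO):
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return pd.DataFrame(
        {"x_um": xy[:, 0], "y_um": xy[:, 1], "channel": channel,
         "intensity": 30.0, "area_um2": 80.0}
    )


def _ray_cast(poly_xy, p):
    """Classic even-odd ray casting oracle (strict interior only)."""
    x, y = p
    inside = False
    n = len(poly_xy)
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


class TestAssignCells:
    POLY = [(0, 0), (800, 100), (1000, 900), (400, 1100), (-100, 600)]

    def test_matches_ray_casting_oracle_on_random_points(self):
        rng = np.random.default_rng(17)
        roi = RoiAnnotation("R", "left", 0.0, Polygon(self.POLY))
        pts = rng.uniform(-300, 1300, size=(200, 2))
        # keep points clearly off the boundary so both methods agree exactly
        pts = pts[[Point(p).distance(Polygon(self.POLY).boundary) > 1e-6 for p in pts]]
        got = assign_cells(_cells(pts), roi)
        expected = [p for p in pts if _ray_cast(self.POLY, p)]
        assert len(got) == len(expected)
        assert np.allclose(got[["x_um", "y_um"]].to_numpy(), np.asarray(expected))

    def test_vertex_and_edge_points_count_as_inside(self):
        roi = RoiAnnotation("R", "left", 0.0, box(0, 0, 100, 100))
        got = assign_cells(_cells([(0, 0), (50, 0), (100, 100), (50, 50), (200, 50)]), roi)
        assert len(got) == 4

    def test_all_outside_gives_empty(self):
        roi = RoiAnnotation("R", "left", 0.0, box(0, 0, 10, 10))
        assert len(assign_cells(_cells([(50, 50), (60, 60)]), roi)) == 0


class TestDensity:
    def test_30_cells_in_1p5_mm2_is_20(self):
        side = np.sqrt(1.5) * 1000
        roi = RoiAnnotation("R", "left", 0.0, box(0, 0, side, side))
        rng = np.random.default_rng(0)
        rec = density(_cells(rng.uniform(1, side - 1, (30, 2))), roi)
        assert rec["density"] == pytest.approx(20.0)
        assert rec["n_cells"] == 30

    def test_empty_is_zero(self):
        roi = RoiAnnotation("R", "left", 0.0, box(0, 0, 1000, 1000))
        assert density(_cells(np.empty((0, 2))), roi)["density"] == 0.0

    def test_doubling_cells_doubles_density(self):
        roi = RoiAnnotation("R", "left", 0.0, box(0, 0, 1000, 1000))
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1000, (40, 2))
        d1 = density(_cells(pts), roi)["density"]
        d2 = density(_cells(np.vstack([pts, pts + 0.5])), roi)["density"]
        assert d2 == pytest.approx(2 * d1)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            RoiAnnotation("R", "left", 0.0, Polygon([(0, 0), (1, 1), (2, 2)]))


def _optimal_match_count(a, b, tol):
    """Exhaustive maximum one-to-one matching oracle over all assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        return 0
    d = np.sqrt(((a[:, None] - b[None]) ** 2).sum(-1))
    small, big, dd = (a, b, d) if len(a) <= len(b) else (b, a, d.T)
    best = 0
    for perm in itertools.permutations(range(len(big)), len(small)):
        best = max(best, sum(dd[i, j] <= tol for i, j in enumerate(perm)))
    return best


class TestMatching:
    def test_identical_lists_all_match_at_zero(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 500, (12, 2))
        pairs = match_double_labeled(_cells(pts), _cells(pts, CHANNEL_CFOS), tol_um=8)
        assert len(pairs) == 12
        assert all(d == 0 for _, _, d in pairs)

    def test_everything_beyond_tolerance_matches_nothing(self):
        a = _cells([(0, 0), (100, 100)])
        b = _cells([(50, 50), (200, 200)], CHANNEL_CFOS)
        assert match_double_labeled(a, b, tol_um=8) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_exhaustive_assignment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(1, 9, 2)
        a = rng.uniform(0, 40, (na, 2))
        b = rng.uniform(0, 40, (nb, 2))
        pairs = match_double_labeled(_cells(a), _cells(b, CHANNEL_CFOS), tol_um=8)
        assert len(pairs) == _optimal_match_count(a, b, 8)

    def test_symmetry_of_argument_order(self):
        rng = np.random.default_rng(77)
        a = rng.uniform(0, 60, (10, 2))
        b = rng.uniform(0, 60, (11, 2))
        ab = {(i, j) for i, j, _ in match_double_labeled(_cells(a), _cells(b), 8)}
        ba = {(j, i) for i, j, _ in match_double_labeled(_cells(b), _cells(a), 8)}
        assert ab == ba

    def test_greedy_trap_configuration_still_optimal(self):
        # nearest-first greedy would match only one pair here
        a = [(0.0, 0.0), (10.0, 0.0)]
        b = [(5.0, 0.0), (17.0, 0.0)]
        pairs = match_double_labeled(_cells(a), _cells(b, CHANNEL_CFOS), tol_um=8)
        assert len(pairs) == 2


class TestPercentages:
    def test_quarter(self):
        out = double_label_percentages(5, 20, 25)
        assert out["pct_double_of_cfos"] == 25.0
        assert out["pct_double_of_tdtomato"] == 20.0
        assert not out["undefined_percentage"]

    def test_zero_double(self):
        assert double_label_percentages(0, 10, 10)["pct_double_of_cfos"] == 0.0

    def test_zero_denominator_flagged(self):
        out = double_label_percentages(0, 0, 5)
        assert np.isnan(out["pct_double_of_cfos"])
        assert out["undefined_percentage"]

    def test_reactivation_probability_recovered_from_generator(self):
        """Fixtures built with reactivation_prob=0.4 should average ~40% double of
        tdTomato across seeds."""
        from vocalmap import synthetic as syn
        from vocalmap.roi import quantify_section

        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            poly = box(0, 0, 2000, 2000)
            cells = syn.place_cells(poly, 30.0, rng, reactivation_prob=0.4)
            roi = RoiAnnotation("R", "left", 0.0, poly)
            rec = quantify_section(cells, [roi])
            if not rec["undefined_percentage"]:
                vals.append(rec["pct_double_of_tdtomato"])
        assert abs(np.mean(vals) - 40.0) < 5.0


class TestBregmaSplit:
    TABLE = pd.DataFrame(
        {
            "region": ["CPu", "CPu", "CPu", "CPu", "PAG", "PAG", "LS"],
            "bregma_mm": [0.80, 0.62, -0.50, -1.50, -4.5, -4.2, 0.3],
            "mouse_id": "m00",
        }
    )

    def test_boundaries_go_rostral(self):
        out = split_by_bregma(self.TABLE)
        sub = dict(zip(out["bregma_mm"], out["subregion"]))
        assert sub[0.80] == "rCPu"
        assert sub[0.62] == "rCPu"  # boundary belongs to the rostral subregion
        assert sub[-0.50] == "cCPu"
        assert sub[-1.50] == "tCPu"
        assert sub[-4.5] == "cPAG"
        assert sub[-4.2] == "rPAG"
        assert sub[0.3] == "LS"  # unruled regions keep their name

    def test_sections_outside_all_intervals_are_dropped(self):
        table = pd.DataFrame({"region": ["CPu"], "bregma_mm": [9.0], "mouse_id": "m"})
        rules = {"CPu": [("rCPu", 0.62, 1.6)]}
        assert len(split_by_bregma(table, rules)) == 0


class TestAggregation:
    def test_mean_of_sections(self):
        recs = pd.DataFrame(
            {
                "mouse_id": "m00",
                "region": "R",
                "subregion": "R",
                "area_mm2": 1.0,
                "n_td": [10, 20, 30],
                "n_fos": 0,
                "n_double": 0,
                "density_td": [10.0, 20.0, 30.0],
                "density_fos": 0.0,
                "density_double": 0.0,
                "pct_double_of_cfos": np.nan,
                "pct_double_of_tdtomato": np.nan,
            }
        )
        out = aggregate_mouse(recs)
        assert out.loc[0, "density_td"] == pytest.approx(20.0)
        assert out.loc[0, "n_sections"] == 3
        assert out.loc[0, "n_td"] == 60

    def test_single_section_passthrough(self):
        recs = pd.DataFrame(
            {
                "mouse_id": "m00", "region": "R", "subregion": "R", "area_mm2": 2.0,
                "n_td": [7], "n_fos": 3, "n_double": 1,
                "density_td": [3.5], "density_fos": 1.5, "density_double": 0.5,
                "pct_double_of_cfos": 33.3, "pct_double_of_tdtomato": 14.3,
            }
        )
        assert aggregate_mouse(recs).loc[0, "density_td"] == 3.5

    def test_hemisphere_pooling_conserves_counts(self, two_region_cohort):
        from vocalmap.roi import quantify_section

        sec = two_region_cohort.sections[0]
        rec = quantify_section(sec.cells, list(sec.rois))
        per_hemi = sum(
            len(assign_cells(sec.cells[sec.cells["channel"] == CHANNEL_TDTOMATO], r))
            for r in sec.rois
        )
        assert rec["n_td"] == per_hemi


class TestBlobDetector:
    def _render(self, centers, shape=(200, 200), amp=80.0, sigma=4.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        img = np.zeros(shape)
        for cx, cy in centers:
            img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        return img

    def test_blank_image_empty(self):
        out = detect_cells_simple(np.zeros((64, 64)), um_per_px=1.0)
        assert len(out) == 0

    def test_five_separated_blobs_found_at_centroids(self):
        centers = [(30, 30), (90, 40), (150, 60), (60, 140), (140, 160)]
        img = self._render(centers)
        out = detect_cells_simple(img, um_per_px=1.0, threshold=20.0)
        assert len(out) == 5
        got = out[["x_um", "y_um"]].to_numpy()
        for cx, cy in centers:
            assert np.min(np.hypot(got[:, 0] - cx, got[:, 1] - cy)) <= 1.0

    def test_dim_blob_below_threshold_excluded(self):
        img = self._render([(50, 50)], amp=8.0, sigma=4.0)
        out = detect_cells_simple(img, um_per_px=1.0, threshold=10.0)
        assert len(out) == 0

    def test_missing_pixel_scale_rejected(self):
        with pytest.raises(ValueError):
            detect_cells_simple(np.zeros((10, 10)), um_per_px=0)
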