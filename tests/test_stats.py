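"""Normality routing, group comparisons, ANOVA, outlier fences, z-score modes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from vocalmap import stats as vs
from vocalmap.stats import (
    MODE_ACROSS_MOUSE,
    MODE_WITHIN_MOUSE,
    ZScoreMatrix,
    compare_groups,
    flag_outliers,
    order_by_usv,
    route_test,
    two_way_anova_tukey,
    zscore,
)


class TestRouting:
    def test_gaussian_samples_route_to_independent_t(self):
        rng = np.random.default_rng(42)
        g1, g2 = rng.normal(10, 1, 10), rng.normal(10, 1, 10)
        # Shapiro oracle on this fixed draw: both p >> 0.05 (0.87, 0.22)
        assert route_test([g1, g2]) == vs.TEST_INDEPENDENT_T

    def test_heavy_skew_routes_to_mann_whitney(self):
        rng = np.random.default_rng(3)
        skewed = rng.lognormal(0, 2.0, 20)  # Shapiro oracle p ~ 4e-9
        normal = np.random.default_rng(42).normal(0, 1, 20)
        assert route_test([skewed, normal]) == vs.TEST_MANN_WHITNEY

    def test_paired_normal_differences_route_to_paired_t(self):
        rng = np.random.default_rng(42)
        base = rng.normal(10, 1, 10)
        assert route_test([base + rng.normal(0.5, 0.2, 10), base], paired=True) == vs.TEST_PAIRED_T

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            route_test([np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0])])


class TestCompare:
    def test_identical_groups_give_p_one(self):
        x = np.array([5.0, 5.0, 5.0, 5.0])
        res = compare_groups(x, x.copy())
        assert res.p_value == 1.0
        assert res.effect_direction == 0

    def test_large_shift_is_highly_significant(self):
        rng = np.random.default_rng(8)
        ctl = rng.normal(10, 1, 9)
        res = compare_groups(ctl + 10, ctl)
        assert res.test_name == vs.TEST_INDEPENDENT_T
        assert res.p_value < 0.001
        assert res.effect_direction == 1

    def test_parametric_summary_is_mean_sem(self):
        rng = np.random.default_rng(9)
        res = compare_groups(rng.normal(5, 1, 8), rng.normal(5, 1, 8))
        assert "mean ± SEM" in res.group1_summary

    def test_exposure_effect_power_on_fixtures(self):
        """A 1.6x exposure effect at n=9/7 with ~10% biological noise should be
        detected at alpha=0.05 in at least 80% of seeds."""
        from vocalmap import synthetic as syn

        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            base = 20.0 * np.exp(rng.normal(0, 0.10, 16))
            mult = np.r_[1.6 * np.ones(9), np.ones(7)]
            counts = rng.poisson(base * mult * 3.0)  # ~3 mm^2 sampled per mouse
            dens = counts / 3.0
            res = compare_groups(dens[:9], dens[9:])
            hits += res.p_value < 0.05
        assert hits / n_seeds >= 0.8


class TestAnova:
    def _toy(self):
        # balanced 2x2 with additive effects, n=2 per cell
        rows = []
        for a, da in (("a1", 0.0), ("a2", 3.0)):
            for b, db in (("b1", 0.0), ("b2", 1.0)):
                for r in (0.0, 0.5):
                    rows.append({"y": 10 + da + db + r, "A": a, "B": b})
        return pd.DataFrame(rows)

    def test_f_matches_hand_sums_of_squares(self):
        """Brute-force sums-of-squares oracle on the balanced 2x2 table."""
        df = self._toy()
        anova, _ = two_way_anova_tukey(df, "y", "A", "B")
        y = df["y"].to_numpy()
        grand = y.mean()
        ss_a = sum(len(g) * (g.mean() - grand) ** 2 for _, g in df.groupby("A")["y"])
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for _, g in df.groupby("B")["y"])
        cell_means = df.groupby(["A", "B"])["y"].mean()
        ss_cells = sum(2 * (m - grand) ** 2 for m in cell_means)
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(((g - g.mean()) ** 2).sum() for _, g in df.groupby(["A", "B"])["y"])
        ms_err = ss_err / 4  # df = N - cells = 8 - 4
        assert anova.loc["C(A)", "F"] == pytest.approx(ss_a / 1 / ms_err, abs=1e-10)
        assert anova.loc["C(B)", "F"] == pytest.approx(ss_b / 1 / ms_err, abs=1e-10)
        assert anova.loc["C(A):C(B)", "F"] == pytest.approx(ss_ab / 1 / ms_err, abs=1e-8)

    def test_all_equal_observations_give_f_zero_p_one(self):
        df = self._toy()
        df["y"] = 7.0
        anova, _ = two_way_anova_tukey(df, "y", "A", "B")
        assert (anova["F"].iloc[:3] == 0).all()
        assert (anova["PR(>F)"].iloc[:3] == 1).all()

    def test_additive_effects_detected_without_interaction(self):
        hits_a = hits_b = spurious = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows = []
            for a, da in (("a1", 0.0), ("a2", 2.0)):
                for b, db in (("b1", 0.0), ("b2", 2.0)):
                    for _ in range(8):
                        rows.append({"y": 10 + da + db + rng.normal(0, 1), "A": a, "B": b})
            anova, _ = two_way_anova_tukey(pd.DataFrame(rows), "y", "A", "B")
            hits_a += anova.loc["C(A)", "PR(>F)"] < 0.01
            hits_b += anova.loc["C(B)", "PR(>F)"] < 0.01
            spurious += anova.loc["C(A):C(B)", "PR(>F)"] < 0.05
        assert hits_a / n_seeds >= 0.9 and hits_b / n_seeds >= 0.9
        assert spurious / n_seeds <= 0.2

    def test_empty_design_cell_named_in_error(self):
        df = self._toy()
        df = df[~((df["A"] == "a2") & (df["B"] == "b2"))]
        with pytest.raises(ValueError, match="a2.*b2"):
            two_way_anova_tukey(df, "y", "A", "B")


class TestOutliers:
    def test_obvious_outlier_flagged(self):
        assert flag_outliers([1.0, 2.0, 3.0, 100.0]).tolist() == [False, False, False, True]

    def test_all_equal_none_flagged(self):
        assert not flag_outliers([5.0] * 6).any()

    def test_matches_brute_force_fences(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            x = rng.normal(0, 1, 15) + rng.choice([0, 8], 15, p=[0.9, 0.1])
            q1, q3 = np.percentile(x, [25, 75])
            iqr = q3 - q1
            expected = (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
            assert (flag_outliers(x) == expected).all()

    def test_refagging_retained_set_is_stable_on_fence_stable_input(self):
        x = np.r_[np.random.default_rng(0).normal(0, 1, 20), 25.0]
        mask = flag_outliers(x)
        retained = x[~mask]
        assert not flag_outliers(retained).any()


def _matrix():
    return pd.DataFrame(
        {"R1": [2.0, 4.0, 6.0], "R2": [10.0, 10.0, 10.0], "R3": [1.0, 5.0, 9.0]},
        index=["m0", "m1", "m2"],
    )


class TestZScore:
    def test_simple_population(self):
        z = zscore(_matrix(), MODE_ACROSS_MOUSE, exclude_outliers=False)
        assert z.values["R1"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_population_flagged_zero(self):
        z = zscore(_matrix(), MODE_ACROSS_MOUSE, exclude_outliers=False)
        assert (z.values["R2"] == 0).all()
        assert z.degenerate_mask["R2"].all()

    def test_retained_entries_have_mean0_sd1_in_both_modes(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.lognormal(1, 0.5, (8, 6)),
                         index=[f"m{i}" for i in range(8)],
                         columns=[f"R{i}" for i in range(6)])
        for mode in (MODE_ACROSS_MOUSE, MODE_WITHIN_MOUSE):
            z = zscore(m, mode)
            vals = z.values.to_numpy()
            axis = 0 if mode == MODE_ACROSS_MOUSE else 1
            mean = np.nanmean(vals, axis=axis)
            sd = np.nanstd(vals, axis=axis, ddof=1)
            assert np.allclose(mean, 0, atol=1e-9)
            assert np.allclose(sd, 1, atol=1e-9)

    def test_outlier_rendered_missing_and_excluded_from_mu_sigma(self):
        m = _matrix()
        m.loc["m3"] = [100.0, 10.0, 5.0]
        m.loc["m4"] = [3.0, 10.0, 5.0]
        z = zscore(m, MODE_ACROSS_MOUSE, exclude_outliers=True)
        assert z.outlier_mask.loc["m3", "R1"]
        assert np.isnan(z.values.loc["m3", "R1"])
        retained = m["R1"][~z.outlier_mask["R1"]]
        expected = (retained - retained.mean()) / retained.std(ddof=1)
        pd.testing.assert_series_equal(z.values["R1"].dropna(), expected, check_names=False)

    @given(shift=st_h.floats(-50, 50), scale=st_h.floats(0.1, 20))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, shift, scale):
        m = _matrix()[["R1", "R3"]]
        z0 = zscore(m, MODE_ACROSS_MOUSE, exclude_outliers=False)
        z1 = zscore(m * scale + shift, MODE_ACROSS_MOUSE, exclude_outliers=False)
        assert np.allclose(z0.values, z1.values, atol=1e-7)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            zscore(_matrix()[["R1"]], MODE_WITHIN_MOUSE)


class TestOrdering:
    def _zm(self, mice):
        vals = pd.DataFrame(np.arange(len(mice) * 2, dtype=float).reshape(len(mice), 2),
                            index=mice, columns=["R1", "R2"])
        f = pd.DataFrame(False, index=mice, columns=["R1", "R2"])
        return ZScoreMatrix(vals, MODE_ACROSS_MOUSE, f, f.copy())

    def test_descending_by_count_controls_last(self):
        mice = ["e0", "e1", "e2", "c0", "c1"]
        usv = pd.Series([5, 50, 20, 0, 0], index=mice)
        groups = pd.Series(["female-exposure"] * 3 + ["no-exposure"] * 2, index=mice)
        out = order_by_usv(self._zm(mice), usv, groups)
        assert list(out.values.index) == ["e1", "e2", "e0", "c0", "c1"]

    def test_ties_preserve_input_order(self):
        mice = ["e0", "e1", "e2"]
        usv = pd.Series([7, 7, 7], index=mice)
        groups = pd.Series(["female-exposure"] * 3, index=mice)
        out = order_by_usv(self._zm(mice), usv, groups)
        assert list(out.values.index) == mice

    def test_missing_count_rejected(self):
        mice = ["e0", "e1", "e2"]
        usv = pd.Series([7.0, np.nan, 3.0], index=mice)
        groups = pd.Series(["female-exposure"] * 3, index=mice)
        with pytest.raises(ValueError, match="missing USV count"):
            order_by_usv(self._zm(mice), usv, groups)

    def test_coupled_region_shows_usv_gradient(self):
        """In a usv_coupling=0.9 region at n=9 exposed, the USV-ordered heatmap rows
        show a strong rank gradient in z (the red-to-blue banding) in most seeds."""
        from scipy.stats import spearmanr

        from vocalmap import pipeline, synthetic as syn

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = syn.CohortConfig(
                n_exposed=9, n_control=3,
                regions=(syn.RegionSpec("COUP", (0.0, 1.2), 25.0, 1.6, 0.9),
                         syn.RegionSpec("FLAT", (0.0, 1.2), 25.0, 1.0, 0.0)),
                master_seed=300 + seed,
            )
            exp = syn.generate_cohort(cfg)
            heat = pipeline.zscore_heatmaps(
                pipeline.per_mouse_table(pipeline.quantify_sections(exp.sections)),
                exp.mice,
            )[MODE_ACROSS_MOUSE]
            exposed = exp.mice.query("group == 'female-exposure'")["mouse_id"]
            col = heat.values.loc[heat.values.index.isin(exposed), "COUP"].dropna()
            rho, _ = spearmanr(np.arange(len(col)), col.to_numpy())
            hits += rho < -0.6  # descending USV order -> descending z
        assert hits / n_seeds >= 0.8
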