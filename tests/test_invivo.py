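import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import nanosynergy as ns
from nanosynergy.invivo import (
    GrowthSummary,
    TumorMeasurements,
    achieved_power,
    compare_groups,
    growth_summary,
    power_two_sample,
    tumor_volume,
)


class TestTumorVolume:
    def test_equal_diameters_give_sphere_volume(self):
        d = 7.3
        assert tumor_volume(d, d) == pytest.approx(math.pi * d**3 / 6)

    def test_zero_diameter_gives_zero(self):
        assert tumor_volume(0.0, 5.0) == 0.0

    def test_printed_formula_evaluation(self):
        # l = sqrt(24), V = (pi/6) * 24^(3/2)
        assert tumor_volume(6.0, 4.0) == pytest.approx((math.pi / 6) * 24**1.5)
        assert tumor_volume(6.0, 4.0) == pytest.approx(61.56, abs=0.01)

    def test_symmetric_and_monotone(self):
        assert tumor_volume(3.0, 8.0) == tumor_volume(8.0, 3.0)
        assert tumor_volume(3.1, 8.0) > tumor_volume(3.0, 8.0)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            tumor_volume(-1.0, 2.0)


def measurements(rows):
    return TumorMeasurements(
        records=pd.DataFrame(rows, columns=["mouse_id", "group", "day", "diameter_a", "diameter_b"])
    )


class TestGrowthSummary:
    def test_day0_change_is_zero_and_doubling_is_100(self):
        d0 = 6.0
        d2 = d0 * 2 ** (1 / 3)  # doubles the volume
        tm = measurements([("m1", "g", 0, d0, d0), ("m1", "g", 7, d2, d2)])
        gs = growth_summary(tm)
        by_day = gs.per_mouse.set_index("day")["pct_change"]
        assert by_day[0] == 0.0
        assert by_day[7] == pytest.approx(100.0)

    def test_control_normalized_mode_maps_control_final_mean_to_100(self):
        rows = []
        for mouse, grp, scale in [("c1", "ctl", 1.3), ("c2", "ctl", 1.5), ("t1", "tx", 1.1), ("t2", "tx", 1.05)]:
            rows.append((mouse, grp, 0, 5.0, 5.0))
            rows.append((mouse, grp, 15, 5.0 * scale, 5.0 * scale))
        gs = growth_summary(measurements(rows), control_group="ctl")
        norm = gs.control_normalized
        ctl_final = norm[(norm["group"] == "ctl") & (norm["day"] == 15)]
        assert ctl_final["mean_pct_of_control_final"].iloc[0] == pytest.approx(100.0)

    def test_mouse_without_day0_excluded_with_warning(self):
        tm = measurements([("m1", "g", 0, 5, 5), ("m1", "g", 3, 6, 6), ("m2", "g", 3, 6, 6)])
        with pytest.warns(UserWarning, match="m2"):
            gs = growth_summary(tm)
        assert gs.excluded_mice == ["m2"]
        assert set(gs.per_mouse["mouse_id"]) == {"m1"}

    def test_noise_free_exponential_data_reproduce_growth_rate(self):
        cfg = ns.TumorSimConfig(groups=[("g", 0.3, 0.12)], n_mice=3, diameter_noise_sd=0.0, seed=0)
        gs = growth_summary(ns.simulate_tumor_growth(cfg))
        one = gs.per_mouse[gs.per_mouse["mouse_id"] == gs.per_mouse["mouse_id"].iloc[0]]
        slope = stats.linregress(one["day"], np.log(one["volume"])).slope
        assert slope == pytest.approx(0.18, abs=1e-10)


def summary_from_values(cells):
    """GrowthSummary stub from {(group, day): [values]}."""
    rows = []
    for (g, d), vals in cells.items():
        for i, v in enumerate(vals):
            rows.append({"mouse_id": f"{g}{i}", "group": g, "day": d, "volume": 1.0, "pct_change": v})
    pm = pd.DataFrame(rows)
    pg = pm.groupby(["group", "day"])["pct_change"].agg(
        mean_pct_change="mean", sd_pct_change="std", n="count"
    ).reset_index()
    return GrowthSummary(per_mouse=pm, per_group=pg)


class TestGroupComparisons:
    def test_identical_groups_give_p_one(self):
        vals = [10.0, 12.0, 14.0, 16.0]
        gs = summary_from_values({("a", 5): vals, ("b", 5): list(vals)})
        rep = compare_groups(gs, kind="ttest", groups=["a", "b"], day=5)
        assert rep.p_value == pytest.approx(1.0)
        assert not rep.significant

    def test_planted_five_sd_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 10)
        b = rng.normal(5, 1, 10)
        gs = summary_from_values({("a", 5): list(a), ("b", 5): list(b)})
        rep = compare_groups(gs, kind="ttest", groups=["a", "b"], day=5)
        assert rep.p_value < 1e-3
        assert rep.significant

    def test_one_way_anova_across_three_groups(self):
        rng = np.random.default_rng(1)
        gs = summary_from_values({
            ("a", 5): list(rng.normal(0, 1, 6)),
            ("b", 5): list(rng.normal(0, 1, 6)),
            ("c", 5): list(rng.normal(8, 1, 6)),
        })
        rep = compare_groups(gs, kind="anova1", day=5)
        assert rep.significant

    def test_two_way_anova_matches_hand_computed_sums_of_squares(self):
        # balanced 2 groups x 2 days, 3 observations per cell
        cells = {
            ("a", 1): [10.0, 12.0, 11.0],
            ("a", 2): [20.0, 22.0, 21.0],
            ("b", 1): [13.0, 15.0, 14.0],
            ("b", 2): [31.0, 33.0, 35.0],
        }
        gs = summary_from_values(cells)
        rep = compare_groups(gs, kind="anova2")

        # oracle: classical balanced fixed-effects decomposition
        y = np.array([cells[(g, d)] for g in ("a", "b") for d in (1, 2)], float)  # 4 x 3
        grand = y.mean()
        g_means = y.reshape(2, 2, 3).mean(axis=(1, 2))
        d_means = y.reshape(2, 2, 3).mean(axis=(0, 2))
        cell_means = y.reshape(2, 2, 3).mean(axis=2)
        r = 3
        ss_g = 2 * r * np.sum((g_means - grand) ** 2)
        ss_e = np.sum((y.reshape(2, 2, 3) - cell_means[..., None]) ** 2)
        ms_g = ss_g / 1
        ms_e = ss_e / (12 - 4)
        f_g = ms_g / ms_e
        assert rep.statistic == pytest.approx(f_g, rel=1e-9)
        assert rep.p_value == pytest.approx(stats.f.sf(f_g, 1, 8), rel=1e-9)

        ss_gd = r * np.sum((cell_means - g_means[:, None] - d_means[None, :] + grand) ** 2)
        f_gd = (ss_gd / 1) / ms_e
        assert rep.details["interaction_p"] == pytest.approx(stats.f.sf(f_gd, 1, 8), rel=1e-9)


class TestPower:
    def quadrature_power(self, n, effect, alpha=0.05):
        """Oracle: integrate the noncentral-t density over the rejection region."""
        df = 2 * n - 2
        nc = effect * math.sqrt(n / 2)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        hi, _ = integrate.quad(lambda t: stats.nct.pdf(t, df, nc), tcrit, np.inf)
        lo, _ = integrate.quad(lambda t: stats.nct.pdf(t, df, nc), -np.inf, -tcrit)
        return hi + lo

    def test_standard_benchmark_effect_1_needs_17_per_group(self):
        assert power_two_sample(1.0, 0.05, 0.8) == 17

    def test_inverse_consistency_against_quadrature(self):
        for effect, power in [(0.5, 0.8), (1.0, 0.8), (1.0, 0.9), (2.0, 0.65)]:
            n = power_two_sample(effect, 0.05, power)
            assert self.quadrature_power(n, effect) >= power - 1e-9
            if n > 2:
                assert self.quadrature_power(n - 1, effect) < power

    def test_tiny_power_target_returns_minimum_n(self):
        assert power_two_sample(1.0, 0.05, 0.051) == 2

    def test_doubling_effect_never_increases_n(self):
        for effect in (0.3, 0.6, 1.2):
            assert power_two_sample(2 * effect) <= power_two_sample(effect)

    def test_achieved_power_monotone_in_n(self):
        assert achieved_power(20, 0.8) > achieved_power(10, 0.8)
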