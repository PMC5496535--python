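import math

import numpy as np
import pytest

from beachdiv.change import (
    ChangeConfig,
    ChangeResult,
    HistoricalPoint,
    adjusted_richness_at_area,
    classify_change,
    compare_periods,
    format_summary,
    historical_points_from_matrices,
    percent_change,
    summarize_changes,
)
from beachdiv.estimation import CurvePoint, build_curve

from conftest import make_units


def _point(s, lo, hi, mode="interpolated"):
    return CurvePoint(t=1, area_m2=1, S_t=s, var_S=1, ci_low=lo, ci_high=hi, mode=mode)


class TestPercentChange:
    def test_talitrid_style_decline(self):
        # four species down to one is a 75% loss
        assert percent_change(4, 1) == pytest.approx(-75.0)

    def test_no_change(self):
        assert percent_change(7.3, 7.3) == 0.0

    def test_gain(self):
        assert percent_change(10, 15) == pytest.approx(50.0)

    def test_zero_baseline_is_not_estimable(self):
        assert math.isnan(percent_change(0, 5))

    def test_scale_invariance(self):
        assert percent_change(8, 6) == pytest.approx(percent_change(80, 60))


class TestClassify:
    def test_historical_above_band_is_significant_decrease(self):
        assert classify_change(10, _point(8, 6.2, 9.1)) == ("decrease", True)

    def test_historical_below_band_is_significant_increase(self):
        assert classify_change(5, _point(8, 6.2, 9.1)) == ("increase", True)

    def test_inside_band_direction_from_adjusted(self):
        assert classify_change(7, _point(8, 6.2, 9.1)) == ("increase", False)
        assert classify_change(8.5, _point(8, 6.2, 9.1)) == ("decrease", False)

    def test_boundary_is_not_significant(self):
        direction, significant = classify_change(9.1, _point(8, 6.2, 9.1))
        assert not significant

    def test_agrees_with_percent_change_sign_when_significant(self):
        for s_hist in (3, 12):
            direction, significant = classify_change(s_hist, _point(8, 6.2, 9.1))
            if significant:
                pct = percent_change(s_hist, 8)
                assert (pct > 0) == (direction == "increase")

    def test_non_finite_ci_rejected(self):
        with pytest.raises(ValueError):
            classify_change(5, _point(8, math.nan, 9.1))


class TestAdjustedRichness:
    def test_reference_area_returns_observed(self, toy_matrix):
        curve = build_curve(toy_matrix)
        pt = adjusted_richness_at_area(curve, 1.0)  # A_total of the toy matrix
        assert pt.mode == "observed" and pt.S_t == pytest.approx(5.0)

    def test_half_area_is_rarefied(self, toy_matrix):
        pt = adjusted_richness_at_area(build_curve(toy_matrix), 0.5)
        assert pt.mode == "interpolated"

    def test_triple_area_is_extrapolated_and_bounded(self, toy_matrix):
        curve = build_curve(toy_matrix)
        pt = adjusted_richness_at_area(curve, 3.0)
        assert pt.mode == "extrapolated"
        assert pt.S_t <= curve.asymptote.S_hat

    def test_non_positive_area_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            adjusted_richness_at_area(build_curve(toy_matrix), 0.0)


class TestComparePeriods:
    def test_identical_periods_zero_change(self, toy_matrix, toy_traits):
        hist = historical_points_from_matrices(
            {"A": toy_matrix}, toy_traits, groups=("overall",)
        )
        res = compare_periods(
            hist, {"A": toy_matrix}, toy_traits, ChangeConfig(groups=("overall",))
        )
        assert len(res) == 1
        assert res[0].pct_change == pytest.approx(0.0)
        assert not res[0].significant

    def test_missing_recent_site_listed(self, toy_matrix, toy_traits):
        hist = [HistoricalPoint(site="B", group="overall", S_hist=5, A_hist=1.0)]
        with pytest.raises(KeyError, match="B"):
            compare_periods(hist, {"A": toy_matrix}, toy_traits)

    def test_group_lost_entirely_is_significant_decrease(self, toy_matrix, toy_traits):
        # recent period never detects the wrack species
        recent = toy_matrix.restrict_units([True] * 4)
        recent.detections = recent.detections.copy()
        recent.detections[2, :] = False  # sp2
        recent.detections[4, :] = False  # sp4
        hist = [HistoricalPoint(site="A", group="wrack", S_hist=2, A_hist=0.6)]
        res = compare_periods(hist, {"A": recent}, toy_traits,
                              ChangeConfig(groups=("wrack",)))[0]
        assert res.S_adj == 0.0
        assert res.direction == "decrease" and res.significant
        assert res.pct_change == pytest.approx(-100.0)

    def test_impact_category_is_attached(self, toy_matrix, toy_traits):
        hist = historical_points_from_matrices(
            {"A": toy_matrix}, toy_traits, groups=("overall",)
        )
        res = compare_periods(
            hist, {"A": toy_matrix}, toy_traits,
            ChangeConfig(groups=("overall",),
                         impact_categories={"A": "groomed_fill"}),
        )
        assert res[0].impact_category == "groomed_fill"


class TestHistoricalPoints:
    def test_overall_uses_total_area(self, toy_matrix, toy_traits):
        pts = historical_points_from_matrices(
            {"A": toy_matrix}, toy_traits, groups=("overall",)
        )
        assert pts[0].S_hist == 5 and pts[0].A_hist == pytest.approx(1.0)

    def test_wrack_uses_zone_area(self, toy_matrix, toy_traits):
        # wrack species sp2 (units 0,1) and sp4 (all units): zone = all units
        pts = historical_points_from_matrices(
            {"A": toy_matrix}, toy_traits, groups=("wrack",)
        )
        assert pts[0].S_hist == 2
        assert pts[0].A_hist == pytest.approx(1.0)

    def test_zone_smaller_than_total_when_wrack_confined(self, toy_traits):
        det = np.zeros((5, 4), dtype=bool)
        det[2, 0] = True  # wrack species only at the high-tide line
        det[0, 3] = True
        from beachdiv.incidence import IncidenceMatrix

        m = IncidenceMatrix([f"sp{i}" for i in range(5)], make_units(4), det)
        pts = historical_points_from_matrices({"A": m}, toy_traits, groups=("wrack",))
        assert pts[0].A_hist == pytest.approx(0.25)


class TestSummaries:
    def _result(self, site, group, pct, direction="increase", significant=False,
                category="none"):
        return ChangeResult(
            site=site, group=group, S_hist=10, A_hist=1.0, S_adj=10 * (1 + pct / 100),
            ci_low=0, ci_high=99, pct_change=pct, direction=direction,
            significant=significant, mode="rarefied", impact_category=category,
        )

    def test_four_beach_mean(self):
        res = [self._result(s, "overall", p, category="groomed_fill")
               for s, p in zip("abcd", (23, 50, 50, 57))]
        summary = summarize_changes(res)
        row = summary.by_category.iloc[0]
        assert row["mean_pct_change"] == pytest.approx(45.0)
        assert row["n"] == 4

    def test_three_beach_decline_mean(self):
        res = [self._result(s, "wrack", p, direction="decrease")
               for s, p in zip("abc", (-23, -50, -50))]
        summary = summarize_changes(res)
        assert summary.by_category.iloc[0]["mean_pct_change"] == pytest.approx(-41.0)

    def test_all_none_directions_counted(self):
        res = [self._result(s, "overall", 0.0, direction="none") for s in "ab"]
        row = summarize_changes(res).by_category.iloc[0]
        assert row["n_none"] == 2 and row["n_increase"] == row["n_decrease"] == 0

    def test_wrack_exceeding_overall_is_counted(self):
        res = [
            self._result("a", "overall", 10),
            self._result("a", "wrack", -40),
            self._result("b", "overall", 30),
            self._result("b", "wrack", 5),
        ]
        summary = summarize_changes(res)
        assert summary.n_wrack_exceeds_overall == 1
        assert summary.frac_wrack_exceeds_overall == pytest.approx(0.5)

    def test_format_rounds_to_whole_percent(self):
        res = [self._result("a", "overall", 45.4)]
        assert "+45%" in format_summary(summarize_changes(res))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_changes([])
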