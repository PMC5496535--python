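from itertools import combinations

import numpy as np
import pytest
from sklearn.base import clone

from beachdiv.estimation import (
    RarefactionExtrapolator,
    bootstrap_ci,
    build_curve,
    chao2_asymptotic,
    effort_grid,
    extrapolated_richness,
    rarefied_richness,
    richness_at_effort,
    unconditional_variance,
)
from beachdiv.incidence import IncidenceMatrix, IncidenceSummary, summarize_incidence

from conftest import make_units, random_matrix


def brute_subset_mean(det, t):
    """Mean richness over all C(R, t) unit subsets — independent oracle."""
    R = det.shape[1]
    vals = [
        det[:, list(sub)].any(axis=1).sum() for sub in combinations(range(R), t)
    ]
    return float(np.mean(vals))


class TestChao2:
    def test_no_uniques_no_undetected(self):
        s = IncidenceSummary(
            R=8, S_obs=10, Y=np.array([2] * 5 + [3] * 5),
            Q=np.array([0, 5, 5, 0, 0, 0, 0, 0]), A_total=8.0, a_bar=1.0,
        )
        est = chao2_asymptotic(s)
        assert est.S_hat == 10 and est.Q0_hat == 0

    def test_standard_form(self, toy_summary):
        est = chao2_asymptotic(toy_summary)
        assert est.Q0_hat == pytest.approx(1.5)
        assert est.S_hat == pytest.approx(6.5)
        assert est.form_used == "standard"

    def test_bias_corrected_single_unique(self):
        s = IncidenceSummary(
            R=5, S_obs=3, Y=np.array([1, 3, 3]),
            Q=np.array([1, 0, 2, 0, 0]), A_total=5.0, a_bar=1.0,
        )
        est = chao2_asymptotic(s)
        assert est.Q0_hat == 0 and est.form_used == "bias_corrected_Q2_zero"


class TestRarefaction:
    def test_full_effort_returns_observed(self, toy_summary):
        assert rarefied_richness(toy_summary, 4) == pytest.approx(5.0)

    def test_single_unit_mean(self, toy_summary):
        # S(1) is the average per-unit richness, sum(Y)/R
        assert rarefied_richness(toy_summary, 1) == pytest.approx(11 / 4)

    def test_two_unit_value(self, toy_summary):
        assert rarefied_richness(toy_summary, 2) == pytest.approx(5 - 7 / 6)

    def test_matches_exhaustive_subsets(self, toy_matrix):
        s = summarize_incidence(toy_matrix)
        for t in range(1, 5):
            assert rarefied_richness(s, t) == pytest.approx(
                brute_subset_mean(toy_matrix.detections, t), abs=1e-12
            )

    @pytest.mark.parametrize("t", [-0.5, 4.5])
    def test_out_of_range_rejected(self, toy_summary, t):
        with pytest.raises(ValueError):
            rarefied_richness(toy_summary, t)

    def test_non_integer_effort_is_monotone_between_integers(self, toy_summary):
        vals = [rarefied_richness(toy_summary, t) for t in np.linspace(0, 4, 33)]
        assert np.all(np.diff(vals) >= -1e-12)


class TestExtrapolation:
    def test_continuity_at_reference(self, toy_summary):
        assert extrapolated_richness(toy_summary, 0) == pytest.approx(5.0)

    def test_hand_value(self, toy_summary):
        assert extrapolated_richness(toy_summary, 4) == pytest.approx(
            5 + 1.5 * (1 - 0.75**4)
        )

    def test_approaches_asymptote(self, toy_summary):
        assert extrapolated_richness(toy_summary, 1e6) == pytest.approx(6.5, abs=1e-6)

    def test_no_uniques_means_no_gain(self):
        s = IncidenceSummary(
            R=4, S_obs=3, Y=np.array([2, 2, 3]),
            Q=np.array([0, 2, 1, 0]), A_total=4.0, a_bar=1.0,
        )
        assert extrapolated_richness(s, 50) == 3.0

    def test_negative_effort_rejected(self, toy_summary):
        with pytest.raises(ValueError):
            extrapolated_richness(toy_summary, -1)


class TestUnconditionalVariance:
    def test_zero_at_zero_effort(self, toy_summary):
        assert unconditional_variance(toy_summary, 0) == pytest.approx(0.0)

    def test_hand_value(self, toy_summary):
        expected = (2 * 0.25 + (5 / 6) ** 2 + 2) - (23 / 6) ** 2 / 6.5
        assert unconditional_variance(toy_summary, 2) == pytest.approx(expected)
        assert unconditional_variance(toy_summary, 2) == pytest.approx(0.9338, abs=5e-5)

    def test_all_species_everywhere_stays_nonnegative(self):
        s = IncidenceSummary(
            R=4, S_obs=3, Y=np.array([4, 4, 4]),
            Q=np.array([0, 0, 0, 3]), A_total=4.0, a_bar=1.0,
        )
        for t in (1, 2, 3):
            assert unconditional_variance(s, t) >= 0.0

    def test_positive_at_full_effort_when_uniques_remain(self, toy_summary):
        # "unconditional": the band does not collapse at t = R
        assert unconditional_variance(toy_summary, 4) > 0


class TestBootstrap:
    def test_deterministic_under_seed(self, toy_summary):
        a = bootstrap_ci(toy_summary, 6.0, B=100, seed=7)
        b = bootstrap_ci(toy_summary, 6.0, B=100, seed=7)
        assert a == b

    def test_complete_detection_gives_tiny_variance(self):
        s = IncidenceSummary(
            R=6, S_obs=4, Y=np.array([6] * 4),
            Q=np.array([0, 0, 0, 0, 0, 4]), A_total=6.0, a_bar=1.0,
        )
        var, lo, hi = bootstrap_ci(s, 3.0, B=100, seed=1)
        assert var < 0.05 and hi - lo < 1.0

    def test_agrees_with_analytic_variance_at_half_effort(self):
        rng = np.random.default_rng(42)
        det = rng.random((25, 12)) < rng.uniform(0.1, 0.7, size=(25, 1))
        m = IncidenceMatrix([f"s{i}" for i in range(25)], make_units(12), det)
        s = summarize_incidence(m)
        t = s.R / 2
        analytic = unconditional_variance(s, t)
        var, _, _ = bootstrap_ci(s, t, B=500, seed=3)
        # loose simulation cross-check: same order of magnitude
        assert var == pytest.approx(analytic, rel=3.0)

    def test_small_B_rejected(self, toy_summary):
        with pytest.raises(ValueError):
            bootstrap_ci(toy_summary, 2.0, B=10)


class TestDispatcher:
    @pytest.mark.parametrize(
        "t,mode", [(2.0, "interpolated"), (4.0, "observed"), (8.0, "extrapolated")]
    )
    def test_mode_dispatch(self, toy_summary, t, mode):
        pt = richness_at_effort(toy_summary, t)
        assert pt.mode == mode
        assert pt.area_m2 == pytest.approx(t * 0.25)
        assert pt.ci_low <= pt.S_t <= pt.ci_high

    def test_observed_point_equals_s_obs(self, toy_summary):
        assert richness_at_effort(toy_summary, 4.0).S_t == pytest.approx(5.0)


class TestCurve:
    def test_integer_grid_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            m = random_matrix(rng, max_R=8)
            curve = build_curve(m, grid=range(1, m.n_units + 1))
            for pt in curve.points:
                assert pt.S_t == pytest.approx(
                    brute_subset_mean(m.detections, int(pt.t)), abs=1e-10
                )

    def test_observed_point_on_curve(self, toy_matrix):
        curve = build_curve(toy_matrix)
        last = curve.points[-1]
        assert last.mode == "observed" and last.S_t == pytest.approx(5.0)

    def test_extrapolated_tail_below_asymptote(self, toy_matrix):
        curve = build_curve(toy_matrix, grid=effort_grid(4, t_max=12.0))
        tail = curve.points[-1]
        assert tail.mode == "extrapolated"
        assert 5.0 < tail.S_t <= curve.asymptote.S_hat

    def test_monotone_richness(self, toy_matrix):
        curve = build_curve(toy_matrix, grid=effort_grid(4, t_max=10.0))
        vals = [p.S_t for p in curve.points]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_long_extrapolation_is_warned(self, toy_matrix):
        curve = build_curve(toy_matrix, grid=[2.0, 20.0])
        assert curve.warnings and "asymptote" in curve.warnings[0]

    def test_degenerate_empty_assemblage(self):
        m = IncidenceMatrix(["a"], make_units(3), np.zeros((1, 3), bool))
        curve = build_curve(m, grid=[1.0, 2.0, 3.0])
        assert all(p.S_t == 0 and p.ci_low == p.ci_high == 0 for p in curve.points[:2])

    def test_narrower_band_at_lower_ci_level(self, toy_matrix):
        c95 = build_curve(toy_matrix, grid=[2.0], ci_level=0.95)
        c90 = build_curve(toy_matrix, grid=[2.0], ci_level=0.90)
        w95 = c95.points[0].ci_high - c95.points[0].ci_low
        w90 = c90.points[0].ci_high - c90.points[0].ci_low
        assert w90 < w95

    def test_empty_matrix_rejected(self):
        m = IncidenceMatrix(["a"], [], np.zeros((1, 0), bool))
        with pytest.raises(ValueError):
            build_curve(m)


class TestSklearnEstimator:
    def test_fit_predict_roundtrip(self, toy_matrix):
        X = toy_matrix.detections.T.astype(int)  # units x species
        est = RarefactionExtrapolator().fit(X, areas=0.25)
        assert est.s_obs_ == 5 and est.n_units_ == 4
        assert est.s_hat_ == pytest.approx(6.5)
        np.testing.assert_allclose(est.predict([1, 4]), [11 / 4, 5.0])

    def test_fit_accepts_incidence_matrix(self, toy_matrix):
        est = RarefactionExtrapolator().fit(toy_matrix)
        assert est.summary_.A_total == pytest.approx(1.0)

    def test_clone_and_params(self):
        est = RarefactionExtrapolator(ci_level=0.9, bootstrap_B=120)
        cl = clone(est)
        assert cl.get_params()["ci_level"] == 0.9
        assert cl.set_params(bootstrap_B=200).bootstrap_B == 200

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            RarefactionExtrapolator().fit(np.array([[0, 2], [1, 0]]))

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            RarefactionExtrapolator().predict([1.0])
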