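"""RCR survival model: evaluation, inversion, derived metrics, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from radioresponse import (
    RCRParameters,
    RCRSurvivalModel,
    compute_sf,
    dose_at_survival,
    evaluate_survival,
    limiting_slope_d0,
    mean_inactivation_dose_auc,
    mean_inactivation_dose_param,
    sf_at,
)

valid_params = st.builds(
    RCRParameters,
    a=st.floats(0.1, 2.0),
    b=st.floats(0.0, 3.0),
    c=st.floats(0.1, 3.0),
)


class TestEvaluateSurvival:
    @pytest.mark.parametrize(
        "params, dose, expected",
        [
            # pure-exponential reduction
            (RCRParameters(0.5, 0.0, 1.0), 2.0, math.exp(-1.0)),
            # both terms: e^-1 + 2 e^-2, independent arithmetic
            (RCRParameters(0.5, 1.0, 1.0), 2.0, math.exp(-1.0) + 2.0 * math.exp(-2.0)),
            # SF3.5 of the toy curve: e^-1.4 + 2.8 e^-4.2
            (RCRParameters(0.4, 0.8, 1.2), 3.5, math.exp(-1.4) + 2.8 * math.exp(-4.2)),
        ],
    )
    def test_closed_form_values(self, params, dose, expected):
        assert evaluate_survival(params, dose) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(params=valid_params)
    def test_survival_is_one_at_zero_dose(self, params):
        assert evaluate_survival(params, 0.0) == 1.0

    def test_negative_dose_rejected(self, toy_params):
        with pytest.raises(ValueError):
            evaluate_survival(toy_params, -1.0)

    def test_vectorized_evaluation(self, toy_params):
        d = np.array([0.0, 1.0, 2.0])
        out = evaluate_survival(toy_params, d)
        assert out.shape == (3,)
        assert out[0] == 1.0

    def test_sf35_below_sf2_over_parameter_sweep(self):
        """Survival at 3.5 Gy is below survival at 2 Gy for killing curves."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = RCRParameters(rng.uniform(0.1, 2), rng.uniform(0, 2), rng.uniform(0.5, 3))
            if evaluate_survival(p, 3.5) < 1:  # curves that actually kill
                assert sf_at(p, 3.5) < sf_at(p, 2.0)


class TestComputeSF:
    @pytest.mark.parametrize(
        "colonies, seeded, pe, expected",
        [(50, 100, 0.5, 1.0), (25, 1000, 0.1, 0.25), (0, 100, 0.5, 0.0)],
    )
    def test_surviving_fraction_arithmetic(self, colonies, seeded, pe, expected):
        assert compute_sf(colonies, seeded, pe) == pytest.approx(expected)

    def test_invalid_plating_efficiency_rejected(self):
        with pytest.raises(ValueError):
            compute_sf(10, 100, 0.0)
        with pytest.raises(ValueError):
            compute_sf(10, 100, 1.5)


class TestDoseAtSurvival:
    def test_closed_form_d10_of_exponential(self):
        params = RCRParameters(a=math.log(10) / 5, b=0.0, c=1.0)
        assert dose_at_survival(params, 0.1) == pytest.approx(5.0, abs=1e-9)

    def test_matches_dense_grid_scan(self, toy_params):
        """Brute-force oracle: first grid dose where S crosses the target."""
        grid = np.arange(0.0, 20.0, 1e-4)
        s = evaluate_survival(toy_params, grid)
        oracle = grid[np.argmax(s < 0.1)]
        assert dose_at_survival(toy_params, 0.1) == pytest.approx(oracle, abs=2e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(params=valid_params, s=st.floats(1e-6, 0.99))
    def test_round_trip_inverse_identity(self, params, s):
        d = dose_at_survival(params, s)
        assert evaluate_survival(params, d) == pytest.approx(s, abs=1e-9)

    def test_invalid_target_rejected(self, toy_params):
        for bad in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                dose_at_survival(toy_params, bad)


class TestMeanInactivationDose:
    def test_exponential_mean_is_reciprocal_rate(self):
        assert mean_inactivation_dose_param(RCRParameters(0.5, 0.0, 1.0)) == 2.0

    def test_closed_form_with_repair_term(self):
        assert mean_inactivation_dose_param(RCRParameters(0.5, 1.0, 1.0)) == pytest.approx(3.0)

    def test_matches_quadrature(self, toy_params):
        """Independent oracle: adaptive quadrature of S over [0, inf)."""
        val, _ = integrate.quad(lambda d: evaluate_survival(toy_params, d), 0, np.inf)
        assert mean_inactivation_dose_param(toy_params) == pytest.approx(val, abs=1e-6)

    def test_a_zero_rejected_as_divergent(self):
        with pytest.raises(ValueError):
            mean_inactivation_dose_param(RCRParameters(0.0, 1.0, 1.0))

    def test_auc_matches_exponential_closed_form(self):
        got = mean_inactivation_dose_auc(RCRParameters(0.5, 0.0, 1.0), d_max=200, step=0.01)
        assert got == pytest.approx(2.0, abs=1e-3)

    def test_auc_step_exceeding_dmax_rejected(self, toy_params):
        with pytest.raises(ValueError):
            mean_inactivation_dose_auc(toy_params, d_max=1.0, step=2.0)

    def test_coarse_grid_overestimates_fine_grid_for_convex_curves(self):
        """Trapezoid chords lie above a convex integrand, so coarse grids
        over-count.  S is convex everywhere only for b = 0 (the repaired
        term makes the curve concave near the origin), so the one-sided
        bound is asserted on pure-exponential curves.
        """
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = RCRParameters(rng.uniform(0.2, 1.5), 0.0, 1.0)
            coarse = mean_inactivation_dose_auc(p, d_max=60, step=1.0)
            fine = mean_inactivation_dose_auc(p, d_max=60, step=0.01)
            assert coarse >= fine - 1e-9


class TestLimitingSlope:
    def test_log_linear_curve_is_exact(self):
        assert limiting_slope_d0(RCRParameters(0.5, 0.0, 1.0), (1, 5)) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "params, expected",
        [
            (RCRParameters(2.0, 1.0, 0.5), 2.0),  # slow repaired mode dominates distally
            (RCRParameters(0.5, 1.0, 2.0), 2.0),  # direct-survival mode dominates
        ],
    )
    def test_distal_window_recovers_slowest_rate(self, params, expected):
        # the repaired term carries a b*d factor, so the local log-slope is
        # -c + 1/d: the 1/min(a, c) asymptote needs a genuinely distal window
        assert limiting_slope_d0(params, (500, 600)) == pytest.approx(expected, rel=0.01)

    def test_invalid_window_rejected(self, toy_params):
        with pytest.raises(ValueError):
            limiting_slope_d0(toy_params, (5, 5))


class TestParameterValidation:
    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            RCRParameters(-0.1, 0.0, 1.0)
        with pytest.raises(ValueError):
            RCRParameters(0.5, -1.0, 1.0)
        with pytest.raises(ValueError):
            RCRParameters(0.5, 0.0, 0.0)


class TestFit:
    def test_exact_recovery_on_noise_free_data(self, toy_params):
        doses = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0])
        sfs = evaluate_survival(toy_params, doses)
        res = RCRSurvivalModel(doses, sfs).fit()
        assert res.converged
        assert res.params.a == pytest.approx(toy_params.a, rel=1e-4)
        assert res.params.b == pytest.approx(toy_params.b, rel=1e-4)
        assert res.params.c == pytest.approx(toy_params.c, rel=1e-4)
        assert res.rss_log < 1e-10

    def test_pure_exponential_degenerate_case(self):
        doses = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0])
        res = RCRSurvivalModel(doses, np.exp(-0.5 * doses)).fit()
        assert res.params.a == pytest.approx(0.5, abs=1e-4)
        assert res.params.b == pytest.approx(0.0, abs=1e-4)

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError, match="4 distinct dose"):
            RCRSurvivalModel([0, 2, 4], [1, 0.5, 0.2])

    def test_nonpositive_sf_excluded_with_warning(self, toy_params):
        doses = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0])
        sfs = evaluate_survival(toy_params, doses)
        sfs[-1] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            res = RCRSurvivalModel(doses, sfs).fit()
        assert res.converged

    def test_linear_objective_available(self, toy_params):
        doses = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0])
        sfs = evaluate_survival(toy_params, doses)
        res = RCRSurvivalModel(doses, sfs).fit(objective="linear")
        assert res.params.a == pytest.approx(toy_params.a, rel=1e-3)

    def test_replicates_fitted_jointly(self, toy_params):
        doses = np.tile([0.0, 1.0, 2.0, 4.0, 6.0, 8.0], 3)
        sfs = evaluate_survival(toy_params, doses)
        res = RCRSurvivalModel(doses, sfs).fit()
        assert res.n_points == 18
        assert res.params.a == pytest.approx(toy_params.a, rel=1e-4)

    def test_summary_and_row_report_metrics(self, toy_params):
        doses = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0])
        res = RCRSurvivalModel(doses, evaluate_survival(toy_params, doses),
                               quality="gamma", cell_line="TOY").fit()
        row = res.to_row()
        assert row["cell_line"] == "TOY"
        assert row["sf2"] == pytest.approx(res.sf2)
        assert "SF2" in res.summary() and "D-bar" in res.summary()
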