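"""PV modelling: empirical step pressures, hysteresis, Venegas fitting,
runs test, EIT calibration, pooling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greylung.errors import CalibrationError, ValidationError
from greylung.pv import (PVSeries, VenegasModel, calibrate_eit,
                         detect_hysteresis, empirical_pressures, fit_venegas,
                         pool_series, predicted_pressures, runs_test,
                         venegas_curve)


def series(inf_p, inf_v, def_p, def_v, kind="delta_mgv", lamb="L1"):
    return PVSeries(lamb, kind, inf_p, inf_v, def_p, def_v)


class TestEmpiricalPressures:
    def test_opening_precedes_largest_increase(self):
        inf_p = [0, 5, 10, 15, 20, 25, 30, 35]
        inf_v = [40, 40, 42, 41, 44, 60, 80, 85]
        # oracle: exhaustive step scan; the largest increase is 60 -> 80,
        # whose immediately preceding point sits at 25 cm H2O
        steps = [(inf_v[i + 1] - inf_v[i], inf_p[i]) for i in range(7)]
        assert max(steps) == (20, 25)
        s = series(inf_p, inf_v, [30, 10], [85, 40])
        assert empirical_pressures(s).opening_pressure == 25

    def test_closing_precedes_largest_decrease(self):
        def_p = [30, 25, 20, 15, 10]
        def_v = [85, 84, 80, 55, 50]
        drops = [(def_v[i] - def_v[i + 1], def_p[i]) for i in range(4)]
        assert max(drops)[1] == 20  # oracle
        s = series([0, 35], [40, 85], def_p, def_v)
        assert empirical_pressures(s).closing_pressure == 20

    def test_ties_break_low_on_inflation_high_on_deflation(self):
        s = series([0, 5, 10, 15], [0, 10, 11, 21],  # steps 10, 1, 10
                   [15, 10, 5, 0], [21, 11, 10, 0])  # drops 10, 1, 10
        result = empirical_pressures(s)
        assert result.opening_pressure == 0
        assert result.closing_pressure == 15

    def test_flat_series_is_undetectable_not_an_error(self):
        s = series([0, 5, 10], [7, 7, 7], [10, 5], [7, 7])
        result = empirical_pressures(s)
        assert result.opening_pressure is None
        assert result.closing_pressure is None
        assert not result.detectable

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            empirical_pressures(series([0], [1], [10, 5], [2, 1]))


class TestDetectHysteresis:
    def test_uniform_offset_detected(self):
        p = [10, 15, 20, 25, 30]
        s = series(p, [1, 2, 3, 4, 5], p[::-1], [15, 14, 13, 12, 11])
        h = detect_hysteresis(s)
        assert h.present and h.mean_paired_difference == pytest.approx(10)

    def test_identical_limbs_absent_with_zero_area(self):
        p = [10, 15, 20, 25, 30]
        v = [1, 2, 3, 4, 5]
        h = detect_hysteresis(series(p, v, p[::-1], v[::-1]))
        assert not h.present
        assert h.loop_area == 0
        assert h.wilcoxon_p == 1.0

    def test_loop_area_matches_hand_trapezoid(self):
        # differences (2, 4, 6, 4, 2) over pressures 10..30 step 5:
        # 5*((2+4)/2 + (4+6)/2 + (6+4)/2 + (4+2)/2) = 80
        p = np.array([10, 15, 20, 25, 30.0])
        inf_v = np.zeros(5)
        def_v = np.array([2, 4, 6, 4, 2.0])[::-1]
        h = detect_hysteresis(series(p, inf_v, p[::-1], def_v))
        assert h.loop_area == pytest.approx(80.0)

    def test_no_matched_pressures_rejected(self):
        with pytest.raises(ValidationError):
            detect_hysteresis(series([0, 5], [1, 2], [12, 7], [3, 2]))


GRID = np.array([0, 5, 10, 15, 20, 25, 30, 35.0])


class TestVenegasFit:
    def test_noiseless_recovery_to_machine_precision(self):
        truth = (2.0, 28.0, 22.0, 3.0)
        res = fit_venegas(GRID, venegas_curve(GRID, *truth))
        for name, value in zip("abcd", truth):
            assert res.params[name] == pytest.approx(value, rel=1e-6)
        assert res.rsquared_adj == pytest.approx(1.0, abs=1e-9)
        assert res.converged

    def test_zero_range_rejected(self):
        with pytest.raises(ValidationError):
            fit_venegas(GRID, np.full(8, 5.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_venegas(GRID[:4], venegas_curve(GRID[:4], 2, 28, 22, 3))

    def test_summary_contains_estimates(self):
        res = fit_venegas(GRID, venegas_curve(GRID, 2, 28, 22, 3))
        text = res.summary()
        assert "adj R2" in text and "22.0" in text

    def test_noisy_median_c_error_within_monte_carlo_tolerance(self):
        # recovery experiment: sigma = 1 AU on the default 8-point grid
        truth = (2.0, 28.0, 22.0, 3.0)
        clean = venegas_curve(GRID, *truth)
        rng = np.random.default_rng(2024)
        errors = []
        for _ in range(200):
            noisy = clean + rng.normal(0, 1.0, size=GRID.size)
            res = fit_venegas(GRID, noisy)
            errors.append(abs(res.params["c"] - truth[2]))
        assert np.median(errors) <= 1.5


class TestPredictedPressures:
    def test_derivative_peak_sits_at_inflection(self):
        res_inf = fit_venegas(GRID, venegas_curve(GRID, 2, 28, 22, 3))
        res_def = fit_venegas(GRID, venegas_curve(GRID, 2, 28, 14, 3))
        opening, closing = predicted_pressures(res_inf, res_def, grid_step=0.1)
        assert opening == pytest.approx(22.0, abs=0.05)
        assert closing == pytest.approx(14.0, abs=0.05)

    def test_inflection_outside_range_warns_and_reports_boundary(self):
        res = fit_venegas(np.linspace(0, 35, 10),
                          venegas_curve(np.linspace(0, 35, 10), 0, 30, 33, 4))
        res.params["c"] = 40.0  # force the boundary case
        with pytest.warns(UserWarning, match="outside"):
            assert res.predicted_pressure() == pytest.approx(35.0)


class TestRunsTest:
    @staticmethod
    def enumeration_p(signs):
        """Exact two-sided p by exhausting all arrangements of the signs."""
        signs = np.asarray(signs)
        n1 = int((signs > 0).sum())
        n = signs.size

        def count_runs(arr):
            return 1 + sum(a != b for a, b in zip(arr, arr[1:]))

        obs = count_runs(list(signs))
        all_runs = [count_runs(arr) for arr in
                    set(itertools.permutations(signs))]
        p_low = sum(r <= obs for r in all_runs) / len(all_runs)
        p_high = sum(r >= obs for r in all_runs) / len(all_runs)
        return min(1.0, 2 * min(p_low, p_high))

    def test_maximal_alternation_matches_enumeration(self):
        resid = [1, -1, 1, -1, 1, -1]
        assert runs_test(resid) == pytest.approx(
            self.enumeration_p(np.sign(resid)), rel=1e-12)

    @pytest.mark.parametrize("signs", [
        (1, 1, -1, -1, 1, 1, -1),
        (1, -1, -1, -1, 1, 1, 1, -1),
        (1, 1, 1, -1, -1, 1, -1, -1, 1),
    ])
    def test_exact_distribution_matches_enumeration(self, signs):
        assert runs_test(np.array(signs, dtype=float)) == pytest.approx(
            self.enumeration_p(signs), rel=1e-12)

    def test_single_sign_gives_degenerate_p(self):
        assert runs_test([1.0, 2.0, 3.0]) == 1.0

    def test_empty_residuals_rejected(self):
        with pytest.raises(ValidationError):
            runs_test([0.0, 0.0])

    @given(st.lists(st.sampled_from([-1.0, 1.0]), min_size=2, max_size=18))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_exact_p_is_a_probability_and_matches_enumeration(self, signs):
        p = runs_test(np.array(signs))
        assert 0 <= p <= 1
        if len(set(signs)) == 2 and len(signs) <= 9:
            assert p == pytest.approx(self.enumeration_p(signs), rel=1e-9)

    def test_normal_approximation_close_to_statsmodels(self):
        from statsmodels.sandbox.stats.runs import runstest_1samp
        rng = np.random.default_rng(5)
        resid = rng.normal(size=40)
        _, sm_p = runstest_1samp(resid, cutoff=0, correction=True)
        assert runs_test(resid) == pytest.approx(sm_p, abs=0.02)


class EITStub:
    def __init__(self, volumes, weights=(0.2, 0.5, 0.3), gain=0.5, offset=0.0):
        volumes = np.asarray(volumes, dtype=float)
        self.syringe_volumes = volumes
        self.z_right_whole = gain * volumes + offset
        for region, w in zip(("ventral", "central", "dorsal"), weights):
            setattr(self, f"z_{region}", gain * w * volumes + offset)


class TestCalibrateEIT:
    def test_affine_inversion_without_offset(self):
        rec = EITStub([0, 5, 10, 20], gain=0.5)
        cal = calibrate_eit(rec)
        assert cal.slope == pytest.approx(2.0)
        np.testing.assert_allclose(cal.volumes["right_whole"],
                                   rec.syringe_volumes, atol=1e-9)

    def test_affine_inversion_with_offset(self):
        rec = EITStub([0, 5, 10, 20], gain=0.5, offset=3.0)
        cal = calibrate_eit(rec)
        np.testing.assert_allclose(cal.volumes["right_whole"],
                                   rec.syringe_volumes, atol=1e-9)
        np.testing.assert_allclose(cal.volumes["central"],
                                   0.5 * rec.syringe_volumes, atol=1e-9)

    def test_regions_sum_to_right_whole(self):
        rec = EITStub([1, 4, 9, 16, 25], weights=(0.25, 0.4, 0.35), offset=2.0)
        cal = calibrate_eit(rec)
        total = sum(cal.volumes[r] for r in ("ventral", "central", "dorsal"))
        np.testing.assert_allclose(total, cal.volumes["right_whole"],
                                   rtol=1e-9)

    def test_constant_impedance_rejected(self):
        rec = EITStub([0, 5, 10], gain=1.0)
        rec.z_right_whole = np.full(3, 7.0)
        with pytest.raises(CalibrationError):
            calibrate_eit(rec)


class TestPoolSeries:
    def test_pooled_point_count(self):
        many = [series(GRID, venegas_curve(GRID, 2, 28, 22, 3),
                       [30, 20, 10], [30, 25, 10], lamb=f"L{i}")
                for i in range(20)]
        pooled = pool_series(many)
        assert pooled.inflation_values.size == 160
        assert pooled.lamb_id == "pooled"

    def test_single_series_identity(self):
        s = series(GRID, venegas_curve(GRID, 2, 28, 22, 3),
                   [30, 20, 10], [30, 25, 10])
        pooled = pool_series([s])
        np.testing.assert_array_equal(pooled.inflation_values,
                                      s.inflation_values)

    def test_mixed_signal_kinds_rejected(self):
        a = series(GRID, GRID, [30, 20], [2, 1], kind="delta_mgv")
        b = series(GRID, GRID, [30, 20], [2, 1], kind="volume_total")
        with pytest.raises(ValidationError):
            pool_series([a, b])

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError):
            pool_series([])


class TestModelAgainstGenerator:
    def test_predicted_pressures_track_truth_inflections(self):
        """On noiseless generator lambs the model-predicted opening/closing
        pressures sit within one schedule step of the true c values."""
        from greylung.synth import make_lamb_truth, simulate_pv_series
        hits_open = hits_close = n = 0
        for seed in range(40):
            t = make_lamb_truth(seed)
            total, _ = simulate_pv_series(t)
            res_inf = VenegasModel.from_series(total, "inflation").fit()
            res_def = VenegasModel.from_series(total, "deflation").fit()
            with np.errstate(over="ignore"):
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    opening = res_inf.predicted_pressure()
                    closing = res_def.predicted_pressure()
            n += 1
            hits_open += abs(opening - t.inflation_params.c) <= 5.0
            hits_close += abs(closing - t.deflation_params.c) <= 5.0
        assert hits_open / n >= 0.9
        assert hits_close / n >= 0.9
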