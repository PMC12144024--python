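import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import waterpet as wp
from waterpet.aif import (
    InputFunction,
    apply_delay,
    apply_dispersion,
    calibrate_input,
    correct_dispersion,
    estimate_delay_dispersion,
    make_aif,
    read_aif_csv,
    write_aif_csv,
)
from waterpet.kinetics import frame_average


def auc(curve: InputFunction) -> float:
    return float(np.trapezoid(curve.activity, curve.times))


class TestMakeAif:
    def test_zero_dose_gives_zero_curve(self):
        assert np.all(make_aif(dose_scale=0.0).activity == 0.0)

    def test_peak_at_gamma_variate_maximum(self):
        # analytic argmax of the gamma-variate bolus: t0 + alpha * beta
        p = {"t0": 15.0, "alpha": 3.0, "beta": 5.0, "recirc_frac": 0.0}
        curve = make_aif(shape_params=p)
        t_peak = curve.times[np.argmax(curve.activity)]
        assert abs(t_peak - 30.0) <= 0.5  # within one grid step

    def test_dose_linearity(self):
        c1 = make_aif(dose_scale=25.0)
        c2 = make_aif(dose_scale=50.0)
        np.testing.assert_allclose(c2.activity, 2 * c1.activity)
        assert auc(c2) == pytest.approx(2 * auc(c1))

    def test_zero_at_time_zero_and_nonnegative(self):
        curve = make_aif()
        assert curve.activity[0] == 0.0
        assert np.all(curve.activity >= 0.0)

    def test_single_early_peak_then_decay(self):
        curve = make_aif()
        i_peak = int(np.argmax(curve.activity))
        assert curve.times[i_peak] < 60.0
        # after the peak the curve never rises again above any earlier value
        tail = curve.activity[i_peak:]
        assert np.all(np.diff(np.maximum.accumulate(tail[::-1])[::-1]) <= 1e-12)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            make_aif(grid=np.array([0.0, 2.0, 1.0]))


class TestCalibration:
    def test_samples_on_curve_give_unit_factor(self, aif):
        samples = [(300.0, float(aif(300.0))), (360.0, float(aif(360.0)))]
        out = calibrate_input(aif, samples)
        assert out.calibration_factor == pytest.approx(1.0)
        np.testing.assert_allclose(out.activity, aif.activity)

    def test_mean_ratio_rule(self):
        # curve value 10 at t=300 and 8 at t=360; samples 20% above each
        t = np.arange(0.0, 400.0, 1.0)
        a = np.interp(t, [0, 300, 360, 399], [10, 10, 8, 8])
        curve = InputFunction(t, a)
        out = calibrate_input(curve, [(300.0, 12.0), (360.0, 9.6)])
        assert out.calibration_factor == pytest.approx(1.2)

    def test_sample_outside_support_raises(self, aif):
        with pytest.raises(ValueError):
            calibrate_input(aif, [(1e5, 1.0)])

    def test_empty_samples_raise(self, aif):
        with pytest.raises(ValueError):
            calibrate_input(aif, [])

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, c):
        curve = make_aif()
        base = [(300.0, 5.0), (360.0, 4.0)]
        f1 = calibrate_input(curve, base).calibration_factor
        f2 = calibrate_input(curve, [(t, c * a) for t, a in base]).calibration_factor
        assert f2 == pytest.approx(c * f1, rel=1e-9)


class TestDispersion:
    def test_tau_zero_is_identity(self, aif):
        out = apply_dispersion(aif, 0.0)
        np.testing.assert_array_equal(out.activity, aif.activity)

    def test_unit_step_closed_form(self):
        t = np.arange(0.0, 200.5, 0.5)
        step = InputFunction(t, np.ones_like(t))
        out = apply_dispersion(step, 10.0)
        expected = 1.0 - np.exp(-t / 10.0)
        np.testing.assert_allclose(out.activity, expected, atol=1e-6)
        assert float(np.interp(10.0, t, out.activity)) == pytest.approx(0.6321, abs=1e-4)

    def test_auc_preserved(self):
        # bolus ends well before T; integrate the output 5 tau past the end
        tau = 8.0
        curve = make_aif(
            shape_params={"recirc_frac": 0.0}, grid=np.arange(0.0, 600.25, 0.5)
        )
        out = apply_dispersion(curve, tau)
        T = 200.0
        sel_in = curve.times <= T
        sel_out = out.times <= T + 5 * tau
        ratio = np.trapezoid(out.activity[sel_out], out.times[sel_out]) / np.trapezoid(
            curve.activity[sel_in], curve.times[sel_in]
        )
        assert 0.99 <= ratio <= 1.01

    def test_negative_tau_rejected(self, aif):
        with pytest.raises(ValueError):
            apply_dispersion(aif, -1.0)
        with pytest.raises(ValueError):
            correct_dispersion(aif, -1.0)

    def test_round_trip_correction(self):
        curve = make_aif()
        dispersed = apply_dispersion(curve, 8.0)
        back = correct_dispersion(dispersed, 8.0)
        err = np.abs(back.activity - curve.activity).max() / curve.activity.max()
        assert err < 0.02

    def test_exponential_decay_corrects_to_zero(self):
        # C(t) = exp(-t/tau) satisfies C + tau dC/dt = 0 identically
        tau = 10.0
        t = np.arange(0.0, 100.5, 0.5)
        curve = InputFunction(t, np.exp(-t / tau))
        out = correct_dispersion(curve, tau, smooth_window=0)
        interior = (t > 1.0) & (t < 99.0)
        assert np.abs(out.activity[interior]).max() < 1e-3

    def test_linearity(self, aif):
        double = InputFunction(aif.times, 2 * aif.activity)
        np.testing.assert_allclose(
            apply_dispersion(double, 6.0).activity,
            2 * apply_dispersion(aif, 6.0).activity,
            rtol=1e-12,
        )


class TestDelay:
    def test_zero_delay_identity(self, aif):
        np.testing.assert_array_equal(apply_delay(aif, 0.0).activity, aif.activity)

    def test_peak_moves_by_delta(self):
        curve = make_aif(shape_params={"recirc_frac": 0.0})
        t_peak = curve.times[np.argmax(curve.activity)]
        shifted = apply_delay(curve, 5.0)
        assert shifted.times[np.argmax(shifted.activity)] == pytest.approx(t_peak + 5.0)

    def test_inverse_shifts(self, aif):
        back = apply_delay(apply_delay(aif, 5.0), -5.0)
        interior = (aif.times > 10.0) & (aif.times < aif.times[-1] - 10.0)
        np.testing.assert_allclose(
            back.activity[interior], aif.activity[interior], atol=1e-9
        )

    def test_shift_disperse_commute(self, aif):
        a = apply_dispersion(apply_delay(aif, 5.0), 8.0)
        b = apply_delay(apply_dispersion(aif, 8.0), 5.0)
        interior = aif.times < aif.times[-1] - 10.0
        tol = 0.005 * aif.activity.max()
        assert np.abs(a.activity[interior] - b.activity[interior]).max() < tol


class TestEstimateDelayDispersion:
    def make_wb_tac(self, aif, schedule, tau, delay, params):
        brain_input = apply_dispersion(apply_delay(aif, delay), tau)
        curve = wp.model_tac(params, brain_input)
        return frame_average(aif.times, curve, schedule)

    def test_recovers_known_tau_and_delay(self, aif, schedule):
        params = wp.KineticParams(K1=0.5, k2=0.55, VA=0.03)
        tac = self.make_wb_tac(aif, schedule, tau=8.0, delay=4.0, params=params)
        fit = estimate_delay_dispersion(tac, aif, tau_grid=np.arange(0.0, 16.0, 1.0))
        assert abs(fit.tau - 8.0) <= 1.0
        assert abs(fit.delay - 4.0) <= 0.5

    def test_null_case(self, aif, schedule):
        params = wp.KineticParams(K1=0.5, k2=0.55, VA=0.03)
        tac = self.make_wb_tac(aif, schedule, tau=0.0, delay=0.0, params=params)
        fit = estimate_delay_dispersion(tac, aif, tau_grid=np.arange(0.0, 6.0, 1.0))
        assert fit.tau == 0.0
        assert abs(fit.delay) < 0.5

    def test_rss_is_minimum_of_table(self, aif, schedule):
        params = wp.KineticParams(K1=0.5, k2=0.55, VA=0.03)
        tac = self.make_wb_tac(aif, schedule, tau=5.0, delay=2.0, params=params)
        fit = estimate_delay_dispersion(tac, aif, tau_grid=np.arange(0.0, 11.0, 2.0))
        assert fit.rss == pytest.approx(fit.per_tau_rss["rss"].min())
        assert fit.tau in fit.per_tau_rss["tau_s"].to_numpy()

    def test_empty_or_negative_grid_rejected(self, aif, schedule):
        tac = wp.TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        with pytest.raises(ValueError):
            estimate_delay_dispersion(tac, aif, tau_grid=np.array([]))
        with pytest.raises(ValueError):
            estimate_delay_dispersion(tac, aif, tau_grid=np.array([-1.0]))


def test_csv_round_trip(tmp_path, aif):
    path = tmp_path / "aif.csv"
    write_aif_csv(aif, path)
    back = read_aif_csv(path)
    np.testing.assert_allclose(back.times, aif.times)
    np.testing.assert_allclose(back.activity, aif.activity)
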