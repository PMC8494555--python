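"""Curve quantifier: each indicator against hand-computable shapes."""

import dataclasses

import numpy as np
import pytest

from ceuskit import (
    Conventions,
    PerfusionParams,
    TICurve,
    analytic_tic_parameters,
    perfusion_curve,
    quantify,
)
from ceuskit.errors import FlatCurveError, InvalidInputError
from ceuskit.tic import (
    arrival_time,
    auc_trapezoid,
    detect_peak,
    estimate_baseline,
    mean_transit_time,
    rise_time,
    slopes_k,
    wash_in_gradient,
)


def curve(times, intensities, window=None):
    t = np.asarray(times, dtype=float)
    return TICurve(
        times=t,
        intensities=np.asarray(intensities, dtype=float),
        window=window if window is not None else max(120.0, float(t[-1])),
    )


def triangle(dt=0.01):
    """Rise 0 -> 100 over 10 s, fall back to 0 over a further 20 s."""
    t = np.arange(0.0, 30.0 + dt, dt)
    y = np.where(t <= 10.0, 10.0 * t, 100.0 - 5.0 * (t - 10.0))
    return curve(t, np.clip(y, 0.0, None))


def ramp(dt=0.01):
    t = np.arange(0.0, 10.0 + dt, dt)
    return curve(t, 10.0 * t)


class TestBaseline:
    def test_constant_curve(self):
        c = curve(np.arange(10.0), np.full(10, 5.0))
        assert estimate_baseline(c) == 5.0

    def test_model_fixture_with_late_arrival(self):
        p = PerfusionParams(t0=15.0, alpha=2.0, beta=5.0, A=1.0, baseline=10.0)
        assert estimate_baseline(perfusion_curve(p)) == pytest.approx(10.0)

    def test_translation_equivariance(self, fast_curve):
        shifted = dataclasses.replace(
            fast_curve, intensities=fast_curve.intensities + 3.0
        )
        assert estimate_baseline(shifted) == pytest.approx(
            estimate_baseline(fast_curve) + 3.0
        )


class TestPeak:
    def test_gamma_variate_argmax(self):
        p = PerfusionParams(t0=10.0, alpha=2.0, beta=5.0, A=1.0, baseline=0.0, dt=0.1)
        ttp, _ = detect_peak(perfusion_curve(p))
        assert ttp == pytest.approx(20.0, abs=2 * p.dt)

    def test_constant_curve_ties_resolve_earliest(self):
        c = curve(np.arange(10.0), np.full(10, 4.0))
        ttp, i_max = detect_peak(c)
        assert ttp == 0.0
        assert i_max == 4.0

    def test_two_equal_maxima_pick_earlier(self):
        y = [0, 0, 0, 9, 0, 0, 0, 9, 0, 0, 0]
        c = curve(np.arange(11.0), y)
        ttp, _ = detect_peak(c, Conventions(smooth_window=1))
        assert ttp == 3.0


class TestArrival:
    def test_ten_percent_crossing_of_a_ramp(self):
        assert arrival_time(ramp(), baseline=0.0, i_max=100.0) == pytest.approx(
            1.0, abs=0.02
        )

    def test_exact_sample_crossing(self):
        c = curve(np.arange(8.0), [0, 0, 0, 10, 20, 30, 40, 50])
        conv = Conventions(smooth_window=1)
        # threshold = 5 crosses between samples; threshold hit exactly at 10
        t = arrival_time(c, baseline=0.0, i_max=50.0, conv=conv)
        assert t == pytest.approx(2.5)

    def test_flat_curve_rejected(self):
        c = curve(np.arange(8.0), np.full(8, 3.0))
        with pytest.raises(FlatCurveError):
            arrival_time(c, baseline=3.0, i_max=3.0)


class TestRiseAndTransit:
    def test_triangle_rise_time(self):
        assert rise_time(triangle(), baseline=0.0) == pytest.approx(9.0, abs=0.05)

    def test_symmetric_triangle_first_moment(self):
        t = np.arange(0.0, 20.0 + 0.01, 0.01)
        y = np.clip(10.0 - np.abs(t - 10.0), 0.0, None) * 10.0
        c = curve(t, y)
        # symmetric about the peak: mTT = peak time - arrival
        conv = Conventions()
        arr = arrival_time(c, 0.0, 100.0, conv)
        assert mean_transit_time(c, baseline=0.0) == pytest.approx(
            10.0 - arr, rel=0.01
        )

    def test_time_shift_invariance(self):
        c = triangle()
        shifted = curve(c.times + 30.0, c.intensities, window=c.window + 30.0)
        assert rise_time(shifted, 0.0) == pytest.approx(rise_time(c, 0.0), rel=1e-6)
        assert mean_transit_time(shifted, 0.0) == pytest.approx(
            mean_transit_time(c, 0.0), rel=1e-6
        )


class TestAUC:
    def test_constant_curve_zero(self):
        c = curve(np.arange(10.0), np.full(10, 6.0))
        assert auc_trapezoid(c) == 0.0

    def test_triangle_area(self):
        assert auc_trapezoid(triangle(), baseline=0.0) == pytest.approx(1500.0, rel=1e-3)

    def test_quadrature_convergence(self, fast_bolus):
        coarse = quantify(perfusion_curve(fast_bolus)).AUC
        fine_params = dataclasses.replace(fast_bolus, dt=fast_bolus.dt / 2)
        fine = quantify(perfusion_curve(fine_params)).AUC
        assert abs(coarse - fine) / fine < 0.005


class TestSlopes:
    def test_linear_ramp_gradient(self):
        assert wash_in_gradient(ramp(), baseline=0.0) == pytest.approx(10.0, rel=0.01)

    def test_constant_curve_rejected(self):
        c = curve(np.arange(8.0), np.full(8, 2.0))
        with pytest.raises(FlatCurveError):
            wash_in_gradient(c, baseline=2.0)

    def test_intensity_scaling_scales_gradient(self):
        c = triangle()
        scaled = curve(c.times, 3.0 * c.intensities)
        assert wash_in_gradient(scaled, 0.0) == pytest.approx(
            3.0 * wash_in_gradient(c, 0.0), rel=1e-6
        )

    def test_triangle_chord_slopes(self):
        k_up, k_down = slopes_k(triangle(), baseline=0.0)
        assert k_up == pytest.approx(100.0 / 9.0, rel=0.02)
        assert k_down == pytest.approx(5.0, rel=0.02)

    def test_monotone_curve_flags_missing_washout(self):
        _, k_down = slopes_k(ramp(), baseline=0.0)
        assert k_down is None

    def test_k_down_nonnegative_on_model_curves(self, fast_bolus):
        _, k_down = slopes_k(perfusion_curve(fast_bolus))
        assert k_down is not None and k_down >= 0


class TestQuantify:
    def test_noiseless_model_recovery_within_two_percent(self, fast_bolus, slow_bolus):
        for params in (fast_bolus, slow_bolus):
            oracle = analytic_tic_parameters(params)
            est = quantify(perfusion_curve(params))
            for name, expected in oracle.as_dict().items():
                value = getattr(est, name)
                assert value == pytest.approx(expected, rel=0.02), name

    def test_constant_curve_flags_enhancement_absent(self):
        c = curve(np.arange(10.0), np.full(10, 5.0))
        p = quantify(c)
        assert p.baseline == 5.0
        assert p.TTP is None and p.Grad is None and p.K_UP is None

    def test_intensity_scale_equivariance(self, fast_bolus):
        base = quantify(perfusion_curve(fast_bolus))
        scaled_params = dataclasses.replace(
            fast_bolus, A=3.0 * fast_bolus.A, baseline=3.0 * fast_bolus.baseline
        )
        scaled = quantify(perfusion_curve(scaled_params))
        for name in ("AUC", "Grad", "K_UP", "K_DOWN"):
            assert getattr(scaled, name) == pytest.approx(
                3.0 * getattr(base, name), rel=0.01
            ), name
        for name in ("TTP", "RT", "mTT"):
            assert getattr(scaled, name) == pytest.approx(
                getattr(base, name), rel=0.01
            ), name

    def test_slower_washout_never_steepens_k_down(self, fast_bolus):
        # compare washout speeds at matched peak enhancement: scale A so
        # I_max stays fixed while beta stretches the time axis
        k_downs = []
        for beta in (4.0, 5.0, 7.0, 9.0):
            params = dataclasses.replace(fast_bolus, beta=beta)
            scale = fast_bolus.peak_enhancement / params.peak_enhancement
            params = dataclasses.replace(params, A=params.A * scale)
            k_downs.append(quantify(perfusion_curve(params)).K_DOWN)
        assert all(a >= b for a, b in zip(k_downs, k_downs[1:]))

    def test_curve_validation(self):
        with pytest.raises(InvalidInputError):
            TICurve(times=np.arange(5.0), intensities=np.ones(5))  # too short
        with pytest.raises(InvalidInputError):
            TICurve(times=np.zeros(10), intensities=np.ones(10))  # not increasing
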