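"""Unit and property tests for the PFR-2CSTR compartment model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikertd.compartment import (
    CompartmentParams,
    DegenerateCascadeError,
    RTDCurve,
    SpikeSchedule,
    UndefinedMetricsError,
    cascade_response,
    closed_form_outlet,
    outlet_cumulative,
    rect_input,
    rtd_metrics,
    window_averaged_outlet,
)

PARAMS = CompartmentParams(4.3, (4.1, 1.0))


def integrate_cascade_rk4(schedule, params, t_end, dt=1e-3):
    """Independent brute-force oracle: classical RK4 on the serial CSTR
    mass balances, integrated piecewise between the input discontinuities
    so the right-hand side is smooth on every segment.

    Returns (times, normalized outlet) on the concatenated fine grids.
    """
    tau_pfr = params.tau_pfr
    taus = params.cstr_taus
    breaks = [0.0, tau_pfr, tau_pfr + schedule.t_spike, t_end]
    breaks = sorted(b for b in set(breaks) if 0.0 <= b <= t_end)

    def rhs(c, u):
        out = []
        prev = u
        for ci, tau in zip(c, taus):
            out.append((prev - ci) / tau)
            prev = ci
        return out

    c = [0.0] * len(taus)
    all_t, all_v = [0.0], [0.0]
    for a, b in zip(breaks, breaks[1:]):
        mid = 0.5 * (a + b) - tau_pfr
        u = 1.0 if 0.0 <= mid <= schedule.t_spike else 0.0
        n = max(1, int(np.ceil((b - a) / dt)))
        h = (b - a) / n
        for k in range(n):
            k1 = rhs(c, u)
            k2 = rhs([ci + 0.5 * h * k1i for ci, k1i in zip(c, k1)], u)
            k3 = rhs([ci + 0.5 * h * k2i for ci, k2i in zip(c, k2)], u)
            k4 = rhs([ci + h * k3i for ci, k3i in zip(c, k3)], u)
            c = [
                ci + h / 6.0 * (k1i + 2 * k2i + 2 * k3i + k4i)
                for ci, k1i, k2i, k3i, k4i in zip(c, k1, k2, k3, k4)
            ]
            all_t.append(a + (k + 1) * h)
            all_v.append(c[-1])
    return np.asarray(all_t), np.asarray(all_v)


class TestRectInput:
    def test_inside_pulse_is_mixed_concentration(self):
        s = SpikeSchedule(c_spike=1.0, q_feed=0.41, q_spike=0.041, t_spike=1.0)
        assert rect_input(0.5, s) == pytest.approx((0.1 / 1.1) * 1.0, rel=1e-3)
        assert rect_input(0.5, s) == pytest.approx(s.gamma * s.c_spike)

    def test_outside_pulse_is_zero_and_boundary_is_closed(self):
        s = SpikeSchedule(t_spike=1.0)
        assert rect_input(2.0, s) == 0.0
        assert rect_input(1.0, s) == s.c_mixed

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rect_input(-0.1, SpikeSchedule())


class TestClosedForm:
    def test_long_spike_plateau_reaches_one(self):
        s = SpikeSchedule(t_spike=40.0)
        t = np.arange(40.0, 44.3, 0.001)
        assert closed_form_outlet(t, s, PARAMS).max() == pytest.approx(1.0, abs=1e-3)

    def test_zero_before_plug_flow_delay(self):
        s = SpikeSchedule(t_spike=5.0)
        t = np.linspace(0, 4.3, 500)
        assert np.all(closed_form_outlet(t, s, PARAMS) == 0.0)
        assert closed_form_outlet(4.31, s, PARAMS) > 0.0

    def test_peak_against_brute_force_oracle(self):
        """The 5-min spike peaks at ~0.6 near 10 min; closed form agrees
        with piecewise RK4 integration of the CSTR mass balances to 1e-6."""
        s = SpikeSchedule(t_spike=5.0)
        t_o, v_o = integrate_cascade_rk4(s, PARAMS, 20.0)
        v_c = closed_form_outlet(t_o, s, PARAMS)
        assert np.abs(v_c - v_o).max() < 1e-6
        t = np.arange(0.0, 60.0005, 0.001)
        f = closed_form_outlet(t, s, PARAMS)
        assert round(float(f.max()), 1) == 0.6
        assert round(float(t[f.argmax()])) == 10

    def test_swap_symmetry(self):
        s = SpikeSchedule(t_spike=5.0)
        t = np.linspace(0, 40, 400)
        a = closed_form_outlet(t, s, CompartmentParams(4.3, (4.1, 1.0)))
        b = closed_form_outlet(t, s, CompartmentParams(4.3, (1.0, 4.1)))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_repeated_root_matches_numeric(self):
        s = SpikeSchedule(t_spike=2.0)
        p = CompartmentParams(1.0, (2.0, 2.0))
        grid = np.linspace(0, 30, 301)
        num = cascade_response(
            lambda x: rect_input(x, s), p, grid, normalize_by=s.c_mixed
        )
        np.testing.assert_allclose(
            closed_form_outlet(grid, s, p), num.values, atol=1e-6
        )

    def test_three_cstr_closed_form_unsupported(self):
        with pytest.raises(DegenerateCascadeError):
            closed_form_outlet(1.0, SpikeSchedule(), CompartmentParams(1.0, (1.0, 2.0, 3.0)))

    def test_continuity_at_gate_times(self):
        s = SpikeSchedule(t_spike=5.0)
        for t_edge in (4.3, 9.3):
            left = closed_form_outlet(t_edge - 1e-7, s, PARAMS)
            right = closed_form_outlet(t_edge + 1e-7, s, PARAMS)
            assert abs(left - right) < 1e-6

    def test_zero_tau_limit_recovers_delayed_rectangle(self):
        s = SpikeSchedule(t_spike=2.0)
        p = CompartmentParams(3.0, (1e-9, 1e-10))
        assert closed_form_outlet(4.0, s, p) == pytest.approx(1.0, abs=1e-6)
        assert closed_form_outlet(2.9, s, p) == 0.0
        assert closed_form_outlet(5.5, s, p) == pytest.approx(0.0, abs=1e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        tau_pfr=st.floats(0.0, 10.0),
        tau1=st.floats(0.1, 10.0),
        tau2=st.floats(0.1, 10.0),
        t_spike=st.floats(0.1, 50.0),
        t=st.floats(0.0, 120.0),
    )
    def test_bounded_between_zero_and_one(self, tau_pfr, tau1, tau2, t_spike, t):
        s = SpikeSchedule(t_spike=t_spike)
        p = CompartmentParams(tau_pfr, (tau1, tau2))
        v = closed_form_outlet(t, s, p)
        assert -1e-12 <= v <= 1.0 + 1e-9

    def test_linear_in_spike_concentration(self):
        t = np.linspace(0, 30, 100)
        lo = SpikeSchedule(c_spike=0.5, t_spike=5.0)
        hi = SpikeSchedule(c_spike=2.0, t_spike=5.0)
        # normalized curves coincide, so raw outputs scale with c_spike
        a = closed_form_outlet(t, lo, PARAMS) * lo.c_mixed
        b = closed_form_outlet(t, hi, PARAMS) * hi.c_mixed
        np.testing.assert_allclose(b, 4.0 * a, rtol=1e-12)


class TestCascadeResponse:
    def test_single_cstr_step_response(self):
        p = CompartmentParams(0.0, (2.5,))
        grid = np.linspace(0, 20, 400)
        curve = cascade_response(lambda t: 1.0, p, grid)
        np.testing.assert_allclose(curve.values, 1 - np.exp(-grid / 2.5), atol=1e-7)

    def test_zero_volume_cascade_is_delayed_copy(self):
        s = SpikeSchedule(t_spike=2.0)
        p = CompartmentParams(1.0, (0.0, 0.0))
        grid = np.linspace(0.05, 10, 200)  # off the discontinuities
        curve = cascade_response(
            lambda t: rect_input(t, s), p, grid, normalize_by=s.c_mixed
        )
        expected = np.where((grid > 1.0) & (grid <= 3.0), 1.0, 0.0)
        mism = np.abs(curve.values - expected)
        # at most the two samples landing exactly on the jump edges may differ
        assert int(np.sum(mism > 1e-9)) <= 2

    def test_matches_closed_form_on_long_grid(self):
        """Sup-norm equivalence of the numeric cascade and the closed form."""
        s = SpikeSchedule(t_spike=5.0)
        grid = np.arange(0.0, 100.01, 0.01)
        num = cascade_response(
            lambda t: rect_input(t, s), PARAMS, grid, dt_max=1e-3,
            normalize_by=s.c_mixed,
        )
        cf = closed_form_outlet(grid, s, PARAMS)
        assert np.abs(num.values - cf).max() < 1e-6

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            cascade_response(lambda t: float("nan"), PARAMS, np.linspace(5, 10, 10))


@pytest.fixture(scope="module")
def short_spike_curve():
    s = SpikeSchedule(t_spike=1.0)
    t = np.arange(0.0, 120.0, 0.002)
    return RTDCurve(t, closed_form_outlet(t, s, PARAMS))


class TestMetricsAndMoments:

    def test_area_equals_spike_duration(self, short_spike_curve):
        m = rtd_metrics(short_spike_curve, threshold=0.01)
        assert m.area == pytest.approx(1.0, rel=1e-3)

    def test_mean_minus_pulse_centroid_is_total_space_time(self, short_spike_curve):
        m = rtd_metrics(short_spike_curve, threshold=0.01)
        assert m.mean_time - 0.5 == pytest.approx(PARAMS.total_time, rel=1e-3)

    def test_onset_approaches_plug_flow_delay(self, short_spike_curve):
        m = rtd_metrics(short_spike_curve, threshold=1e-4)
        assert m.onset_time == pytest.approx(4.3, abs=0.05)

    def test_all_zero_curve_rejected(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(UndefinedMetricsError):
            rtd_metrics(RTDCurve(t, np.zeros_like(t)), threshold=0.1)

    def test_onset_not_after_peak(self, short_spike_curve):
        m = rtd_metrics(short_spike_curve, threshold=0.05)
        assert m.onset_time <= m.peak_time

    def test_window_average_matches_quadrature(self):
        s = SpikeSchedule(t_spike=1.0)
        windows = np.array([[4.0, 6.0], [8.0, 10.0], [14.0, 16.0]])
        wa = window_averaged_outlet(windows, s, PARAMS)
        for (a, b), v in zip(windows, wa):
            t = np.linspace(a, b, 4001)
            q = np.trapezoid(closed_form_outlet(t, s, PARAMS), t) / (b - a)
            assert v == pytest.approx(q, rel=1e-8)

    def test_cumulative_integral_conserves_mass(self):
        # total eluted mass equals the injected pulse duration (normalized)
        s = SpikeSchedule(t_spike=5.0)
        assert outlet_cumulative(400.0, s, PARAMS) == pytest.approx(5.0, rel=1e-9)


class TestValidation:
    def test_schedule_requires_positive_fields(self):
        with pytest.raises(ValueError):
            SpikeSchedule(t_spike=0.0)

    def test_params_canonical_ordering(self):
        p = CompartmentParams(1.0, (1.0, 4.0)).canonical()
        assert p.cstr_taus == (4.0, 1.0)

    def test_curve_requires_increasing_times(self):
        with pytest.raises(ValueError):
            RTDCurve(np.array([0.0, 1.0, 1.0]), np.zeros(3))
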