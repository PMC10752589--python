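import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from starburst.rf import (RFParams, apply_sensor_filter, bc_drive,
                          rf_area_fraction, sensor_kernel,
                          simulate_bc_response, shift_trace)
from starburst.stimuli import make_bar_stimulus, make_flash_stimulus


def riemann_area(width, rf_x, stim, t, dx=0.1):
    """Brute-force overlap integral of the unit-mass Gaussian on a dense
    0.1 um grid (Simpson quadrature so the oracle's own error stays well
    below the comparison tolerance)."""
    from scipy.integrate import simpson
    sigma = width / (2 * np.sqrt(2 * np.log(2)))
    total = 0.0
    for a, b in stim.footprint(t):
        n = max(3, int(np.ceil((b - a) / dx)) | 1)
        x = np.linspace(a, b, n)
        total += simpson(np.exp(-((x - rf_x) ** 2) / (2 * sigma ** 2)), x=x)
    return total / (sigma * np.sqrt(2 * np.pi))


class TestAreaFraction:
    def test_full_coverage_is_one(self):
        stim = make_flash_stimulus(4.0)
        for w in (10.0, 50.0, 150.0):
            assert rf_area_fraction(w, 500.0, stim, 100.0) == pytest.approx(1.0, abs=1e-9)

    def test_half_coverage_at_leading_edge(self):
        # leading edge exactly at the RF center, bar extends far behind
        stim = make_bar_stimulus(0.5)
        assert rf_area_fraction(50.0, 500.0, stim, 1000.0) == pytest.approx(0.5, abs=1e-9)

    def test_matches_riemann_oracle(self):
        rng = np.random.default_rng(7)
        stim = make_bar_stimulus(0.5)
        for _ in range(20):
            w = rng.uniform(15, 250)
            x = rng.uniform(150, 850)
            t = rng.uniform(0, stim.total_duration_ms)
            assert rf_area_fraction(w, x, stim, t) == pytest.approx(
                riemann_area(w, x, stim, t), abs=1e-6)

    def test_monotone_while_bar_covers_rf(self):
        stim = make_bar_stimulus(0.5)
        vals = [rf_area_fraction(60.0, 500.0, stim, t)
                for t in np.arange(0, 2000.0, 50.0)]   # before any uncovering
        assert np.all(np.diff(vals) >= -1e-12)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            rf_area_fraction(0.0, 500.0, make_bar_stimulus(0.5), 10.0)


class TestRecursion:
    def test_zero_contrast_gives_zero_response(self):
        # a fully masked bar never illuminates the arena
        stim = make_bar_stimulus(0.5, mask_intervals=[(0.0, 1000.0)])
        tr = simulate_bc_response(RFParams(), stim)
        assert np.all(tr.rf_full == 0.0)

    def test_flash_steady_state_closed_form(self):
        # no surround, effectively no adaptation: the center recursion's
        # fixed point gives RF_full -> amp * area / (area + R_in)
        p = RFParams(amplitude=0.7, surround_strength=1e-9,
                     center_decay=1e12, center_width=50.0)
        tr = simulate_bc_response(p, make_flash_stimulus(4.0))
        area_inf = 1.0
        expect = 0.7 * area_inf / (area_inf + 0.1 * area_inf)
        assert tr.rf_full[-5] == pytest.approx(expect, rel=1e-3)

    def test_flash_engages_entire_rf_at_onset(self):
        # area_center reaches its asymptotic value immediately, whatever
        # the width
        for w in (20.0, 97.0, 300.0):
            tr = simulate_bc_response(RFParams(center_width=w),
                                      make_flash_stimulus(2.0))
            assert tr.area_center[1] == pytest.approx(tr.area_center.max(),
                                                      abs=1e-9)

    def test_direction_symmetry_for_centered_cell(self):
        p = RFParams()
        tr_r = simulate_bc_response(p, make_bar_stimulus(0.5, 1), rf_x=500.0)
        tr_l = simulate_bc_response(p, make_bar_stimulus(0.5, -1), rf_x=500.0)
        np.testing.assert_allclose(tr_r.rf_full, tr_l.rf_full, atol=1e-12)

    def test_wide_center_leads_narrow_center(self):
        from starburst.metrics import onset_time
        stim = make_bar_stimulus(0.5)
        wide = simulate_bc_response(RFParams(center_width=97.0), stim)
        narrow = simulate_bc_response(RFParams(center_width=22.0), stim)
        lead = onset_time(narrow.rf_full) - onset_time(wide.rf_full)
        assert lead > 0.0          # wide RF responds first
        assert 30.0 < lead < 500.0  # on the order of a hundred ms at 0.5 mm/s

    def test_delay_is_pure_time_shift(self):
        stim = make_bar_stimulus(1.0)
        base = simulate_bc_response(RFParams(delay=0.0), stim)
        delayed = simulate_bc_response(RFParams(delay=50.0), stim)
        np.testing.assert_allclose(delayed.rf_full[50:-1],
                                   base.rf_full[:-51], atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(amp=st.floats(0.05, 1.0), ss=st.floats(0.0, 1.0),
           rev=st.floats(0.0, 1.0), w=st.floats(10.0, 300.0),
           rise=st.floats(1.0, 300.0), decay=st.floats(5.0, 5000.0))
    def test_bounds_and_adaptation_invariants(self, amp, ss, rev, w, rise, decay):
        p = RFParams(amplitude=amp, surround_strength=ss,
                     surround_reversal=rev, center_width=w,
                     center_rise=rise, center_decay=decay)
        tr = simulate_bc_response(p, make_bar_stimulus(2.0))
        assert np.all(tr.rf_full >= 0.0) and np.all(tr.rf_full <= 1.0)
        assert np.all(tr.adaptation >= 0.0) and np.all(tr.adaptation <= 1.0)
        assert np.all(np.diff(tr.adaptation) <= 1e-12)


class TestSensorFilter:
    def test_impulse_response_is_kernel_with_analytic_peak(self):
        k = sensor_kernel(10.0, 50.0)
        x = np.zeros(600)
        x[0] = 1.0
        out = apply_sensor_filter(x)
        n = min(out.size, k.size)
        np.testing.assert_allclose(out[:n], k[:n], atol=1e-12)
        tau_star = np.log(50.0 / 10.0) * 10.0 * 50.0 / 40.0   # ~20.1 ms
        assert abs(np.argmax(k) - tau_star) <= 1.0

    def test_constant_input_constant_output(self):
        out = apply_sensor_filter(np.ones(2000))
        tail = out[800:]
        assert np.ptp(tail) < 1e-9 * tail.mean()

    def test_step_matches_direct_convolution(self):
        rng = np.random.default_rng(3)
        x = np.r_[np.zeros(50), np.ones(200)] + 0.01 * rng.standard_normal(250)
        k = sensor_kernel(10.0, 50.0)
        expect = np.convolve(x, k)[:250]
        np.testing.assert_allclose(apply_sensor_filter(x), expect, atol=1e-12)

    def test_invalid_filter_times(self):
        with pytest.raises(ValueError):
            sensor_kernel(50.0, 10.0)
        with pytest.raises(ValueError):
            sensor_kernel(0.0, 50.0)


def test_shift_trace_fractional():
    x = np.arange(10.0)
    np.testing.assert_allclose(shift_trace(x, 2.5)[3:],
                               np.arange(0.5, 7.0, 1.0))
    assert np.all(shift_trace(x, 2.5)[:3] <= 0.5)


def test_param_validation():
    with pytest.raises(ValueError):
        RFParams(amplitude=1.2)
    with pytest.raises(ValueError):
        RFParams(center_width=-5.0)
    with pytest.raises(ValueError):
        RFParams(delay=-1.0)


def test_bc_drive_matches_single_cell():
    p = RFParams(delay=30.0)
    stim = make_bar_stimulus(1.0)
    d = bc_drive(p, stim, [400.0, 600.0])
    single = simulate_bc_response(p, stim, rf_x=400.0)
    np.testing.assert_allclose(d[:, 0], single.rf_full, atol=1e-12)
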