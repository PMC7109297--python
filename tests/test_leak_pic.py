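"""Leak fitting, leak subtraction, PIC metrics, RMP and capacitance."""

import numpy as np
import pytest

from mnephys.features import (LeakFit, PICResult, analyze_pic,
                              estimate_capacitance, fit_leak, measure_pic,
                              rmp_from_ramp, subtract_leak)
from mnephys.params import MNParameters, passive_parameters
from mnephys.protocols import (build_capacitance_step_protocol,
                               build_cclamp_step_protocol,
                               build_vclamp_ramp_protocol)
from mnephys.simulate import simulate
from mnephys.sweep import Sweep


def _line_sweep(slope=2.0, intercept=120.0):
    """Synthetic voltage-clamp triangular ramp whose response is an exact
    line I = slope*(V + 60) ... i.e. slope*V + intercept."""
    up = np.linspace(-90, 0, 901)
    cmd = np.concatenate([up, up[::-1][1:]])
    resp = slope * cmd + intercept
    return Sweep(dt=1.0, mode="voltage_clamp", command=cmd, response=resp)


class TestFitLeak:
    def test_exact_line_recovered(self):
        sw = _line_sweep(2.0, 120.0)
        lk = fit_leak(sw)
        assert lk.slope == pytest.approx(2.0, abs=1e-12)
        assert lk.intercept == pytest.approx(120.0, abs=1e-9)
        assert lk.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_passive_cell_within_2pct(self, passive_vc_fast):
        lk = fit_leak(passive_vc_fast)
        assert lk.slope == pytest.approx(20.0, rel=0.02)
        assert lk.input_resistance == pytest.approx(50.0, rel=0.02)

    def test_window_outside_ramp_rejected(self, passive_vc_fast):
        with pytest.raises(ValueError, match="outside"):
            fit_leak(passive_vc_fast, window=(-120.0, -100.0))

    def test_negative_slope_flagged(self):
        sw = _line_sweep(-1.0, 0.0)
        lk = fit_leak(sw)
        assert not lk.ok and np.isnan(lk.input_resistance)

    def test_pic_contaminated_window_has_larger_residual(self, default_cell):
        """A fit window that overlaps NaP activation shows an elevated RMS
        residual compared with the subthreshold default window."""
        prot = build_vclamp_ramp_protocol(-90, 0, 8.0, 8.0, pre_hold=0.2,
                                          post_hold=0.2)
        sw = simulate(default_cell, prot, seed=None)
        good = fit_leak(sw, window=(-85.0, -70.0))
        contaminated = fit_leak(sw, window=(-48.0, -35.0))
        assert contaminated.rms_residual > 5.0 * good.rms_residual


class TestSubtractLeak:
    def test_own_fit_gives_zero(self):
        sw = _line_sweep()
        assert np.allclose(subtract_leak(sw, fit_leak(sw)), 0.0, atol=1e-9)

    def test_zero_fit_is_identity(self):
        sw = _line_sweep()
        zero = LeakFit(0.0, 0.0, (-85.0, -65.0), 0.0)
        np.testing.assert_array_equal(subtract_leak(sw, zero), sw.response)


class TestMeasurePIC:
    def test_worked_geometry_examples(self):
        """Negative-slope range and normalised amplitude arithmetic."""
        r = PICResult(onset_V=-42.9, max_V=-30.0, amplitude=-344.0,
                      negative_slope_range=-30.0 - (-42.9),
                      normalized_amplitude=-344.0 / 282.0)
        assert r.negative_slope_range == pytest.approx(12.9)
        assert r.normalized_amplitude == pytest.approx(-1.22, abs=0.005)

    def test_range_identity_and_invariants(self, default_cell):
        prot = build_vclamp_ramp_protocol(-90, 0, 8.0, 8.0, pre_hold=0.2,
                                          post_hold=0.2)
        sw = simulate(default_cell, prot, seed=3)
        pic = analyze_pic(sw, default_cell.C)
        assert pic.present
        assert pic.amplitude < 0
        assert pic.onset_V <= pic.max_V
        assert pic.negative_slope_range == pytest.approx(
            pic.max_V - pic.onset_V)
        assert pic.normalized_amplitude == pytest.approx(
            pic.amplitude / default_cell.C)

    def test_passive_cell_pic_absent(self, passive_vc_fast):
        pic = analyze_pic(passive_vc_fast, 200.0)
        assert not pic.present
        assert np.isnan(pic.amplitude)

    def test_onset_criterion_uses_noise(self):
        """A synthetic dip shallower than the criterion is not an onset."""
        cmd = np.linspace(-90, 0, 901)
        shallow = -3.0 * np.exp(-0.5 * ((cmd + 40) / 5.0) ** 2)
        r = measure_pic(shallow, cmd, 200.0, dt=1.0, noise_rms=0.0)
        assert not r.present
        deep = 10.0 * shallow
        r2 = measure_pic(deep, cmd, 200.0, dt=1.0, noise_rms=0.0)
        assert r2.present and r2.max_V == pytest.approx(-40.0, abs=1.0)


class TestRMP:
    def test_passive_cell_near_EL(self, passive_cell):
        prot = build_vclamp_ramp_protocol(-90, 0, 8.0, 8.0, pre_hold=0.2,
                                          post_hold=0.2)
        sw = simulate(passive_cell, prot, seed=2)
        assert rmp_from_ramp(sw) == pytest.approx(-60.0, abs=0.5)

    def test_all_positive_response_flags_missing(self):
        up = np.linspace(-90, 0, 901)
        cmd = np.concatenate([up, up[::-1][1:]])
        resp = np.full_like(cmd, 50.0)
        sw = Sweep(dt=1.0, mode="voltage_clamp", command=cmd, response=resp)
        assert rmp_from_ramp(sw) is None

    def test_midpoint_interpolation(self):
        """Samples straddling zero at (-61 mV, +4 pA), (-59 mV, -4 pA)
        interpolate to -60 mV."""
        desc = np.linspace(0, -90, 91)
        resp = 4.0 * (desc + 60.0)  # +4 pA one sample before the crossing
        cmd = np.concatenate([[-90.0], desc])
        resp = np.concatenate([[resp[0]], resp])
        sw = Sweep(dt=1.0, mode="voltage_clamp", command=cmd, response=resp,
                   )
        assert rmp_from_ramp(sw, smooth_ms=1.0) == pytest.approx(-60.0,
                                                                 abs=0.05)


class TestCapacitance:
    def test_passive_recovery_within_5pct(self, passive_cell):
        sw = simulate(passive_cell, build_capacitance_step_protocol(),
                      seed=5)
        assert estimate_capacitance(sw) == pytest.approx(200.0, rel=0.05)

    def test_tau_doubles_with_capacitance(self):
        taus = {}
        for C in (150.0, 300.0):
            p = passive_parameters(C=C, gL=20.0)
            sw = simulate(p, build_capacitance_step_protocol(), seed=None)
            taus[C] = estimate_capacitance(sw)
        assert taus[300.0] / taus[150.0] == pytest.approx(2.0, rel=0.02)

    def test_noiseless_synthetic_exponential_exact(self):
        """tau = 10 ms at g = 20 nS inverts to exactly 200 pF."""
        dt = 0.1
        pre = np.full(1000, -60.0)
        t = np.arange(2500) * dt
        step = -65.0 + 5.0 * np.exp(-t / 10.0)
        post_t = np.arange(1500) * dt
        post = -60.0 - 5.0 * np.exp(-post_t / 10.0)
        V = np.concatenate([pre, step, post])
        cmd = np.concatenate([np.zeros(1000), np.full(2500, -100.0),
                              np.zeros(1500)])
        sw = Sweep(dt=dt, mode="current_clamp", command=cmd, response=V)
        assert estimate_capacitance(sw) == pytest.approx(200.0, rel=1e-4)

    def test_short_pre_epoch_rejected(self, passive_cell):
        prot = build_cclamp_step_protocol(-100.0, duration=0.2,
                                          pre_hold=0.005)
        sw = simulate(passive_cell, prot, seed=None)
        with pytest.raises(ValueError, match="10 ms"):
            estimate_capacitance(sw)
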