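"""Spike detection, F-I ramp metrics, step firing, AHP and sag."""

import math

import numpy as np
import pytest

from mnephys.features import (ahp_metrics, delta_i, detect_spikes,
                              fi_ramp_metrics, sag_metrics,
                              step_firing_metrics)
from mnephys.params import MNParameters
from mnephys.protocols import (build_cclamp_ramp_protocol,
                               build_cclamp_step_protocol)
from mnephys.simulate import simulate
from mnephys.sweep import Sweep


def _cc_sweep(V, dt=0.1, cmd=None):
    if cmd is None:
        cmd = np.zeros_like(V)
    return Sweep(dt=dt, mode="current_clamp", command=cmd, response=V)


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        assert detect_spikes(_cc_sweep(np.full(5000, -60.0))) == []

    def test_triangle_spike_closed_form(self):
        """Isosceles triangle: 50 V/s rise for 2 ms from -60 mV, symmetric
        fall -> rise 50 V/s, fall -50 V/s, half-width = half the base."""
        dt = 0.1
        base = np.full(1000, -60.0)
        up = -60.0 + 50.0 * np.arange(1, 21) * dt  # 50 V/s == 50 mV/ms
        V = np.concatenate([base, up, up[::-1][1:], np.full(1000, -60.0)])
        sw = _cc_sweep(V, dt=dt)
        spikes = detect_spikes(sw)
        assert len(spikes) == 1
        sp = spikes[0]
        assert sp.rate_of_rise == pytest.approx(50.0, rel=0.05)
        assert sp.rate_of_fall == pytest.approx(-50.0, rel=0.05)
        assert sp.threshold_V == pytest.approx(-60.0, abs=2.0)
        # midpoint at half height -> crossing separation = half the base
        assert sp.half_width == pytest.approx(2.0, abs=2 * dt)

    def test_simulated_count_matches_fine_reference(self, default_cell):
        prot = build_cclamp_step_protocol(1000.0, duration=0.4,
                                          pre_hold=0.2, post_hold=0.1)
        coarse = simulate(default_cell, prot, seed=None, dt=0.025)
        fine = simulate(default_cell, prot, seed=None, dt=0.0025)
        n_coarse = len(detect_spikes(coarse))
        n_fine = len(detect_spikes(fine))
        assert n_coarse == n_fine and n_coarse > 5

    def test_threshold_matches_fine_reference_within_1mV(self, default_cell,
                                                         default_cc_ramp):
        prot = build_cclamp_ramp_protocol(900, 3, 3)
        fine = simulate(default_cell, prot, seed=None, dt=0.0025)
        thr_coarse = detect_spikes(default_cc_ramp)[0].threshold_V
        thr_fine = detect_spikes(fine)[0].threshold_V
        assert abs(thr_coarse - thr_fine) < 1.0


class TestFIRamp:
    @pytest.mark.parametrize("i_on,i_off,expected", [
        (459.0, 443.0, -16.0),   # sustained-firing severe pattern
        (627.0, 768.0, 141.0),   # unaffected pattern
    ])
    def test_delta_i_worked_examples(self, i_on, i_off, expected):
        assert delta_i(i_on, i_off) == pytest.approx(expected)

    def test_delta_i_identity_on_simulated_ramp(self, default_cc_ramp):
        fi = fi_ramp_metrics(default_cc_ramp)
        assert fi.ok and fi.n_spikes > 10
        assert fi.delta_I == fi.I_off - fi.I_on
        assert fi.offset_on_descending

    def test_constructed_linear_fi_slope(self):
        """Spike train with frequency = 0.02 * I (Hz, I in pA) recovers an
        F-I slope of 20 Hz/nA."""
        dt = 0.1
        dur_ms = 4000.0
        n = int(dur_ms / dt) + 1
        t = np.arange(n) * dt
        cmd = 1000.0 * t / dur_ms                      # 0 -> 1000 pA ramp
        # spike times such that 1/ISI = 0.02 * I(t) starting at 300 pA
        times = [1200.0]
        while times[-1] < 3600.0:
            I = 1000.0 * times[-1] / dur_ms
            f = 0.02 * I
            times.append(times[-1] + 1000.0 / f)
        V = np.full(n, -60.0)
        for ts in times:
            i = int(ts / dt)
            if i + 10 < n:
                V[i:i + 5] += np.linspace(0, 100, 5)   # fast rise to +40
                V[i + 5:i + 10] += np.linspace(100, 0, 5)[1:].tolist() + [0]
        sw = _cc_sweep(V, dt=dt, cmd=cmd)
        fi = fi_ramp_metrics(sw)
        assert fi.fi_slope == pytest.approx(20.0, rel=0.05)

    def test_spikeless_sweep_flagged(self):
        fi = fi_ramp_metrics(_cc_sweep(np.full(3000, -60.0)))
        assert not fi.ok and math.isnan(fi.I_on)


class TestStepFiring:
    def test_constant_isi_reciprocal(self):
        V = np.full(20000, -60.0)
        cmd = np.zeros_like(V)
        cmd[3000:7500] = 500.0
        for k in range(40):   # spikes every 10 ms, through the whole step
            i = 3200 + k * 100
            V[i:i + 3] = [0.0, 30.0, 0.0]
        sw = _cc_sweep(V, cmd=cmd)
        m = step_firing_metrics([sw])
        assert m.max_instantaneous_Hz == pytest.approx(100.0, rel=0.02)
        assert m.max_steady_state_Hz == pytest.approx(100.0, rel=0.02)
        assert m.block == "none"

    def test_doublet_then_slow(self):
        """One 5 ms ISI doublet then 20 ms ISIs: instantaneous 200 Hz,
        steady-state 50 Hz."""
        V = np.full(30000, -60.0)
        cmd = np.zeros_like(V)
        cmd[3000:25000] = 500.0
        spikes_at = [3100, 3150]
        t = 3150
        while t + 200 < 24800:
            t += 200
            spikes_at.append(t)
        for i in spikes_at:
            V[i:i + 3] = [0.0, 30.0, 0.0]
        m = step_firing_metrics([_cc_sweep(V, cmd=cmd)])
        assert m.max_instantaneous_Hz == pytest.approx(200.0, rel=0.02)
        assert m.max_steady_state_Hz == pytest.approx(50.0, rel=0.02)

    def test_block_flags(self):
        """Silence with depolarised V while the step persists flags
        sustained block; resumed firing flags transient block."""
        def mk(resume):
            V = np.full(30000, -60.0)
            cmd = np.zeros_like(V)
            cmd[3000:25000] = 1000.0
            for k in range(10):
                i = 3100 + k * 100
                V[i:i + 3] = [0.0, 30.0, 0.0]
            V[4200:25000] = -20.0   # depolarised plateau
            if resume:
                for k in range(5):
                    i = 15000 + k * 100
                    V[i:i + 3] = [0.0, 30.0, 0.0]
            return _cc_sweep(V, cmd=cmd)
        assert step_firing_metrics([mk(False)]).block == "sustained"
        assert step_firing_metrics([mk(True)]).block == "transient"

    def test_sham_cell_blocks_at_high_step(self, default_cell):
        prot = build_cclamp_step_protocol(3000.0, duration=0.8,
                                          pre_hold=0.2, post_hold=0.1)
        sw = simulate(default_cell, prot, seed=None)
        m = step_firing_metrics([sw])
        assert m.block == "sustained"


class TestAHP:
    def test_closed_form_exponential(self):
        """V = baseline - 5*exp(-t/50) after the trough: amplitude 5 mV,
        half-decay 50*ln2 ~ 34.7 ms."""
        dt = 0.1
        base = np.full(2000, -60.0)
        spike = np.concatenate([np.linspace(-60, 30, 15),
                                np.linspace(30, -65, 15)[1:]])
        t = np.arange(0, 400, dt)
        ahp = -60.0 - 5.0 * np.exp(-t / 50.0)
        V = np.concatenate([base, spike, ahp])
        amp, half = ahp_metrics(_cc_sweep(V, dt=dt), smooth_ms=dt)
        assert amp == pytest.approx(5.0, abs=0.1)
        assert half == pytest.approx(50.0 * math.log(2), abs=1.5)

    def test_no_undershoot_zero_amplitude(self):
        dt = 0.1
        base = np.full(2000, -60.0)
        spike = np.concatenate([np.linspace(-60, 30, 15),
                                np.linspace(30, -60, 15)[1:]])
        V = np.concatenate([base, spike, np.full(4000, -59.9)])
        amp, half = ahp_metrics(_cc_sweep(V, dt=dt))
        assert amp == 0.0 and math.isnan(half)

    def test_multi_spike_sweep_rejected(self, default_cc_ramp):
        with pytest.raises(ValueError, match="exactly one"):
            ahp_metrics(default_cc_ramp)

    def test_amplitude_increases_with_gAHP(self, protocols):
        amps = []
        for g in (0.5, 1.0):
            p = MNParameters(gAHP=g)
            sw = simulate(p, protocols["ahp_pulse"], seed=None)
            amps.append(ahp_metrics(sw)[0])
        assert amps[1] > amps[0] > 0


class TestSag:
    def test_passive_cell_no_sag(self, passive_cell, protocols):
        sw = simulate(passive_cell, protocols["sag_step"], seed=4)
        amp, ratio, rebound = sag_metrics(sw)
        assert abs(amp) < 0.5
        assert abs(ratio) < 0.02
        assert not rebound

    def test_sag_increases_with_gH(self, protocols):
        amps = []
        for g in (2.5, 6.0):
            p = MNParameters(gH=g, gNaT=0.0)  # no rebound spikes
            sw = simulate(p, protocols["sag_step"], seed=None)
            amps.append(sag_metrics(sw)[0])
        assert amps[1] > amps[0] > 0.5

    def test_ratio_bounded(self, default_cell, protocols):
        sw = simulate(default_cell, protocols["sag_step"], seed=6)
        _, ratio, _ = sag_metrics(sw)
        assert 0.0 <= ratio <= 1.0

    def test_depolarising_step_rejected(self, default_cell):
        prot = build_cclamp_step_protocol(200.0, duration=0.5)
        sw = simulate(default_cell, prot, seed=None)
        with pytest.raises(ValueError, match="hyperpolarising"):
            sag_metrics(sw)
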