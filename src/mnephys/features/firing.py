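"""Firing-pattern metrics: F-I ramps (I_ON / I_OFF / delta-I), current-step
firing rates with depolarisation-block detection, the single-spike
afterhyperpolarisation, and hyperpolarising-step sag.

delta_I = I_OFF - I_ON: positive when firing ceases at a higher current on
the descending ramp than it started on the ascending one; negative delta-I
indicates self-sustained firing supported by a persistent inward current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..sweep import Sweep
from ._util import boxcar, step_epoch
from .spikes import SpikeEvent, detect_spikes

__all__ = ["FIResult", "StepFiring", "delta_i", "fi_ramp_metrics",
           "step_firing_metrics", "ahp_metrics", "sag_metrics"]


def delta_i(i_on: float, i_off: float) -> float:
    """delta_I = I_OFF - I_ON (pA), the firing hysteresis of a current ramp."""
    return i_off - i_on


@dataclass(frozen=True)
class FIResult:
    """Frequency-current metrics of a triangular current-clamp ramp."""
    I_on: float = math.nan        # pA, command current at first spike threshold
    I_off: float = math.nan       # pA, command current at last spike threshold
    delta_I: float = math.nan     # pA, I_off - I_on
    fi_slope: float = math.nan    # Hz/nA, ascending-limb frequency-current gain
    threshold_V: float = math.nan  # mV, first ramp spike threshold
    n_spikes: int = 0
    offset_on_descending: bool = False

    @property
    def ok(self) -> bool:
        return self.n_spikes > 0


def fi_ramp_metrics(sweep: Sweep,
                    spikes: list[SpikeEvent] | None = None) -> FIResult:
    """I_ON, I_OFF, delta-I, F-I slope and threshold from a current ramp.

    With < 2 spikes the slope is NaN; with no spikes all fields are NaN and
    the result is flagged not-ok for QC.  The F-I slope is the least-squares
    slope of instantaneous frequency (1/ISI, attributed to the second spike
    of each interval) versus command current on the ascending limb.
    """
    if sweep.mode != "current_clamp":
        raise ValueError("F-I metrics require a current-clamp ramp")
    if spikes is None:
        spikes = detect_spikes(sweep)
    if len(spikes) == 0:
        return FIResult()
    first, last = spikes[0], spikes[-1]
    t_peak_cmd = sweep.time[int(np.argmax(sweep.command))]
    i_on = first.I_at_threshold
    i_off = last.I_at_threshold
    fi_slope = math.nan
    if len(spikes) >= 3:
        asc = [s for s in spikes if s.t_peak <= t_peak_cmd]
        if len(asc) >= 3:
            tt = np.array([s.t_peak for s in asc])
            isi = np.diff(tt)               # ms
            f = 1000.0 / isi                # Hz
            i_nA = np.array([np.interp(s.t_threshold, sweep.time,
                                       sweep.command)
                             for s in asc[1:]]) / 1000.0
            if len(f) >= 2 and np.ptp(i_nA) > 0:
                fi_slope = float(np.polyfit(i_nA, f, 1)[0])
    return FIResult(I_on=float(i_on), I_off=float(i_off),
                    delta_I=float(i_off - i_on), fi_slope=fi_slope,
                    threshold_V=float(first.threshold_V),
                    n_spikes=len(spikes),
                    offset_on_descending=bool(last.t_peak > t_peak_cmd))


@dataclass(frozen=True)
class StepFiring:
    """Firing metrics across a family of depolarising current steps."""
    max_instantaneous_Hz: float = math.nan
    max_steady_state_Hz: float = math.nan
    block: str = "none"        # none | transient | sustained
    per_sweep: tuple = field(default_factory=tuple)


_BLOCK_MIN_GAP_MS = 150.0   # silent, depolarised period that counts as block


def _sweep_step_metrics(sweep: Sweep, spikes: list[SpikeEvent]):
    on, off = step_epoch(sweep)
    t_on, t_off = on * sweep.dt, off * sweep.dt
    in_step = [s for s in spikes if t_on <= s.t_peak <= t_off]
    inst = steady = math.nan
    block = "none"
    if len(in_step) >= 2:
        tt = np.array([s.t_peak for s in in_step])
        isi = np.diff(tt)
        inst = float(1000.0 / isi.min())
        half = t_on + (t_off - t_on) / 2.0
        late = isi[tt[1:] >= half]
        if len(late) > 0:
            steady = float(np.mean(1000.0 / late))
    if len(in_step) >= 1:
        # depolarisation block: silence while the step persists with V held
        # above the last spike's threshold
        last = in_step[-1]
        tail_start = last.t_peak + 20.0
        if t_off - last.t_peak > _BLOCK_MIN_GAP_MS and tail_start < t_off:
            sel = (sweep.time >= tail_start) & (sweep.time <= t_off)
            if np.mean(sweep.response[sel]) > last.threshold_V:
                block = "sustained"
        if len(in_step) >= 2 and block == "none":
            tt = np.array([s.t_peak for s in in_step])
            isi = np.diff(tt)
            med = np.median(isi)
            for k, gap in enumerate(isi):
                if gap > max(_BLOCK_MIN_GAP_MS, 5 * med):
                    sel = (sweep.time > tt[k] + 20.0) & \
                          (sweep.time < tt[k + 1] - 5.0)
                    if sel.any() and np.mean(sweep.response[sel]) > \
                            in_step[k].threshold_V:
                        block = "transient"
                        break
    return inst, steady, block


def step_firing_metrics(sweeps: list[Sweep],
                        spikes_per_sweep: list[list[SpikeEvent]] | None = None,
                        ) -> StepFiring:
    """Maximum instantaneous and steady-state firing frequency across a step
    family, plus a depolarisation-block flag.

    Instantaneous frequency is the reciprocal of the shortest inter-spike
    interval of a sweep; steady-state frequency averages 1/ISI over the last
    half of the step.  The family block flag is 'transient' if any sweep
    resumes firing after a silent depolarised gap, else 'sustained' if any
    sweep ceases firing while the step persists with the membrane held above
    threshold, else 'none'.
    """
    if len(sweeps) == 0:
        raise ValueError("need at least one step sweep")
    if spikes_per_sweep is None:
        spikes_per_sweep = [detect_spikes(s) for s in sweeps]
    per = [_sweep_step_metrics(sw, sp)
           for sw, sp in zip(sweeps, spikes_per_sweep)]
    insts = [p[0] for p in per if np.isfinite(p[0])]
    steadies = [p[1] for p in per if np.isfinite(p[1])]
    blocks = {p[2] for p in per}
    if "transient" in blocks:
        block = "transient"
    elif "sustained" in blocks:
        block = "sustained"
    else:
        block = "none"
    return StepFiring(
        max_instantaneous_Hz=max(insts) if insts else math.nan,
        max_steady_state_Hz=max(steadies) if steadies else math.nan,
        block=block, per_sweep=tuple(per))


def ahp_metrics(sweep: Sweep,
                spikes: list[SpikeEvent] | None = None,
                smooth_ms: float = 2.0) -> tuple[float, float]:
    """Afterhyperpolarisation amplitude (mV) and half-decay duration (ms)
    from a sweep containing exactly one near-threshold spike.

    Amplitude is the pre-spike baseline minus the post-spike minimum
    (positive when the trajectory undershoots); half-decay is the time from
    the AHP trough until half the amplitude has recovered.  Raises on
    multi-spike sweeps; returns (0, nan) when there is no undershoot.
    """
    if spikes is None:
        spikes = detect_spikes(sweep)
    if len(spikes) != 1:
        raise ValueError(f"AHP needs exactly one spike, got {len(spikes)}")
    sp = spikes[0]
    dt = sweep.dt
    t = sweep.time
    V = boxcar(sweep.response, smooth_ms, dt)
    if t[-1] - sp.t_peak < 200.0:
        raise ValueError("need >= 200 ms of post-spike epoch")
    base_lo = max(0.0, sp.t_threshold - 55.0)
    base_sel = (t >= base_lo) & (t <= sp.t_threshold - 5.0)
    baseline = float(np.mean(V[base_sel]))
    post = (t > sp.t_peak + 2.0)
    idx = np.nonzero(post)[0]
    trough_rel = int(np.argmin(V[idx]))
    i_tr = idx[trough_rel]
    trough = float(V[i_tr])
    amplitude = baseline - trough
    if amplitude <= 0:
        return 0.0, math.nan
    target = trough + amplitude / 2.0
    rec = np.nonzero(V[i_tr:] >= target)[0]
    half_decay = float(rec[0] * dt) if len(rec) else math.nan
    return float(amplitude), half_decay


def sag_metrics(sweep: Sweep, smooth_ms: float = 5.0,
                rebound_criterion_mV: float | None = None,
                ) -> tuple[float, float, bool]:
    """Sag amplitude (mV), sag ratio and rebound flag from a hyperpolarising
    current step.

    sag amplitude = steady-state V (mean of the last 20% of the step) minus
    the peak hyperpolarised V; sag ratio divides by (baseline - peak).  The
    rebound flag is set when the post-step potential overshoots baseline by
    more than the noise criterion (default 3 * pre-step SD + 0.5 mV).
    """
    if sweep.mode != "current_clamp":
        raise ValueError("sag metrics require a current-clamp sweep")
    on, off = step_epoch(sweep)
    if sweep.command[on] >= sweep.command[0]:
        raise ValueError("sag requires a hyperpolarising (negative) step")
    dt = sweep.dt
    V = boxcar(sweep.response, smooth_ms, dt)
    pre = sweep.response[max(0, on - int(100 / dt)):on]
    baseline = float(np.mean(pre))
    seg = V[on:off + 1]
    peak = float(seg.min())
    n20 = max(1, int(0.2 * len(seg)))
    steady = float(np.mean(seg[-n20:]))
    sag_amp = steady - peak
    denom = baseline - peak
    ratio = sag_amp / denom if denom > 0 else math.nan
    if rebound_criterion_mV is None:
        rebound_criterion_mV = 0.5 + 3.0 * float(np.std(pre))
    post = V[off + 1:off + 1 + int(300 / dt)]
    rebound = bool(len(post) and post.max() > baseline + rebound_criterion_mV)
    return float(sag_amp), float(ratio), rebound
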