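"""Action-potential detection and per-spike shape measurement.

Spikes are local maxima with >= 20 mV prominence whose rising phase reaches
dV/dt >= 10 V/s.  The threshold of each spike is the last upward crossing of
dV/dt = 10 V/s before its peak (with mV/ms == V/s at these units).  Rate of
rise/fall are the extrema of the first derivative within the spike window,
and the duration is measured at the midpoint between peak and threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ..sweep import Sweep
from ._util import boxcar

__all__ = ["SpikeEvent", "detect_spikes", "DVDT_THRESHOLD"]

DVDT_THRESHOLD = 10.0     # V/s, threshold-crossing criterion
PEAK_PROMINENCE = 20.0    # mV
MAX_LOOKBACK_MS = 20.0    # threshold search window before each peak
FALL_WINDOW_MS = 10.0     # rate-of-fall search window after each peak


@dataclass(frozen=True)
class SpikeEvent:
    t_threshold: float    # ms, time of the dV/dt = 10 V/s crossing
    t_peak: float         # ms
    threshold_V: float    # mV
    peak_V: float         # mV
    rate_of_rise: float   # V/s, max dV/dt between threshold and peak
    rate_of_fall: float   # V/s, most negative dV/dt after the peak
    half_width: float     # ms, duration at (peak_V + threshold_V) / 2
    I_at_threshold: float  # pA, command current at threshold (ramp sweeps)

    @property
    def height(self) -> float:
        """Spike height above threshold, mV."""
        return self.peak_V - self.threshold_V


def _cross_time(t0: float, t1: float, y0: float, y1: float,
                level: float) -> float:
    if y1 == y0:
        return t0
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def detect_spikes(sweep: Sweep) -> list[SpikeEvent]:
    """Detect action potentials in a current-clamp sweep, time-ordered.

    Returns an empty list when no spike meets the criteria.
    """
    if sweep.mode != "current_clamp":
        raise ValueError("spike detection requires a current-clamp sweep")
    V = sweep.response
    dt = sweep.dt
    t = sweep.time
    dvdt = np.gradient(V, dt)              # mV/ms == V/s
    dvdt_sm = boxcar(dvdt, 3 * dt, dt)     # light smoothing for crossings

    peaks, _ = find_peaks(V, prominence=PEAK_PROMINENCE)
    look = int(round(MAX_LOOKBACK_MS / dt))
    fall_n = int(round(FALL_WINDOW_MS / dt))
    events: list[SpikeEvent] = []
    for ip, p in enumerate(peaks):
        lo = max(0, p - look)
        if ip > 0:
            lo = max(lo, peaks[ip - 1])
        rise_seg = dvdt[lo:p + 1]
        if len(rise_seg) == 0 or rise_seg.max() < DVDT_THRESHOLD:
            continue  # too slow to be a spike
        # last upward crossing of the 10 V/s criterion before the peak
        seg = dvdt_sm[lo:p + 1]
        above = seg >= DVDT_THRESHOLD
        up = np.nonzero(above[1:] & ~above[:-1])[0]
        if len(up) > 0:
            i = lo + up[-1]  # crossing between i and i+1
            t_thr = _cross_time(t[i], t[i + 1], dvdt_sm[i], dvdt_sm[i + 1],
                                DVDT_THRESHOLD)
            thr_V = float(np.interp(t_thr, t, V))
        elif above.all():
            i = lo
            t_thr = t[lo]
            thr_V = float(V[lo])
        else:
            continue
        hi = min(len(V) - 1, p + fall_n)
        if ip < len(peaks) - 1:
            hi = min(hi, peaks[ip + 1])
        rate_rise = float(dvdt[max(lo, i):p + 1].max())
        rate_fall = float(dvdt[p:hi + 1].min()) if hi > p else np.nan
        peak_V = float(V[p])
        mid = 0.5 * (peak_V + thr_V)
        # half-width: crossing of `mid` on the rise and the fall
        rise_i = np.nonzero(V[i:p + 1] >= mid)[0]
        t_up = np.nan
        if len(rise_i) > 0 and rise_i[0] > 0:
            a = i + rise_i[0] - 1
            t_up = _cross_time(t[a], t[a + 1], V[a], V[a + 1], mid)
        elif len(rise_i) > 0:
            t_up = t[i + rise_i[0]]
        fall_i = np.nonzero(V[p:hi + 1] <= mid)[0]
        t_down = np.nan
        if len(fall_i) > 0 and fall_i[0] > 0:
            a = p + fall_i[0] - 1
            t_down = _cross_time(t[a], t[a + 1], V[a], V[a + 1], mid)
        half_width = float(t_down - t_up) if np.isfinite(t_up) and \
            np.isfinite(t_down) else np.nan
        events.append(SpikeEvent(
            t_threshold=float(t_thr), t_peak=float(t[p]),
            threshold_V=thr_V, peak_V=peak_V,
            rate_of_rise=rate_rise, rate_of_fall=rate_fall,
            half_width=half_width,
            I_at_threshold=float(np.interp(t_thr, t, sweep.command))))
    return events
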