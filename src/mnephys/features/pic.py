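"""Persistent inward current (PIC) metrics from leak-subtracted ramps.

The PIC appears as an inward (negative) deviation from the leak line during
a slow depolarising voltage ramp.  Onset is the voltage where the smoothed
leak-subtracted current first drops below a noise-referenced criterion and
stays below it; the PIC maximum is the voltage of the most negative
leak-subtracted current; their difference is the negative-slope range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..sweep import Sweep
from ._util import ascending_limb, boxcar
from .leak import LeakFit, fit_leak, subtract_leak

__all__ = ["PICResult", "measure_pic", "analyze_pic"]

ONSET_BASE_PA = 5.0       # pA, onset criterion floor
ONSET_NOISE_MULT = 3.0    # multiples of pre-ramp RMS noise added to floor
ONSET_HOLD_MS = 20.0      # must stay below criterion at least this long
SMOOTH_MS = 1.0           # boxcar width


@dataclass(frozen=True)
class PICResult:
    """Leak-subtracted PIC metrics for one ramp speed.

    When no onset is detected (``present`` False) the PIC fields are NaN,
    never zero-filled.
    """
    onset_V: float                 # mV
    max_V: float                   # mV at the most negative current
    amplitude: float               # pA (<= 0)
    negative_slope_range: float    # mV, max_V - onset_V
    normalized_amplitude: float    # pA/pF
    ramp_tag: str = ""
    present: bool = True

    def __post_init__(self) -> None:
        if self.present:
            if self.amplitude > 0:
                raise ValueError("PIC amplitude must be <= 0 (inward)")
            if self.onset_V > self.max_V + 1e-9:
                raise ValueError("onset_V must be <= max_V")


def _absent(tag: str) -> PICResult:
    return PICResult(np.nan, np.nan, np.nan, np.nan, np.nan, tag,
                     present=False)


def measure_pic(subtracted: np.ndarray, command: np.ndarray,
                capacitance: float, dt: float, *,
                noise_rms: float = 0.0, search_from: float | None = None,
                ramp_tag: str = "") -> PICResult:
    """Measure PIC metrics on an ascending-limb leak-subtracted signal.

    Parameters
    ----------
    subtracted, command
        Leak-subtracted current (pA) and command voltage (mV) samples of the
        ascending ramp limb (equal length, time-ordered).
    capacitance
        Whole-cell capacitance (pF) used for the normalised amplitude.
    noise_rms
        RMS of the smoothed leak-subtracted signal during the pre-ramp hold;
        enters the onset criterion -(5 pA + 3*noise_rms).
    search_from
        Lowest command voltage considered (defaults to the upper edge of the
        usual leak window, holding + 25 mV).
    """
    subtracted = np.asarray(subtracted, dtype=float)
    command = np.asarray(command, dtype=float)
    if subtracted.shape != command.shape:
        raise ValueError("subtracted and command must have equal length")
    sm = boxcar(subtracted, SMOOTH_MS, dt)
    if search_from is None:
        search_from = command[0] + 25.0
    sel = command >= search_from
    if sel.sum() < 2:
        raise ValueError("no samples above the search voltage")
    smv, cmv = sm[sel], command[sel]

    crit = -(ONSET_BASE_PA + ONSET_NOISE_MULT * noise_rms)
    below = smv < crit
    hold_n = max(1, int(round(ONSET_HOLD_MS / dt)))
    onset_idx = None
    i = 0
    idx = np.nonzero(below)[0]
    for i in idx:
        j = min(i + hold_n, len(below))
        if below[i:j].all() and j - i >= min(hold_n, len(below) - i):
            onset_idx = i
            break
    if onset_idx is None:
        return _absent(ramp_tag)

    imin = onset_idx + int(np.argmin(smv[onset_idx:]))
    amplitude = float(smv[imin])
    onset_V = float(cmv[onset_idx])
    max_V = float(cmv[imin])
    return PICResult(onset_V=onset_V, max_V=max_V, amplitude=amplitude,
                     negative_slope_range=max_V - onset_V,
                     normalized_amplitude=amplitude / capacitance,
                     ramp_tag=ramp_tag, present=True)


def analyze_pic(sweep: Sweep, capacitance: float,
                leak: LeakFit | None = None, ramp_tag: str = "") -> PICResult:
    """Convenience wrapper: leak fit, subtraction, noise estimate and PIC
    measurement on the ascending limb of a voltage-clamp ramp sweep."""
    if leak is None:
        leak = fit_leak(sweep)
    if not leak.ok:
        raise ValueError("leak fit failed QC; cannot measure PIC")
    sub = subtract_leak(sweep, leak)
    asc = ascending_limb(sweep)
    cmd = sweep.command[asc]
    sub_asc = sub[asc]
    # pre-ramp hold: samples at the holding level before the ramp moves
    holding = cmd[0]
    hold_idx = np.nonzero(cmd == holding)[0]
    sm_all = boxcar(sub_asc, SMOOTH_MS, sweep.dt)
    noise_rms = float(np.sqrt(np.mean(sm_all[hold_idx] ** 2))) \
        if len(hold_idx) >= 2 else 0.0
    return measure_pic(sub_asc, cmd, capacitance, sweep.dt,
                       noise_rms=noise_rms, ramp_tag=ramp_tag)
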