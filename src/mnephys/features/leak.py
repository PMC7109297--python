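"""Leak-line fitting, leak subtraction, resting potential and capacitance.

Input resistance comes from the slope of the leak current near the holding
potential on the ascending limb of a voltage-clamp ramp; the resting
membrane potential is read in voltage clamp as the command voltage at which
the injected current crosses 0 pA on the descending ramp.  Capacitance is
estimated from the membrane-charging transient of a small hyperpolarising
current step (C = tau * g_total), replacing the amplifier's whole-cell
compensation readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ..sweep import Sweep
from ._util import ascending_limb, boxcar, descending_limb, step_epoch

__all__ = ["LeakFit", "fit_leak", "subtract_leak", "rmp_from_ramp",
           "estimate_capacitance"]

DEFAULT_WINDOW_OFFSET = (5.0, 25.0)  # mV above holding, per default config


@dataclass(frozen=True)
class LeakFit:
    """Least-squares leak line I = slope*V + intercept over a subthreshold
    window of the ascending voltage-ramp limb."""
    slope: float          # nS (pA/mV)
    intercept: float      # pA
    window: tuple[float, float]  # mV
    rms_residual: float   # pA

    @property
    def ok(self) -> bool:
        """Leak fits with non-positive slope fail QC."""
        return np.isfinite(self.slope) and self.slope > 0

    @property
    def input_resistance(self) -> float:
        """Input resistance in MOhm (1000 / slope[nS])."""
        return 1000.0 / self.slope if self.ok else np.nan


def fit_leak(sweep: Sweep, window: tuple[float, float] | None = None) -> LeakFit:
    """Fit the leak line on the ascending limb of a voltage-clamp ramp.

    ``window`` is the command-voltage interval used for the fit; the default
    is holding+5 to holding+25 mV, which precedes PIC activation.
    """
    if sweep.mode != "voltage_clamp":
        raise ValueError("leak fit requires a voltage-clamp sweep")
    asc = ascending_limb(sweep)
    cmd = sweep.command[asc]
    resp = sweep.response[asc]
    if window is None:
        holding = cmd[0]
        window = (holding + DEFAULT_WINDOW_OFFSET[0],
                  holding + DEFAULT_WINDOW_OFFSET[1])
    lo, hi = window
    if not lo < hi:
        raise ValueError("window low must be < high")
    if lo < cmd.min() - 1e-9 or hi > cmd.max() + 1e-9:
        raise ValueError(
            f"fit window [{lo}, {hi}] mV outside ascending ramp range "
            f"[{cmd.min():.1f}, {cmd.max():.1f}] mV")
    sel = (cmd >= lo) & (cmd <= hi)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 samples in the leak-fit window")
    slope, intercept = np.polyfit(cmd[sel], resp[sel], 1)
    resid = resp[sel] - (slope * cmd[sel] + intercept)
    return LeakFit(float(slope), float(intercept), (float(lo), float(hi)),
                   float(np.sqrt(np.mean(resid ** 2))))


def subtract_leak(sweep: Sweep, leak: LeakFit) -> np.ndarray:
    """Sample-wise leak-subtracted current: response - (slope*command + b)."""
    if sweep.mode != "voltage_clamp":
        raise ValueError("leak subtraction requires a voltage-clamp sweep")
    return sweep.response - (leak.slope * sweep.command + leak.intercept)


def rmp_from_ramp(sweep: Sweep, smooth_ms: float = 2.0) -> float | None:
    """Resting membrane potential: command voltage at the last positive-to-
    negative zero crossing of the (smoothed) injected current on the
    descending voltage-ramp limb; linear interpolation between samples.

    Returns ``None`` (QC flag upstream) when the current never crosses zero.
    """
    if sweep.mode != "voltage_clamp":
        raise ValueError("RMP-from-ramp requires a voltage-clamp sweep")
    desc = descending_limb(sweep)
    cmd = sweep.command[desc]
    resp = boxcar(sweep.response[desc], smooth_ms, sweep.dt)
    # restrict to the strictly descending ramp (exclude trailing hold)
    dcmd = np.diff(cmd)
    moving = np.nonzero(dcmd < 0)[0]
    if len(moving) == 0:
        return None
    end = moving[-1] + 1
    cmd, resp = cmd[:end + 1], resp[:end + 1]
    sign = np.sign(resp)
    crossings = np.nonzero((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    if len(crossings) == 0:
        return None
    i = crossings[-1]
    frac = resp[i] / (resp[i] - resp[i + 1])
    return float(cmd[i] + frac * (cmd[i + 1] - cmd[i]))


def estimate_capacitance(sweep: Sweep) -> float | None:
    """Whole-cell capacitance from the charging transient of a small
    hyperpolarising current step.

    A single exponential V(t) = V_ss + (V_0 - V_ss) exp(-t/tau) is fitted to
    the membrane potential during the step; the total conductance is the
    steady-state slope g = |dI| / |dV_ss| and C = tau * g.  Returns ``None``
    if the fit does not converge.
    """
    if sweep.mode != "current_clamp":
        raise ValueError("capacitance estimate requires a current-clamp step")
    on, off = step_epoch(sweep)
    dt = sweep.dt
    if on * dt < 10.0 or (len(sweep.command) - off) * dt < 10.0:
        raise ValueError("step needs >= 10 ms pre/post epochs")
    dI = sweep.command[on] - sweep.command[0]
    if dI == 0:
        raise ValueError("zero-amplitude step")
    v = sweep.response
    v0 = float(np.mean(v[max(0, on - int(50 / dt)):on]))

    def fit_tau(seg: np.ndarray) -> tuple[float, float] | None:
        """Fit V(t) = v_ss + dv*exp(-t/tau); return (v_ss, tau)."""
        t = np.arange(len(seg)) * dt
        v_ss_guess = float(np.mean(seg[-max(1, len(seg) // 5):]))
        tau_guess = max(dt, 0.2 * t[-1])

        def model(t, v_ss, dv, tau):
            return v_ss + dv * np.exp(-t / tau)

        try:
            popt, _ = curve_fit(
                model, t, seg,
                p0=(v_ss_guess, seg[0] - v_ss_guess, tau_guess),
                bounds=([-150.0, -100.0, dt / 2], [50.0, 100.0, 10 * t[-1]]),
                maxfev=10000)
        except (RuntimeError, ValueError):
            return None
        v_ss, _, tau = popt
        if not (np.isfinite(tau) and tau > 0):
            return None
        return float(v_ss), float(tau)

    on_fit = fit_tau(v[on:off + 1])
    if on_fit is None:
        return None
    v_ss, tau_on = on_fit
    dV = v_ss - v0
    if dV == 0:
        return None
    g_total = abs(dI / dV)  # nS
    estimates = [tau_on * g_total]
    # the recovery transient after step offset carries the same tau;
    # average the two fits to halve the noise on the estimate
    off_fit = fit_tau(v[off + 1:])
    if off_fit is not None:
        estimates.append(off_fit[1] * g_total)
    return float(np.mean(estimates))  # ms * nS = pF
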