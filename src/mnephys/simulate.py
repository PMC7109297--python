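"""Single-compartment conductance-based motoneuron simulator.

The membrane equation is

    C dV/dt = I_cmd - [I_L + I_NaT + I_Kdr + I_NaP + I_CaL + I_H + I_AHP]

with Hodgkin-Huxley-style currents:

    I_L    = gL (V - EL)
    I_NaT  = gNaT m_inf(V)^3 h (V - ENa)      transient Na+, m instantaneous
    I_Kdr  = gKdr n^4 (V - EK)                delayed rectifier
    I_NaP  = gNaP mp_inf(V) hp (V - ENa)      persistent Na+; hp inactivates
                                              slowly (tau_inact_NaP, may be inf)
    I_CaL  = gCaL mc (V - ECa)                L-type Ca2+, slow activation,
                                              non-inactivating
    I_H    = gH r (V - EH)                    hyperpolarisation-activated (sag)
    I_AHP  = gAHP z (V - EK)                  spike-triggered adaptation;
                                              z += 1 per spike, decays tau_AHP

Voltage clamp forces V to the command and records the injected current
I_inj = C dV_cmd/dt + sum(I_ionic); current clamp integrates V and records it.
Integration uses a fixed-step explicit midpoint (RK2) scheme, default step
0.025 ms, with gates updated alongside V.  Emitted sweeps are decimated to a
10 kHz acquisition grid by default and may carry additive Gaussian recording
noise on the response.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import (MNParameters, KDR_TAU_N, NAT_TAU_H_MAX, NAT_TAU_H_MIN)
from .protocols import ProtocolSpec
from .sweep import Sweep, SweepMeta

__all__ = ["simulate", "ionic_current_ss", "resting_potential",
           "SimulationError", "DEFAULT_DT", "DEFAULT_SAMPLE_DT",
           "DEFAULT_NOISE_SD"]

DEFAULT_DT = 0.025          # ms, integration step
DEFAULT_SAMPLE_DT = 0.1     # ms, emitted sampling interval (10 kHz)
DEFAULT_NOISE_SD = {"voltage_clamp": 5.0,   # pA
                    "current_clamp": 0.3}   # mV
_V_BLOWUP = 500.0           # mV, |V| beyond this aborts integration
_SPIKE_CROSS_V = 0.0        # mV, upward crossing increments adaptation

# packed parameter vector layout (see _pack)
_C, _GL, _EL = 0, 1, 2
_GNAT, _VM, _KM, _VH, _KH = 3, 4, 5, 6, 7
_GKDR, _VN, _KN = 8, 9, 10
_GNAP, _VMP, _KMP, _TAUHP, _VHP, _KHP = 11, 12, 13, 14, 15, 16
_GCAL, _VMC, _KMC, _TAUMC = 17, 18, 19, 20
_GH, _VR, _KR, _TAUR = 21, 22, 23, 24
_GAHP, _TAUZ = 25, 26
_ENA, _EK, _ECA, _EH = 27, 28, 29, 30
_TAUN, _TAUHMIN, _TAUHMAX = 31, 32, 33


class SimulationError(RuntimeError):
    """Numerical failure during integration (e.g. voltage blow-up)."""


def _pack(p: MNParameters) -> np.ndarray:
    return np.array([
        p.C, p.gL, p.EL,
        p.gNaT, p.V_half_mNaT, p.k_mNaT, p.V_half_hNaT, p.k_hNaT,
        p.gKdr, p.V_half_Kdr, p.k_Kdr,
        p.gNaP, p.V_half_NaP, p.k_NaP, p.tau_inact_NaP,
        p.V_half_inact_NaP, p.k_inact_NaP,
        p.gCaL, p.V_half_CaL, p.k_CaL, p.tau_CaL,
        p.gH, p.V_half_H, p.k_H, p.tau_H,
        p.gAHP, p.tau_AHP,
        p.ENa, p.EK, p.ECa, p.EH,
        KDR_TAU_N, NAT_TAU_H_MIN, NAT_TAU_H_MAX,
    ])


@njit(cache=True, fastmath=True)
def _ionic(V, h, n, hp, mc, r, z, pr):
    m_inf = 1.0 / (1.0 + math.exp(-(V - pr[_VM]) / pr[_KM]))
    mp_inf = 1.0 / (1.0 + math.exp(-(V - pr[_VMP]) / pr[_KMP]))
    I = pr[_GL] * (V - pr[_EL])
    I += pr[_GNAT] * m_inf * m_inf * m_inf * h * (V - pr[_ENA])
    I += pr[_GKDR] * n * n * n * n * (V - pr[_EK])
    I += pr[_GNAP] * mp_inf * hp * (V - pr[_ENA])
    I += pr[_GCAL] * mc * (V - pr[_ECA])
    I += pr[_GH] * r * (V - pr[_EH])
    I += pr[_GAHP] * z * (V - pr[_EK])
    return I


@njit(cache=True, fastmath=True)
def _gate_derivs(V, h, n, hp, mc, r, z, pr):
    h_inf = 1.0 / (1.0 + math.exp((V - pr[_VH]) / pr[_KH]))
    n_inf = 1.0 / (1.0 + math.exp(-(V - pr[_VN]) / pr[_KN]))
    hp_inf = 1.0 / (1.0 + math.exp((V - pr[_VHP]) / pr[_KHP]))
    mc_inf = 1.0 / (1.0 + math.exp(-(V - pr[_VMC]) / pr[_KMC]))
    r_inf = 1.0 / (1.0 + math.exp((V - pr[_VR]) / pr[_KR]))
    u = (V - pr[_VH]) / 15.0
    tau_h = pr[_TAUHMIN] + (pr[_TAUHMAX] - pr[_TAUHMIN]) * math.exp(-u * u)
    dh = (h_inf - h) / tau_h
    dn = (n_inf - n) / pr[_TAUN]
    dhp = 0.0 if np.isinf(pr[_TAUHP]) else (hp_inf - hp) / pr[_TAUHP]
    dmc = (mc_inf - mc) / pr[_TAUMC]
    dr = (r_inf - r) / pr[_TAUR]
    dz = -z / pr[_TAUZ]
    return dh, dn, dhp, dmc, dr, dz


@njit(cache=True, fastmath=True)
def _integrate(cmd, dcmd, dt, vclamp, pr, y0, stride, out):
    """RK2 (explicit midpoint) integration; records every stride-th sample
    into ``out``.  Returns 0 on success, 1 on voltage blow-up."""
    V, h, n, hp, mc, r, z = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5], y0[6]
    n_steps = cmd.shape[0]
    j = 0
    for i in range(n_steps):
        if vclamp:
            V = cmd[i]
        if i % stride == 0:
            if vclamp:
                out[j] = pr[_C] * dcmd[i] + _ionic(V, h, n, hp, mc, r, z, pr)
            else:
                out[j] = V
            j += 1
        if i == n_steps - 1:
            break
        dh1, dn1, dhp1, dmc1, dr1, dz1 = _gate_derivs(
            V, h, n, hp, mc, r, z, pr)
        if vclamp:
            Vm = 0.5 * (cmd[i] + cmd[i + 1])
        else:
            I1 = _ionic(V, h, n, hp, mc, r, z, pr)
            dV1 = (cmd[i] - I1) / pr[_C]
            Vm = V + 0.5 * dt * dV1
        hm = h + 0.5 * dt * dh1
        nm = n + 0.5 * dt * dn1
        hpm = hp + 0.5 * dt * dhp1
        mcm = mc + 0.5 * dt * dmc1
        rm = r + 0.5 * dt * dr1
        zm = z + 0.5 * dt * dz1
        dh2, dn2, dhp2, dmc2, dr2, dz2 = _gate_derivs(
            Vm, hm, nm, hpm, mcm, rm, zm, pr)
        if not vclamp:
            Icm = 0.5 * (cmd[i] + cmd[i + 1])
            I2 = _ionic(Vm, hm, nm, hpm, mcm, rm, zm, pr)
            Vnew = V + dt * (Icm - I2) / pr[_C]
            # spike-triggered adaptation increment on upward 0 mV crossing
            if V < _SPIKE_CROSS_V and Vnew >= _SPIKE_CROSS_V:
                z += 1.0
            V = Vnew
            if not (-_V_BLOWUP < V < _V_BLOWUP):  # catches NaN too
                return 1
        h += dt * dh2
        n += dt * dn2
        hp += dt * dhp2
        mc += dt * dmc2
        r += dt * dr2
        z += dt * dz2
    return 0


def _sigmoid_up(V, half, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) - half) / k))


def _sigmoid_down(V, half, k):
    return 1.0 / (1.0 + np.exp((np.asarray(V, dtype=float) - half) / k))


def ionic_current_ss(p: MNParameters, V, hp: float | np.ndarray | None = None,
                     z: float = 0.0):
    """Steady-state total ionic current (pA) at voltage ``V`` (mV).

    All gates sit at their voltage-dependent steady states except NaP
    inactivation, which defaults to hp_inf(V) for finite ``tau_inact_NaP``
    and to 1 when the channel does not inactivate; pass ``hp`` to override.
    This is the analytic quasi-steady-state I-V used as the oracle for slow
    voltage ramps.
    """
    V = np.asarray(V, dtype=float)
    if hp is None:
        hp = 1.0 if math.isinf(p.tau_inact_NaP) else \
            _sigmoid_down(V, p.V_half_inact_NaP, p.k_inact_NaP)
    I = p.gL * (V - p.EL)
    I = I + p.gNaT * _sigmoid_up(V, p.V_half_mNaT, p.k_mNaT) ** 3 * \
        _sigmoid_down(V, p.V_half_hNaT, p.k_hNaT) * (V - p.ENa)
    I = I + p.gKdr * _sigmoid_up(V, p.V_half_Kdr, p.k_Kdr) ** 4 * (V - p.EK)
    I = I + p.gNaP * _sigmoid_up(V, p.V_half_NaP, p.k_NaP) * hp * (V - p.ENa)
    I = I + p.gCaL * _sigmoid_up(V, p.V_half_CaL, p.k_CaL) * (V - p.ECa)
    I = I + p.gH * _sigmoid_down(V, p.V_half_H, p.k_H) * (V - p.EH)
    I = I + p.gAHP * z * (V - p.EK)
    return I


def resting_potential(p: MNParameters, I_hold: float = 0.0) -> float:
    """Most hyperpolarised steady state of C dV/dt = I_hold - I_ss(V)."""
    from scipy.optimize import brentq

    grid = np.linspace(-120.0, -20.0, 2001)
    f = I_hold - ionic_current_ss(p, grid)
    sign = np.sign(f)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if len(crossings) == 0:
        raise SimulationError("no resting potential found in [-120, -20] mV")
    i = crossings[0]
    return brentq(lambda v: I_hold - float(ionic_current_ss(p, v)),
                  grid[i], grid[i + 1], xtol=1e-10)


def _initial_state(p: MNParameters, protocol: ProtocolSpec,
                   cmd0: float) -> np.ndarray:
    if protocol.mode == "voltage_clamp":
        V0 = cmd0
    else:
        V0 = resting_potential(p, I_hold=cmd0)
    hp0 = 1.0 if math.isinf(p.tau_inact_NaP) else \
        float(_sigmoid_down(V0, p.V_half_inact_NaP, p.k_inact_NaP))
    return np.array([
        V0,
        float(_sigmoid_down(V0, p.V_half_hNaT, p.k_hNaT)),
        float(_sigmoid_up(V0, p.V_half_Kdr, p.k_Kdr)),
        hp0,
        float(_sigmoid_up(V0, p.V_half_CaL, p.k_CaL)),
        float(_sigmoid_down(V0, p.V_half_H, p.k_H)),
        0.0,
    ])


def simulate(params: MNParameters, protocol: ProtocolSpec,
             dt: float = DEFAULT_DT, seed: int | None = None, *,
             sample_dt: float = DEFAULT_SAMPLE_DT,
             noise_sd: float | None = None,
             meta: SweepMeta | None = None) -> Sweep:
    """Run one protocol on one model cell and return the recorded Sweep.

    Parameters
    ----------
    dt
        Integration step in ms (default 0.025).
    seed
        Seed for the additive Gaussian recording noise.  ``None`` disables
        noise; with a seed, output is fully deterministic.
    sample_dt
        Emitted sample interval in ms (default 0.1 = 10 kHz); must be an
        integer multiple of ``dt``.
    noise_sd
        Recording-noise SD on the response (pA in voltage clamp, mV in
        current clamp); defaults to 5 pA / 0.3 mV when a seed is given.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    stride = int(round(sample_dt / dt))
    if stride < 1 or abs(stride * dt - sample_dt) > 1e-9:
        raise ValueError("sample_dt must be an integer multiple of dt")
    cmd, dcmd = protocol.sample(dt)
    pr = _pack(params)
    y0 = _initial_state(params, protocol, cmd[0])
    n_out = (len(cmd) - 1) // stride + 1
    out = np.empty(n_out)
    vclamp = protocol.mode == "voltage_clamp"
    status = _integrate(cmd, dcmd, dt, vclamp, pr, y0, stride, out)
    if status != 0:
        raise SimulationError(
            f"voltage blow-up (|V| > {_V_BLOWUP:g} mV) integrating "
            f"protocol {protocol.protocol_id!r}; reduce dt or check parameters")
    if seed is not None:
        sd = DEFAULT_NOISE_SD[protocol.mode] if noise_sd is None else noise_sd
        if sd > 0:
            rng = np.random.default_rng(seed)
            out = out + rng.normal(0.0, sd, size=out.shape)
    if meta is None:
        meta = SweepMeta(protocol_id=protocol.protocol_id,
                         seed=-1 if seed is None else seed)
    return Sweep(dt=sample_dt, mode=protocol.mode,
                 command=cmd[::stride].copy(), response=out, meta=meta)
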