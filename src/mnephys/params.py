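"""Biophysical parameters of the single-compartment motoneuron model.

Units throughout the package: capacitance pF, conductance nS, voltage mV,
current pA, time ms.  With these units ``C dV/dt`` (pF * mV/ms) and ``g*(V-E)``
(nS * mV) are both in pA, so no conversion factors appear in the equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = ["MNParameters", "passive_parameters"]

# Fixed kinetic constants (not varied across cells).
NAT_TAU_H_MIN = 0.8   # ms, transient Na+ inactivation tau floor
NAT_TAU_H_MAX = 10.0  # ms, peak of the bell-shaped tau_h near V_half_hNaT
KDR_TAU_N = 4.0       # ms, delayed-rectifier activation tau


@dataclass(frozen=True)
class MNParameters:
    """Conductances, reversals and kinetics for one model motoneuron.

    Defaults describe a neonatal sham-control cell: input resistance
    ~55 MOhm, rest near -60 mV, a persistent inward current of a few
    hundred pA carried by persistent Na+ (fast activation, slow
    inactivation) and L-type Ca2+ (slow activation, non-inactivating).
    """

    C: float = 190.0            # pF, whole-cell capacitance
    gL: float = 18.0            # nS, leak conductance (1/input resistance)
    EL: float = -62.0           # mV, leak reversal (sets rest)
    gNaT: float = 1600.0        # nS, transient Na+ (spike upstroke)
    V_half_mNaT: float = -33.0  # mV, NaT activation half-voltage (m^3, instant)
    k_mNaT: float = 5.0         # mV
    V_half_hNaT: float = -48.0  # mV, NaT fast-inactivation half-voltage
    k_hNaT: float = 4.5         # mV (h falls with depolarisation)
    gKdr: float = 1400.0         # nS, delayed-rectifier K+ (repolarisation)
    V_half_Kdr: float = -28.0   # mV, Kdr activation half-voltage (n^4)
    k_Kdr: float = 6.0          # mV
    gNaP: float = 6.0           # nS, persistent Na+ (fast PIC component)
    V_half_NaP: float = -43.0   # mV, NaP activation half-voltage
    k_NaP: float = 5.0          # mV, NaP activation slope
    tau_inact_NaP: float = 150.0  # ms, NaP slow inactivation (inf = none)
    V_half_inact_NaP: float = -45.0  # mV, NaP inactivation half-voltage
    k_inact_NaP: float = 7.0    # mV
    gCaL: float = 0.9           # nS, L-type Ca2+ (slow PIC component)
    V_half_CaL: float = -30.0   # mV
    k_CaL: float = 5.0          # mV
    tau_CaL: float = 100.0       # ms, CaL activation time constant
    gH: float = 2.5             # nS, hyperpolarisation-activated (sag)
    V_half_H: float = -90.0     # mV
    k_H: float = 6.0            # mV (activates with hyperpolarisation)
    tau_H: float = 250.0        # ms
    gAHP: float = 0.5           # nS per spike, adaptation conductance
    tau_AHP: float = 1000.0      # ms, AHP decay
    ENa: float = 50.0           # mV
    EK: float = -88.0           # mV
    ECa: float = 60.0           # mV
    EH: float = -35.0           # mV

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"capacitance must be positive, got {self.C}")
        for name in ("gL", "gNaT", "gKdr", "gNaP", "gCaL", "gH", "gAHP"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name in ("tau_inact_NaP", "tau_CaL", "tau_H", "tau_AHP"):
            v = getattr(self, name)
            if not v > 0:  # inf allowed, NaN and <=0 rejected
                raise ValueError(f"time constant {name} must be > 0, got {v}")
        for name in ("k_NaP", "k_CaL", "k_H", "k_mNaT", "k_hNaT", "k_Kdr",
                     "k_inact_NaP"):
            if getattr(self, name) == 0:
                raise ValueError(f"slope factor {name} must be nonzero")
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if f_.name != "tau_inact_NaP" and not math.isfinite(v):
                raise ValueError(f"{f_.name} must be finite, got {v}")

    def replace(self, **changes: float) -> "MNParameters":
        return replace(self, **changes)


def passive_parameters(C: float = 190.0, gL: float = 18.0,
                       EL: float = -62.0) -> MNParameters:
    """A cell with every voltage-gated conductance removed (pure RC leak)."""
    return MNParameters(C=C, gL=gL, EL=EL, gNaT=0.0, gKdr=0.0, gNaP=0.0,
                        gCaL=0.0, gH=0.0, gAHP=0.0)
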