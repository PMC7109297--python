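"""Seeded synthetic cohort generation.

A cohort mirrors the experimental design: four injury groups (sham,
HI-unaffected, HI-mild, HI-severe) of neonatal (P0-P5) spinal motoneurons,
each cell drawn from group-specific parameter distributions and run through
a shared protocol battery.  Group shifts are chosen so the severe group
reproduces the directions of the injured phenotype: depolarised resting
potential (~+8 mV), ~45% larger capacitance (with spike conductances scaled
to keep channel density constant), delayed/reduced persistent-Na+ slow
inactivation (longer tau and a +9 mV shifted inactivation curve), a larger
and more depolarised L-type Ca2+ conductance, and weaker spike-triggered
adaptation.  Together these let the sustained inward current offset
adaptation at firing offset and shrink delta-I sharply relative to sham.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np

from .params import MNParameters
from .protocols import (ProtocolSpec, build_capacitance_step_protocol,
                        build_cclamp_ramp_protocol, build_cclamp_step_protocol,
                        build_vclamp_ramp_protocol)
from .simulate import DEFAULT_DT, DEFAULT_NOISE_SD, simulate
from .sweep import REGIONS, Sweep, SweepMeta

__all__ = ["ParamDist", "GroupSpec", "CohortSpec", "CellRecord",
           "default_cohort_spec", "default_protocol_set", "generate_cohort",
           "draw_parameters", "severe_shift", "mild_shift"]

_MAX_REJECT = 1000  # bounded rejection sampling per parameter


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal distribution for one MNParameters field."""
    mean: float
    sd: float = 0.0
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.low <= self.mean <= self.high:
            raise ValueError(f"mean {self.mean} outside bounds "
                             f"[{self.low}, {self.high}]")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0 or not math.isfinite(self.mean):
            return self.mean
        for _ in range(_MAX_REJECT):
            x = rng.normal(self.mean, self.sd)
            if self.low <= x <= self.high:
                return x
        raise RuntimeError(
            f"rejection sampling failed for ParamDist(mean={self.mean}, "
            f"sd={self.sd}, bounds=[{self.low}, {self.high}])")


def _rel(mean: float, rel_sd: float = 0.12, lo_frac: float = 0.55,
         hi_frac: float = 1.6) -> ParamDist:
    """Conductance-style distribution: relative SD, bounded multiples."""
    return ParamDist(mean, abs(mean) * rel_sd, mean * lo_frac, mean * hi_frac)


def sham_distributions() -> dict[str, ParamDist]:
    """Per-field distributions of the sham (control) group.

    Means are the MNParameters defaults; SDs give realistic between-cell
    variability (relative ~12-15% for conductances, a few mV for reversal
    and half-activation voltages).
    """
    d = MNParameters()
    out = {
        "C": _rel(d.C, 0.12, 0.6, 1.5),
        "gL": _rel(d.gL, 0.12),
        "EL": ParamDist(d.EL, 2.5, d.EL - 7.0, d.EL + 7.0),
        "gNaP": _rel(d.gNaP, 0.12),
        "gCaL": _rel(d.gCaL, 0.15),
        "gH": _rel(d.gH, 0.20),
        "gAHP": _rel(d.gAHP, 0.12),
        "V_half_NaP": ParamDist(d.V_half_NaP, 1.0, d.V_half_NaP - 3,
                                d.V_half_NaP + 3),
        "V_half_CaL": ParamDist(d.V_half_CaL, 1.0, d.V_half_CaL - 3,
                                d.V_half_CaL + 3),
        "tau_inact_NaP": _rel(d.tau_inact_NaP, 0.15),
        "tau_CaL": _rel(d.tau_CaL, 0.15),
        "tau_AHP": _rel(d.tau_AHP, 0.10),
        "tau_H": _rel(d.tau_H, 0.15),
    }
    return out


def severe_shift() -> dict[str, ParamDist]:
    """HI-severe distribution overrides (see module docstring)."""
    return {
        "C": _rel(275.0, 0.10, 0.75, 1.3),
        "EL": ParamDist(-54.0, 1.2, -57.0, -51.5),
        "tau_inact_NaP": _rel(6000.0, 0.15),
        "V_half_inact_NaP": ParamDist(-36.0, 0.75, -38.0, -34.0),
        "gNaP": _rel(5.5, 0.08),
        "gCaL": _rel(6.0, 0.15),
        "V_half_CaL": ParamDist(-25.0, 1.0, -28.0, -22.0),
        "V_half_NaP": ParamDist(-38.0, 0.7, -40.0, -36.5),
        "gAHP": _rel(0.15, 0.12),
    }


def mild_shift() -> dict[str, ParamDist]:
    """HI-mild distribution overrides: roughly halfway shifts."""
    return {
        "C": _rel(220.0, 0.12, 0.6, 1.5),
        "EL": ParamDist(-58.5, 2.0, -63.0, -54.0),
        "tau_inact_NaP": _rel(1500.0, 0.15),
        "V_half_inact_NaP": ParamDist(-40.0, 1.0, -43.0, -37.0),
        "gCaL": _rel(3.0, 0.15),
        "V_half_CaL": ParamDist(-28.0, 1.0, -31.0, -25.0),
        "V_half_NaP": ParamDist(-40.5, 1.0, -43.5, -37.5),
        "gAHP": _rel(0.3, 0.12),
    }


@dataclass(frozen=True)
class GroupSpec:
    """Cell count and parameter distributions for one injury group."""
    n: int
    distributions: Mapping[str, ParamDist]
    noise_sd_vc: float = DEFAULT_NOISE_SD["voltage_clamp"]
    noise_sd_cc: float = DEFAULT_NOISE_SD["current_clamp"]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group needs n >= 1 cells")
        if self.noise_sd_vc < 0 or self.noise_sd_cc < 0:
            raise ValueError("noise SDs must be >= 0")
        valid = {f.name for f in dc_fields(MNParameters)}
        for k in self.distributions:
            if k not in valid:
                raise ValueError(f"unknown MNParameters field {k!r}")


@dataclass(frozen=True)
class CohortSpec:
    groups: Mapping[str, GroupSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def default_cohort_spec(seed: int = 0,
                        n_per_group: Mapping[str, int] | None = None,
                        ) -> CohortSpec:
    """The packaged default cohort: group sizes 9/12/10/8 and the
    sham/mild/severe parameter shifts described in the module docstring."""
    if n_per_group is None:
        n_per_group = {"sham": 9, "HI_unaffected": 12,
                       "HI_mild": 10, "HI_severe": 8}
    sham = sham_distributions()
    per_group = {
        "sham": sham,
        "HI_unaffected": dict(sham),
        "HI_mild": {**sham, **mild_shift()},
        "HI_severe": {**sham, **severe_shift()},
    }
    groups = {g: GroupSpec(n=n_per_group[g], distributions=per_group[g])
              for g in n_per_group}
    return CohortSpec(groups=groups, seed=seed)


def default_protocol_set() -> list[ProtocolSpec]:
    """The full protocol battery every cohort cell is run through."""
    return [
        build_vclamp_ramp_protocol(-90, 0, 2.5, 2.5, protocol_id="vc_ramp_5s"),
        build_vclamp_ramp_protocol(-90, 0, 8.0, 8.0, protocol_id="vc_ramp_16s"),
        build_capacitance_step_protocol(),
        build_cclamp_ramp_protocol(900, 3, 3, protocol_id="cc_ramp"),
        build_cclamp_step_protocol(1000, 1.0, protocol_id="cc_step_1000"),
        build_cclamp_step_protocol(1600, 1.0, protocol_id="cc_step_1600"),
        build_cclamp_step_protocol(2200, 1.0, protocol_id="cc_step_2200"),
        build_cclamp_step_protocol(3000, 1.0, protocol_id="cc_step_3000"),
        # brief strong pulse elicits exactly one spike for AHP measurement
        build_cclamp_step_protocol(2000, 0.005, pre_hold=0.2, post_hold=0.5,
                                   protocol_id="ahp_pulse"),
        build_cclamp_step_protocol(-1000, 1.0, pre_hold=0.3, post_hold=0.6,
                                   protocol_id="sag_step"),
    ]


# gNaT/gKdr scale with capacitance (constant channel density) so larger
# cells keep spiking; small lognormal-ish jitter on top.
_DENSITY_JITTER = 0.05


def draw_parameters(dists: Mapping[str, ParamDist],
                    rng: np.random.Generator) -> MNParameters:
    """Draw one cell's MNParameters from per-field distributions."""
    base = MNParameters()
    values = {name: dist.draw(rng) for name, dist in dists.items()}
    C = values.get("C", base.C)
    scale = C / base.C
    for g in ("gNaT", "gKdr"):
        if g not in values:
            jit = 1.0 + _DENSITY_JITTER * rng.standard_normal()
            values[g] = getattr(base, g) * scale * max(jit, 0.5)
    return base.replace(**values)


@dataclass
class CellRecord:
    """All sweeps of one cohort cell plus its ground-truth parameters."""
    cell_id: str
    group: str
    age: str
    region: str
    params: MNParameters
    sweeps: dict[str, Sweep] = field(default_factory=dict)


def generate_cohort(spec: CohortSpec,
                    protocol_set: Sequence[ProtocolSpec] | None = None,
                    dt: float = DEFAULT_DT,
                    progress: bool = False) -> list[CellRecord]:
    """Simulate every cell of the cohort through every protocol.

    Fully deterministic for a given (spec, protocol_set, dt): per-cell seeds
    derive from ``spec.seed`` via ``numpy.random.SeedSequence`` spawning.
    """
    if protocol_set is None:
        protocol_set = default_protocol_set()
    cells: list[CellRecord] = []
    idx = 0
    for group in spec.groups:
        gspec = spec.groups[group]
        for j in range(gspec.n):
            ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(idx,))
            rng = np.random.default_rng(ss)
            params = draw_parameters(gspec.distributions, rng)
            age = f"P{rng.integers(0, 6)}"
            region = rng.choice(REGIONS, p=[0.4, 0.1, 0.4, 0.1])
            cell_id = f"{group}_{j:03d}"
            rec = CellRecord(cell_id, group, age, region, params)
            for k, prot in enumerate(protocol_set):
                noise = (gspec.noise_sd_vc if prot.mode == "voltage_clamp"
                         else gspec.noise_sd_cc)
                sweep_seed = int(rng.integers(0, 2**31 - 1))
                meta = SweepMeta(cell_id=cell_id, group=group, age=age,
                                 region=str(region),
                                 protocol_id=prot.protocol_id,
                                 seed=sweep_seed)
                rec.sweeps[prot.protocol_id] = simulate(
                    params, prot, dt=dt, seed=sweep_seed, noise_sd=noise,
                    meta=meta)
            cells.append(rec)
            idx += 1
            if progress:
                print(f"  simulated {cell_id}")
    return cells
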