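"""Per-cell feature records: orchestrates all extractors over a cell's
protocol battery, applies the exclusion rule, and builds the flat feature
table (one row per cell, one column per variable)."""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import pandas as pd

from ..sweep import Sweep
from .firing import ahp_metrics, fi_ramp_metrics, sag_metrics, step_firing_metrics
from .leak import estimate_capacitance, fit_leak, rmp_from_ramp
from .pic import analyze_pic
from .spikes import detect_spikes

__all__ = ["CellFeatures", "qc_cell", "extract_cell_features",
           "features_table", "RMP_EXCLUSION_MV", "FEATURE_COLUMNS"]

log = logging.getLogger("mnephys.features")

RMP_EXCLUSION_MV = -45.0  # cells more depolarised than this are excluded

# protocol-id roles in the default battery
ROLE_VC_FAST = "vc_ramp_5s"
ROLE_VC_SLOW = "vc_ramp_16s"
ROLE_CAP = "cap_step"
ROLE_CC_RAMP = "cc_ramp"
ROLE_AHP = "ahp_pulse"
ROLE_SAG = "sag_step"
STEP_PREFIX = "cc_step_"

_REQUIRED = (ROLE_VC_FAST, ROLE_CC_RAMP)


@dataclass
class CellFeatures:
    """Flat per-cell feature record (NaN marks missing measurements)."""
    cell_id: str
    group: str
    age: str
    region: str
    qc: str = "included"   # included | excluded_RMP | missing_protocol
    rin_MOhm: float = math.nan
    capacitance_pF: float = math.nan
    rmp_mV: float = math.nan
    # PIC metrics, fast (5 s) and slow (16 s) ramp
    pic_onset_mV_5s: float = math.nan
    pic_max_mV_5s: float = math.nan
    pic_amp_pA_5s: float = math.nan
    pic_neg_slope_range_mV_5s: float = math.nan
    pic_norm_amp_pApF_5s: float = math.nan
    pic_onset_mV_16s: float = math.nan
    pic_max_mV_16s: float = math.nan
    pic_amp_pA_16s: float = math.nan
    pic_neg_slope_range_mV_16s: float = math.nan
    pic_norm_amp_pApF_16s: float = math.nan
    # ramp firing
    I_on_pA: float = math.nan
    I_off_pA: float = math.nan
    delta_I_pA: float = math.nan
    fi_slope_Hz_nA: float = math.nan
    threshold_mV: float = math.nan
    # step firing
    max_inst_freq_Hz: float = math.nan
    max_steady_freq_Hz: float = math.nan
    depol_block: str = ""
    # spike shape (first ramp spike)
    spike_height_mV: float = math.nan
    rate_of_rise_Vs: float = math.nan
    rate_of_fall_Vs: float = math.nan
    half_width_ms: float = math.nan
    # AHP and sag
    ahp_amp_mV: float = math.nan
    ahp_half_decay_ms: float = math.nan
    sag_amp_mV: float = math.nan
    sag_ratio: float = math.nan
    rebound: bool = False


def qc_cell(features: CellFeatures) -> str:
    """Exclusion rule: cells with RMP strictly more depolarised than -45 mV
    are excluded; missing required protocols flag missing_protocol."""
    if features.qc == "missing_protocol":
        return "missing_protocol"
    if math.isfinite(features.rmp_mV) and features.rmp_mV > RMP_EXCLUSION_MV:
        return "excluded_RMP"
    return "included"


def extract_cell_features(sweeps: dict[str, Sweep], *, cell_id: str = "",
                          group: str = "", age: str = "", region: str = "",
                          ) -> CellFeatures:
    """Run every applicable extractor over one cell's sweeps.

    ``sweeps`` maps protocol ids (see the default battery) to Sweeps.
    Missing protocols leave their features NaN; missing *required* protocols
    (fast voltage ramp, current ramp) set qc = missing_protocol.
    """
    first = next(iter(sweeps.values()), None)
    if first is not None and not cell_id:
        cell_id, group = first.meta.cell_id, first.meta.group
        age, region = first.meta.age, first.meta.region
    feats = CellFeatures(cell_id=cell_id, group=group, age=age, region=region)

    missing = [r for r in _REQUIRED if r not in sweeps]
    if missing:
        feats.qc = "missing_protocol"
        log.warning("cell %s: missing required protocols %s", cell_id, missing)

    cap = math.nan
    if ROLE_CAP in sweeps:
        c = estimate_capacitance(sweeps[ROLE_CAP])
        cap = c if c is not None else math.nan
    feats.capacitance_pF = cap

    # RMP read on the slowest available ramp (smallest C*dV/dt offset)
    rmp_role = ROLE_VC_SLOW if ROLE_VC_SLOW in sweeps else ROLE_VC_FAST
    for role, tag in ((ROLE_VC_FAST, "5s"), (ROLE_VC_SLOW, "16s")):
        if role not in sweeps:
            continue
        sw = sweeps[role]
        leak = fit_leak(sw)
        if tag == "5s":
            if leak.ok:
                feats.rin_MOhm = leak.input_resistance
            else:
                log.warning("cell %s: non-positive leak slope", cell_id)
        if role == rmp_role:
            rmp = rmp_from_ramp(sw)
            feats.rmp_mV = rmp if rmp is not None else math.nan
            if rmp is None:
                log.warning("cell %s: no zero-current crossing for RMP",
                            cell_id)
        if leak.ok:
            pic = analyze_pic(sw, cap, leak=leak, ramp_tag=tag)
            if pic.present:
                setattr(feats, f"pic_onset_mV_{tag}", pic.onset_V)
                setattr(feats, f"pic_max_mV_{tag}", pic.max_V)
                setattr(feats, f"pic_amp_pA_{tag}", pic.amplitude)
                setattr(feats, f"pic_neg_slope_range_mV_{tag}",
                        pic.negative_slope_range)
                setattr(feats, f"pic_norm_amp_pApF_{tag}",
                        pic.normalized_amplitude)

    if ROLE_CC_RAMP in sweeps:
        sw = sweeps[ROLE_CC_RAMP]
        spikes = detect_spikes(sw)
        fi = fi_ramp_metrics(sw, spikes)
        if fi.ok:
            feats.I_on_pA = fi.I_on
            feats.I_off_pA = fi.I_off
            feats.delta_I_pA = fi.delta_I
            feats.fi_slope_Hz_nA = fi.fi_slope
            feats.threshold_mV = fi.threshold_V
            sp = spikes[0]   # first ramp spike defines AP shape
            feats.spike_height_mV = sp.height
            feats.rate_of_rise_Vs = sp.rate_of_rise
            feats.rate_of_fall_Vs = sp.rate_of_fall
            feats.half_width_ms = sp.half_width
        else:
            log.warning("cell %s: no ramp spikes, F-I features missing",
                        cell_id)

    step_sweeps = [sweeps[k] for k in sorted(sweeps) if
                   k.startswith(STEP_PREFIX)]
    if step_sweeps:
        sf = step_firing_metrics(step_sweeps)
        feats.max_inst_freq_Hz = sf.max_instantaneous_Hz
        feats.max_steady_freq_Hz = sf.max_steady_state_Hz
        feats.depol_block = sf.block

    if ROLE_AHP in sweeps:
        try:
            amp, half = ahp_metrics(sweeps[ROLE_AHP])
            feats.ahp_amp_mV = amp
            feats.ahp_half_decay_ms = half
        except ValueError as e:
            log.warning("cell %s: AHP rejected (%s)", cell_id, e)

    if ROLE_SAG in sweeps:
        try:
            amp, ratio, reb = sag_metrics(sweeps[ROLE_SAG])
            feats.sag_amp_mV = amp
            feats.sag_ratio = ratio
            feats.rebound = reb
        except ValueError as e:
            log.warning("cell %s: sag rejected (%s)", cell_id, e)

    feats.qc = qc_cell(feats)
    if feats.qc == "excluded_RMP":
        log.info("cell %s excluded: RMP %.1f mV more depolarised than "
                 "%.0f mV", cell_id, feats.rmp_mV, RMP_EXCLUSION_MV)
    return feats


FEATURE_COLUMNS = list(CellFeatures.__dataclass_fields__)


def features_table(records: list[CellFeatures]) -> pd.DataFrame:
    """One row per cell, one column per variable, metadata columns first."""
    df = pd.DataFrame([asdict(r) for r in records], columns=FEATURE_COLUMNS)
    return df
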