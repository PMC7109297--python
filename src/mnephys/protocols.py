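"""Clamp protocol definitions and the standard protocol builders.

A protocol is an ordered list of segments, each a hold, ramp or step of the
command signal.  Voltage-clamp levels are in mV, current-clamp levels in pA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "Segment",
    "ProtocolSpec",
    "build_vclamp_ramp_protocol",
    "build_cclamp_ramp_protocol",
    "build_cclamp_step_protocol",
    "build_capacitance_step_protocol",
]

Mode = Literal["voltage_clamp", "current_clamp"]
SegmentKind = Literal["hold", "ramp", "step"]


@dataclass(frozen=True)
class Segment:
    """One protocol epoch: the command moves from ``start`` to ``end`` over
    ``duration`` seconds (linearly for a ramp; hold/step are constant and
    require start == end)."""

    kind: SegmentKind
    start: float
    end: float
    duration: float  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        if not (np.isfinite(self.start) and np.isfinite(self.end)):
            raise ValueError("segment levels must be finite")
        if self.kind in ("hold", "step") and self.start != self.end:
            raise ValueError(f"{self.kind} segment must have start == end")

    @property
    def slope(self) -> float:
        """Command slope in level-units per second."""
        return (self.end - self.start) / self.duration


@dataclass(frozen=True)
class ProtocolSpec:
    mode: Mode
    segments: tuple[Segment, ...]
    protocol_id: str = "protocol"

    def __post_init__(self) -> None:
        if self.mode not in ("voltage_clamp", "current_clamp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        prev_end = None
        for seg in self.segments:
            if seg.kind == "ramp" and prev_end is not None and seg.start != prev_end:
                raise ValueError(
                    f"ramp must start at previous segment's end level "
                    f"({seg.start} != {prev_end})")
            prev_end = seg.end

    @property
    def duration(self) -> float:
        """Total protocol duration in seconds."""
        return sum(s.duration for s in self.segments)

    @property
    def command_units(self) -> str:
        return "mV" if self.mode == "voltage_clamp" else "pA"

    @property
    def response_units(self) -> str:
        return "pA" if self.mode == "voltage_clamp" else "mV"

    def sample(self, dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
        """Sample the command and its analytic time-derivative on a uniform
        grid of spacing ``dt_ms``.

        The derivative is taken piecewise per segment (corner samples get the
        slope of the segment they open), so the returned pair is exactly
        consistent with the protocol's piecewise-linear definition.
        """
        if dt_ms <= 0:
            raise ValueError("dt must be positive")
        n_total = int(round(self.duration * 1000.0 / dt_ms)) + 1
        cmd = np.empty(n_total)
        dcmd = np.empty(n_total)  # level-units per ms
        i = 0
        for seg in self.segments:
            n = int(round(seg.duration * 1000.0 / dt_ms))
            sl = seg.slope / 1000.0  # per ms
            idx = np.arange(n)
            cmd[i:i + n] = seg.start + sl * idx * dt_ms
            dcmd[i:i + n] = sl if seg.kind == "ramp" else 0.0
            i += n
        cmd[i] = self.segments[-1].end
        dcmd[i] = 0.0
        return cmd, dcmd


def build_vclamp_ramp_protocol(holding: float, peak: float, rise: float,
                               fall: float, pre_hold: float = 0.5,
                               post_hold: float = 0.5,
                               protocol_id: str | None = None) -> ProtocolSpec:
    """Triangular voltage-clamp ramp: hold -> ascending ramp to ``peak`` in
    ``rise`` s -> descending ramp back to ``holding`` in ``fall`` s -> hold.

    The standard PIC protocols hold at -90 mV and ramp to 0 mV in 2.5 s
    (36 mV/s) or 8 s (11.25 mV/s), returning symmetrically.
    """
    if rise <= 0 or fall <= 0:
        raise ValueError("rise and fall durations must be positive")
    if protocol_id is None:
        protocol_id = f"vc_ramp_{rise + fall:g}s"
    segs = (
        Segment("hold", holding, holding, pre_hold),
        Segment("ramp", holding, peak, rise),
        Segment("ramp", peak, holding, fall),
        Segment("hold", holding, holding, post_hold),
    )
    return ProtocolSpec("voltage_clamp", segs, protocol_id)


def ramp_slope(protocol: ProtocolSpec) -> float:
    """Ascending-ramp slope of a triangular protocol, in units/s."""
    for seg in protocol.segments:
        if seg.kind == "ramp":
            return seg.slope
    raise ValueError("protocol has no ramp segment")


def build_cclamp_ramp_protocol(peak_pA: float, rise: float, fall: float,
                               pre_hold: float = 0.5, post_hold: float = 0.5,
                               protocol_id: str = "cc_ramp") -> ProtocolSpec:
    """Triangular current-clamp ramp from 0 pA used for F-I and dI."""
    if rise <= 0 or fall <= 0:
        raise ValueError("rise and fall durations must be positive")
    segs = (
        Segment("hold", 0.0, 0.0, pre_hold),
        Segment("ramp", 0.0, peak_pA, rise),
        Segment("ramp", peak_pA, 0.0, fall),
        Segment("hold", 0.0, 0.0, post_hold),
    )
    return ProtocolSpec("current_clamp", segs, protocol_id)


def build_cclamp_step_protocol(amplitude_pA: float, duration: float = 1.0,
                               pre_hold: float = 0.3, post_hold: float = 0.5,
                               protocol_id: str | None = None) -> ProtocolSpec:
    """Square current step (depolarising or hyperpolarising) from 0 pA."""
    if protocol_id is None:
        protocol_id = f"cc_step_{amplitude_pA:g}pA"
    segs = (
        Segment("hold", 0.0, 0.0, pre_hold),
        Segment("step", amplitude_pA, amplitude_pA, duration),
        Segment("hold", 0.0, 0.0, post_hold),
    )
    return ProtocolSpec("current_clamp", segs, protocol_id)


def build_capacitance_step_protocol(amplitude_pA: float = -150.0,
                                    duration: float = 0.25,
                                    pre_hold: float = 0.1,
                                    post_hold: float = 0.15) -> ProtocolSpec:
    """Small hyperpolarising current step for the membrane-transient
    capacitance estimate (C = tau * g_total)."""
    return build_cclamp_step_protocol(amplitude_pA, duration, pre_hold,
                                      post_hold, protocol_id="cap_step")
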