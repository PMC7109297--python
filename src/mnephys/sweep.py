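"""The in-memory sweep container: one protocol epoch of command + response."""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = ["Sweep", "SweepMeta"]

REGIONS = ("cervical", "thoracic", "lumbar", "sacral")
GROUPS = ("sham", "HI_unaffected", "HI_mild", "HI_severe")


@dataclass
class SweepMeta:
    cell_id: str = "cell"
    group: str = "sham"
    age: str = "P0"          # postnatal day, P0..P5
    region: str = "lumbar"
    protocol_id: str = "protocol"
    seed: int = 0


@dataclass
class Sweep:
    """Sampled command and response signals for one protocol epoch.

    ``dt`` is the sample interval in ms.  In voltage clamp the command is mV
    and the response (injected current) pA; in current clamp the command is
    pA and the response (membrane potential) mV.
    """

    dt: float
    mode: str
    command: np.ndarray
    response: np.ndarray
    meta: SweepMeta = field(default_factory=SweepMeta)

    def __post_init__(self) -> None:
        self.command = np.asarray(self.command, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mode not in ("voltage_clamp", "current_clamp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.command.ndim != 1 or self.response.ndim != 1:
            raise ValueError("command and response must be 1-D")
        if len(self.command) != len(self.response):
            raise ValueError("command and response must have equal length")
        if len(self.command) < 2:
            raise ValueError("sweep needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.command)

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms."""
        return np.arange(self.n_samples) * self.dt

    @property
    def command_units(self) -> str:
        return "mV" if self.mode == "voltage_clamp" else "pA"

    @property
    def response_units(self) -> str:
        return "pA" if self.mode == "voltage_clamp" else "mV"
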