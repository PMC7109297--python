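"""Shared helpers for feature extraction."""

from __future__ import annotations

import numpy as np

from ..sweep import Sweep


def boxcar(x: np.ndarray, width_ms: float, dt: float) -> np.ndarray:
    """Centered moving-average smoothing; width rounded to an odd number of
    samples; no-op if the window is a single sample."""
    n = max(1, int(round(width_ms / dt)))
    if n % 2 == 0:
        n += 1
    if n == 1:
        return np.asarray(x, dtype=float)
    k = np.ones(n) / n
    pad = n // 2
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(xp, k, mode="valid")


def ascending_limb(sweep: Sweep) -> slice:
    """Index slice of the ascending limb of a triangular ramp command
    (start of sweep through the command maximum)."""
    i_peak = int(np.argmax(sweep.command))
    return slice(0, i_peak + 1)


def descending_limb(sweep: Sweep) -> slice:
    i_peak = int(np.argmax(sweep.command))
    return slice(i_peak, len(sweep.command))


def step_epoch(sweep: Sweep) -> tuple[int, int]:
    """(onset, offset) sample indices of a square step command (the epoch
    where the command differs from its initial level)."""
    cmd = sweep.command
    off_level = cmd[0]
    changed = np.nonzero(cmd != off_level)[0]
    if len(changed) == 0:
        raise ValueError("command contains no step")
    return int(changed[0]), int(changed[-1])
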