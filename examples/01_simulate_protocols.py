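"""Simulate the standard voltage- and current-clamp protocols on one cell.

Builds the slow PIC ramp (holding -90 mV, 11.25 mV/s to 0 mV and back) and
a current ramp, runs them on the default sham motoneuron, and prints what
the recordings look like numerically.
"""

import numpy as np

from mnephys import (MNParameters, build_cclamp_ramp_protocol,
                     build_vclamp_ramp_protocol, simulate)
from mnephys.protocols import ramp_slope

cell = MNParameters()

vc = build_vclamp_ramp_protocol(-90, 0, 8.0, 8.0)
print(f"voltage ramp: {ramp_slope(vc):.2f} mV/s, {vc.duration:.1f} s total")
sweep = simulate(cell, vc, seed=1)
print(f"  {sweep.n_samples} samples at {1/sweep.dt:.0f} kHz; "
      f"current range [{sweep.response.min():.0f}, "
      f"{sweep.response.max():.0f}] pA")
# the inward dip below the leak line between -50 and -30 mV is the PIC

cc = build_cclamp_ramp_protocol(900, 3, 3)
sweep = simulate(cell, cc, seed=2)
n_spk = int(np.sum((sweep.response[:-1] < 0) & (sweep.response[1:] >= 0)))
print(f"current ramp to 900 pA: ~{n_spk} spikes, "
      f"V range [{sweep.response.min():.1f}, {sweep.response.max():.1f}] mV")
# spikes appear above rheobase on the ascending limb and persist partway
# down the descending limb; the current distance between onset and offset
# is the delta-I hysteresis measured in example 03
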