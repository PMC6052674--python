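"""Compute overall dynamic body acceleration (ODBA) from raw tri-axial
accelerometer bursts.

Builds a handful of synthetic 30-s bursts with known activity states,
applies a device calibration, and converts each burst to a single ODBA
value (g).  Active bursts should come out roughly an order of magnitude
above inactive ones.
"""

import numpy as np

from terrapath import synth
from terrapath.accel import Calibration, apply_calibration, compute_odba

cfg = synth.SynthConfig(seed=7)
bursts, labels = synth.simulate_bursts(cfg, n_bursts=6)

cal = Calibration(offset=[0.01, -0.02, 0.0], gain=[1.0, 1.0, 1.02])
for burst, state in zip(bursts, labels["state"]):
    miscal = burst.__class__(
        individual=burst.individual,
        timestamp=burst.timestamp,
        samples=burst.samples / cal.gain + cal.offset,  # what the device logged
        rate=burst.rate,
        calibration=cal,
    )
    odba = compute_odba(apply_calibration(miscal))
    print(f"{burst.timestamp}  ODBA = {odba:.4f} g  (true state: {state})")

print()
print("Each value is the burst mean of |dynamic x| + |dynamic y| + |dynamic z|")
print("after removing the per-axis static (gravitational) component;")
print("active bursts sit near 0.03-0.06 g, inactive ones near 0.003 g.")
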